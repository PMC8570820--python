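"""Benchmark the heuristic search against Smith-Waterman ground truth.

Replays the evaluation protocol used to validate heuristic protein aligners:
the full Smith-Waterman oracle (the role SSEARCH plays) defines the set of
true (query, subject) pairs at E <= 1e-8, and the heuristic's hit list is
scored against it.  Precision is the fraction of reported hits that are
true; recall the fraction of true pairs reported.  Rates are truncated (not
rounded) at two decimals, the convention that reproduces published
benchmark tables from their printed hit counts.
"""

import numpy as np

import pzsearch as pz

rng = np.random.default_rng(42)
query = pz.AminoAcidSequence("query300aa", pz.random_protein(300, rng))

specs = [pz.PlantSpec(query, 15, ident, 0.01) for ident in (0.9, 0.8, 0.7, 0.6)]
sim = pz.SimConfig(n_samples=20, seqs_per_sample=250, planted=specs, rng_seed=42)
reference = pz.generate_reference(sim)
refs = reference.all_sequences()

result = pz.search([query], [refs], pz.SearchConfig())
predicted = {h.pair for h in result.per_query[query.id].hits}

truth = pz.make_ground_truth([query], refs, threshold=1e-8)
precision, recall, tp = pz.precision_recall(predicted, truth.pairs)

print(f"planted homologs: {len(reference.planted)} at identities 0.9/0.8/0.7/0.6")
print(f"ground truth (full Smith-Waterman, E <= 1e-8): {len(truth.pairs)} pairs")
print(f"heuristic search: {len(predicted)} hits, {tp} true")
print(f"precision {pz.format_rate(precision)} ({len(predicted)} hits)  "
      f"recall {pz.format_rate(recall)} ({len(predicted)} hits)")
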