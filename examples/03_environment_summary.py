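"""Summarize where in the environment a query's homologs were found.

After searching an ontology-annotated reference, every hit is attributed to
its sample's environment class and coordinates.  The class table shows the
environmental distribution of similar sequences (the basis for functional
inference: a transporter hitting mostly gut samples is likely gut-adapted);
the geography table shows where those samples were collected.
"""

import numpy as np

import pzsearch as pz

rng = np.random.default_rng(3)
query = pz.AminoAcidSequence("transporter_like", pz.random_protein(250, rng))

sim = pz.SimConfig(
    n_samples=10,
    seqs_per_sample=80,
    planted=[pz.PlantSpec(query, 20, 0.85, 0.01)],
    rng_seed=3,
)
reference = pz.generate_reference(sim)

result = pz.search([query], reference.chunks, pz.SearchConfig())
hits = result.per_query[query.id].hits
print(f"{len(hits)} hits across {len(reference.metadata)} samples\n")

env = pz.summarize_by_class(hits, reference.metadata, "env")
print("environment classes (hit_fraction = share of all hits):")
print(env.to_string(index=False), "\n")

geo = pz.summarize_geography(hits, reference.metadata)
print("geographic distribution:")
print(geo.to_string(index=False))
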