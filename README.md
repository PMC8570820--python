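# pzsearch

Fast amino-acid similarity search against large, chunked metagenome protein
references — with a rigorous Smith–Waterman oracle for benchmarking and
ontology-based summarization of where in the environment a query's homologs
occur.

## The problem

Public metagenome collections hold billions of predicted protein sequences,
each tied to a sampled environment (gut, soil, marine water, ...) and often
to coordinates. Searching a query protein against such a collection answers
two questions at once: *does this sequence have homologs out there?* and
*in which environments do they live?* — the basis for functional inference
and homolog mining. The obstacle is scale: classic database-indexing
aligners need the whole reference resident in memory.

`pzsearch` takes the opposite layout: it builds an exact k-mer seed table
over the **query** set (small, bounded at 10 000 sequences per submission)
and **streams** the reference past it in chunks. Memory stays proportional
to the queries; the reference can be arbitrarily large and split across
files or workers, and chunked results merge into a ranking that is
bit-identical to a single pass.

## The method

For each reference sequence the aligner:

1. looks up every length-k word (default k = 4) in the query seed table;
2. collapses seeds on one (query, diagonal) within 2k residues and extends
   each survivor gap-free with an X-drop rule (default drop 20);
3. when the ungapped segment reaches 22 bits, performs a banded affine-gap
   local extension (band 64 diagonals around the seed diagonal, BLOSUM62,
   gap open 11 / extend 1);
4. converts raw scores S to Karlin–Altschul statistics,

   E = K·m·n·e^(−λS),  bits = (λS − ln K)/ln 2,

   with the published gapped constants λ = 0.267, K = 0.041 and n the
   **grand total** residue count over all chunks, then reports the best
   alignment per query–subject pair with E ≤ 10⁻⁸, ranked, up to 10 000
   hits per query.

For validation, `pzsearch.smith_waterman` is a full-matrix, affine-gap
exact local aligner (the role SSEARCH plays in published benchmarks):
`make_ground_truth` runs it over all pairs and `precision_recall` scores a
tool's hit list against it, truncating (not rounding) rates at two
decimals — the convention that reproduces published three-tool comparison
tables from their printed hit counts (e.g. 215/303 → 70.95, 224/303 →
73.92).

The `synthdata` module generates download-free references that emulate an
ontology-annotated metagenome collection: samples with environment classes,
body-site classes and coordinates, decoy proteins drawn from BLOSUM62
background frequencies, and homologs of chosen queries planted at
controlled identity with a truth table.

## Worked example

`examples/02_benchmark_against_oracle.py` plants 60 homologs of a
300-residue query (15 each at identities 0.9, 0.8, 0.7, 0.6, indel rate
0.01) into 20 samples × 250 decoys, searches with the defaults, and scores
the result against the exhaustive Smith–Waterman truth:

```
planted homologs: 60 at identities 0.9/0.8/0.7/0.6
ground truth (full Smith-Waterman, E <= 1e-8): 60 pairs
heuristic search: 60 hits, 60 true
precision 100 (60 hits)  recall 100 (60 hits)
```

All 60 planted homologs — and no decoy — reach E ≤ 10⁻⁸ under the exact
aligner, and the heuristic recovers every one of them with no false
positives. `examples/01_search_planted_reference.py` shows the underlying
hit table and `examples/03_environment_summary.py` the environment-class
and geographic summaries, e.g.:

```
class_id class_label  hit_count  hit_fraction  distinct_samples
  ENV:02        soil          6          0.30                 2
  ENV:05  hot spring          6          0.30                 3
  ENV:01         gut          5          0.25                 2
  ENV:04  freshwater          3          0.15                 2
```

The same operations are available as a CLI for shell pipelines:

```
pzsearch simulate --samples 20 --seqs-per-sample 250 \
    --plant query.faa:60:0.8:0.01 --seed 42 --out-dir fixtures/
pzsearch search --query query.faa --db fixtures/ --out hits.tsv --evalue 1e-8
pzsearch oracle --query query.faa --db fixtures/ --out truth.tsv
pzsearch eval --pred hits.tsv --truth truth.tsv --out report.tsv
pzsearch summarize --hits hits.tsv --metadata fixtures/samples.tsv \
    --namespace env --out env_summary.tsv
```

Hit tables are BLAST `outfmt 6`-compatible 12-column TSV.

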