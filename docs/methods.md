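# Methods

## Model and procedure

`pzsearch` is a seed-and-extend local protein aligner with the
query/reference roles swapped relative to classic database search: the
k-mer index is built over the query set and the reference is streamed past
it. The contract this buys is *data-parallel merge invariance*: because
E-values are computed against the grand total reference residue count
(communicated to every chunk before extension) and ties are broken on
(E-value, bit score, subject id), a search over C chunks with W workers
serializes to the same bytes as a single pass over the concatenated
reference. The merge is a plain sort; no rescaling or re-ranking step
exists that could break it.

The pipeline per reference sequence:

1. **Seeding.** Exact k-mer lookup (default k = 4) in the query postings
   table; no reduced alphabet and no neighborhood words by default
   (neighborhood expansion is a config hook, off). One-hit triggering:
   every surviving seed is extended. Words containing `*` — and, by
   default, `X` — are never indexed; homopolymer words are indexed but
   capped at 10 000 postings scanned per word per reference sequence, a
   worst-case guard against low-complexity blowup.
2. **Seed deduplication.** On one (query, diagonal), seeds within 2k
   residues of the last kept seed collapse to the leftmost, avoiding
   redundant extensions of the same region.
3. **Ungapped X-drop extension** (drop 20 raw units): grow left and right
   from the seed, stop a side once its running sum falls `x_drop` below
   that side's best, return the best prefix/suffix pair. The result is the
   maximal-scoring gap-free segment through the seed up to the X-drop
   approximation.
4. **Gapped banded extension**, triggered at 22 bits ungapped. A local
   affine-gap alignment restricted to 64 diagonals centred on the seed
   diagonal. Because the ungapped segment lies inside the band, the gapped
   score never falls below the ungapped score, and widening the band can
   only raise it. Rows whose in-band best has fallen `x_drop_gapped = 38`
   below the running best (past the best row) terminate the scan.
   Out-of-band cells are treated as fresh local starts (score 0), which is
   sound for a *local* alignment lower bound.
5. **Statistics and ranking.** E = K·m·n·e^(−λS), bits = (λS − ln K)/ln 2,
   with the published BLOSUM62 gap 11/1 constants λ = 0.267, K = 0.041.
   The search space is the raw m·n product — no finite-size length
   adjustment — which makes the heuristic's and the oracle's E-values
   exactly commensurable (see "Why precision is structurally high" below).
   The best HSP per (query, subject) pair becomes the hit; hits with
   E ≤ `evalue_max` (default 10⁻⁸) are ranked by (E, −bits, subject id)
   and truncated at `max_hits_per_query` (default 10 000). Query
   submissions are capped at 10 000 sequences.

**Gap cost convention.** A gap of length L costs
`gap_open + (L − 1) · gap_extend`: the first gapped residue pays the
opening cost. With the default 11/1 a length-1 gap costs 11. (NCBI tools
write the same scheme as "open 11, extend 1" but charge 11 + L; the
published λ/K for 11/1 are insensitive to this off-by-one at the reported
precision, and all internal consistency checks — oracle, replay, Biopython
cross-validation — use one convention throughout.)

**Tie-breaking.** The DP best cell is the first maximum in row-major scan
order (smallest end coordinates); traceback prefers aligned columns, then
subject-consuming gaps. This is a determinism device, not a biological
claim: every emitted path replays to its exact integer score, and tests
assert byte-stable output across chunkings and worker counts.

## The Smith–Waterman oracle and the evaluation protocol

`smith_waterman` is a full-matrix affine-gap local aligner with traceback
(no band, no X-drop); `smith_waterman_score` is the linear-memory
score-only kernel used for bulk ground truth. Both are numba-compiled and
verified against (a) an independently written plain-Python three-matrix DP
in the test suite and (b) Biopython's `PairwiseAligner` in local mode —
two implementations the package code never calls.

`make_ground_truth` runs the exact aligner over all (query, subject) pairs
— feasible only at desk scale, which is the point of the synthetic
fixtures — and keeps pairs with E ≤ threshold. `precision_recall` counts
query–subject *pairs* (best HSP per pair), and **truncates** rates at the
second decimal using integer arithmetic (`10000·tp // denom / 100`).
Truncation, not rounding, is the convention that reproduces published
benchmark-table rates from their printed counts (215/303 → 70.95 and
224/303 → 73.92 would round to .96/.93). Display strings trim trailing
zeros ("91.8", "100"); stored values keep two decimals. An empty
prediction set against non-empty truth yields recall 0.00 with precision
undefined (emitted as `NA`); two empty sets are vacuously perfect.

**Why precision is structurally high.** Every heuristic HSP score is
bounded by the exact optimum for its pair, and both sides use the same
E-value formula and the same total n. A heuristic hit with E ≤ t therefore
has exact E ≤ t, i.e. it is in the ground truth by construction. Observed
precision below 100% could only arise from comparing against truth built
with a different search space — which the API prevents by defaulting both
to the reference's total residue count. The benchmark's informative axis
is recall.

## Synthetic reference generator

The generator emulates the *product* of a metagenome annotation pipeline —
many samples, each contributing predicted proteins, annotated with an
environment-ontology class, optionally a body-site class, and coordinates —
without any external download.

- **Decoys** are i.i.d. draws from the BLOSUM62 background amino-acid
  frequencies. This keeps the chance-score null consistent with the
  scoring matrix, so the E-value calibration sanity checks (no decoy at
  E ≤ 10⁻⁸ in a ~10⁶-residue reference) are meaningful. Real metagenome
  proteins have domain structure, composition bias and shared families;
  i.i.d. decoys have none of these, so passing tests bound chance hits
  under the null model, not false-positive rates on real data.
- **Planted homologs**: per-column substitution with probability
  1 − target_identity to a uniformly chosen different residue; indel
  events per column at `indel_rate` (default 0.01, range capped at 0.2),
  geometric lengths with mean 2, insertions and deletions equally likely.
  Realized identity (fraction of query columns unsubstituted and
  undeleted) is recorded in the truth table and recounted in tests.
- **Defaults** — 20 samples × 250 sequences, lengths uniform on
  [100, 350] residues (short-read gene predictions are short), one
  environment class per sample (multi-class behind a flag so the
  Σ fraction = 1 conservation law stays testable), five environment
  classes with gut/soil/marine-skewed weights, a small city coordinate
  pool including a no-coordinate entry. The standard benchmark plants
  60 homologs of a 300-residue query, 15 each at identities
  0.9/0.8/0.7/0.6 — spanning comfortably-detectable to
  near-twilight-zone for a 300-residue protein at E ≤ 10⁻⁸.
- **Determinism**: one `numpy` Generator seeded from the config; same
  config ⇒ byte-identical files. The generator spawns a child seed
  sequence from the integer seed so that sequences a user draws elsewhere
  with the same integer (e.g. the query itself) are independent of the
  reference stream — without this, a decoy can be a shifted copy of the
  query.

## Summarization

The counting unit is the hit (best HSP per pair), so a protein abundant in
a sample contributes once per matching sequence — abundance is preserved,
which is the motivation for searching unassembled predicted proteins in
the first place. Each hit counts toward *every* class annotating its
sample, so multi-class fractions may sum above 1 (documented in the API);
with single-class metadata the counts, including the reserved
`unclassified` and `no-location` rows, sum exactly to the number of input
hits. Classes are flat labels from the metadata table; ontology-graph
rollup to ancestor classes is a deliberate non-feature (the ontologies are
external resources), left as an extension point. The class table reports
both hit counts and distinct-sample counts, since either could be the
quantity of interest.

## Design choices where the design was open

- **Sample attribution** uses the `sampleID|sequenceID` header convention,
  overridable by an explicit two-column map file. Some convention was
  required; this one keeps FASTA self-contained.
- **Heuristic operating point** (k = 4 exact seeds, one-hit trigger,
  X-drops 20/38, 22-bit gapped trigger, band 64): BLAST-family values
  chosen for high sensitivity on moderately-to-highly similar sequences
  at the E ≤ 10⁻⁸ operating point. The ungapped trigger at 22 bits is far
  below the ~75 bits needed to reach 10⁻⁸ in a megaresidue search, so no
  reportable hit can be lost at the trigger.
- **Scoring scheme** BLOSUM62 11/1 with its published constants — the
  default of the tools such searches are compared against, making
  E-values commensurable across tools. BLOSUM50 13/2 is bundled; other
  schemes need explicit `KarlinAltschulParams`.
- **Workers** map chunks to processes (`ProcessPoolExecutor`); merge
  invariance makes the worker count invisible in the output, which is
  asserted byte-for-byte in tests.

## Numerical notes and degenerate inputs

- All alignment scores are 32-bit integers end to end; path replay is
  asserted as exact integer equality, never approximate.
- `E = m·n·2^(−bits)` agrees with the direct formula to < 10⁻¹² relative
  error (measured ~2·10⁻¹⁴).
- Queries shorter than k are excluded from seeding with a warning but
  remain valid oracle inputs. References shorter than k yield no seeds.
  An empty reference returns empty results with a warning rather than an
  error. A gapped extension that degenerates to an empty path falls back
  to its ungapped segment.
- Problem sizes throughout tests and the acceptance script (≈5 000
  reference sequences, ≈1.1 Mresidues, hundreds of oracle pairs) are
  chosen so the full suite completes in minutes on one CPU while keeping
  every planted-homolog identity class populated.

## Known limitations

- No composition-based score adjustment, no sum statistics over multiple
  HSPs, no finite-size length correction: E-values are exact for the
  stated model, which is slightly conservative for short sequences.
- The banded gapped extension can under-score alignments whose optimal
  path drifts more than half the band off the seed diagonal (≈32
  diagonals); at the default indel rates this never binds, and the oracle
  dominance tests quantify the gap (zero observed on the benchmark).
- The i.i.d. decoy model understates real-data false positives (see
  above); sensitivity results on planted homologs transfer to real data
  only to the extent that real homologs preserve exact 4-mers, which
  holds for the ≥ 60%-identity regime the benchmark targets.
- Translated (nucleotide) search, FASTQ input and ontology OBO parsing
  are out of scope.
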