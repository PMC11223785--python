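# Methods

This note records how each stage of the pipeline is defined, which knobs
matter, and where the design was genuinely open.

## Chain representation

A `ProteinChain` is an identifier, a one-letter sequence and the ordered Cα
trace in ångström. Parsing (gemmi) keeps only ATOM Cα atoms of amino-acid
residues, ordered by residue number with insertion codes breaking ties
lexicographically. Residues without a Cα are dropped, not imputed — predicted
models are complete, so this path only guards experimental input — and any
chain left with fewer than 3 Cα atoms is rejected. The 3-residue floor is
this package's own rule: below it neither a distance matrix nor a
superposition is meaningful.

## Embedding

The structural summary is the pairwise Cα distance matrix, which discards
orientation, position and handedness, and never looks at the sequence. The
compression operator is fixed as: bilinearly resample the n×n matrix onto an
m×m grid whose corner samples coincide with the matrix corners (sample
position `i·(n−1)/(m−1)`), then flatten the strict upper triangle row-major.
Choices worth recording:

- **m = 8 (dimension 28).** At 32-bit floats this is ~100 bytes per chain,
  the regime where an embedding store for a database of hundreds of millions
  of chains fits in tens of GiB and a 10-million-candidate Euclidean scan is
  trivial. m is a config knob (`EmbeddingConfig.grid_size`).
- **Diagonal excluded.** The resized diagonal is ~0 by construction and
  carries no information.
- **No per-protein normalization.** Absolute distances preserve global size,
  so a small and a large protein of the same shape embed differently;
  `EmbeddingConfig.scale` exposes a global divisor for callers who want
  different units. Scaling all coordinates by k scales the embedding by k
  exactly (bilinearity), a property the tests assert.
- **Precision.** Embeddings are computed in float64 (rigid-motion invariance
  holds to 1e-9 and is tested at that level) and stored on disk as float32
  (round-trip tolerance 1e-6).

Intrinsic limitations, asserted as tests rather than hidden: the embedding
is chirality-blind (a mirror image embeds identically), sequence-blind, and
weights unstructured regions equally with secondary structure.

## Learned index

k-means (k-means++ init, fixed seed, 10 restarts) partitions the embedding
collection into K buckets; bucket membership is the argmin distance to the
final centroids, recomputed after fitting so the "every item sits in its
nearest centroid's bucket" invariant holds exactly, ties to the lowest
cluster id. A fully connected network (one hidden layer of 128 ReLU units,
K-way softmax, cross-entropy, adam, fixed 50-epoch budget, seeded init)
is trained to map an embedding to its bucket label and acts as the query
router: `probe` returns the `n_probe` highest-scoring buckets (descending
score, ties by ascending cluster id). Buckets are never re-assigned after
training — the router only routes.

Two training details are this package's own: inputs to the network are
standardized by the training-set feature mean/std (raw embedding entries
are ångström distances whose scale varies by an order of magnitude across
features; the standardization is baked into the frozen forward pass), and
the adam step size is 0.01 — with the sklearn default of 1e-3 the router is
clearly underfit within the 50-epoch budget. After training, the weights
are extracted into a plain NumPy forward pass, so routing is deterministic,
bit-reproducible after save/load, and independent of sklearn internals.

Desk-scale defaults: K = 64, n_probe = 10. With n_probe = K the index
degenerates to exhaustive search; the test suite uses this as the oracle
(top-50 ids and order must equal brute force exactly) and the `bench`
command quantifies the recall/probe-width trade-off. On the standard
20-family × 50-member benchmark, recall@10 at n_probe = 10 is required to
be ≥ 0.9 and recall must be non-decreasing in n_probe.

## Alignment and metrics

`kabsch_superpose` is the closed-form SVD solution with the determinant
correction excluding reflections; tests check it against a derivative-free
numerical optimizer and against 100 random rotations per pairing.

The TM-score uses the standard normalization
`d0(L) = 1.24·(L−15)^(1/3) − 1.8`, floored at 0.5 Å, and
`TM = (1/L) Σ 1/(1+(d_i/d0)²)`. **Normalization length is the query chain
length** by default — the score of a pair is asymmetric, and the stored
value is always query-normalized; `TMParams.normalization_length` overrides
this.

`align_chains` is an iterative sequence-order-dependent engine:

1. Deterministic starts: gapless threadings at offsets 0, ±⌈min(n)/4⌉,
   ±2⌈min(n)/4⌉ and the length-difference offset, plus 20-residue fragment
   seeds anchored at the start/middle/end of both chains.
2. Per start, iterate: Kabsch superposition on the current pairs → residue
   score matrix `S_ij = 1/(1+(d_ij/d0)²)` in the superposed frame → global
   dynamic programming → new pairs; stop when the TM-score gain falls below
   `convergence_tol` (1e-6) or after `max_iterations` (30).
3. Return the best-scoring alignment over all starts; RMSD, aligned count
   and sequence identity are computed over its pairs.

The DP uses a flat gap penalty of −0.6 with **free end gaps**: terminal
gaps are the norm when chains differ in length, and penalizing them biases
short-vs-long alignments; internal gaps pay the penalty. The recurrence is
JIT-compiled (numba) since it is the pipeline's hot loop. The engine tracks
the best score per iteration (`score_trace`), which is non-decreasing by
construction and exposed for inspection.

## Search workflow

A query token is classified in order: UniProt accession pattern (official
regular expression, returned as-is), 4-character PDB id (local table
lookup), else gene symbol (local table lookup); one-to-many mappings
resolve to the lexicographically smallest accession with alternatives
logged. Live mapping services are deliberately replaced by two-column TSV
tables so the engine is testable offline; the table loader is the seam
where a networked resolver could be slotted in. Queries must be present in
the indexed chain store — uploading foreign structures is out of scope.

The staged pipeline is: resolve → embed → probe(n_probe = 10) → gather →
rank by Euclidean distance (ties by ascending id) → cap at 1000 candidates
→ align the first 50 → attach organism metadata. `expand` scores the next
50/100/200/300 hits (clamped at the candidate count); scored hits are
always a prefix of the ranking, so expansion order cannot change the
result. Alignment results are cached by (query id, result id, scorer
digest) and whole sessions by query id; a repeated search performs no
alignment work, which the tests observe via an instrumentation counter.

CSV export schema (header is part of the contract):
`query_id,result_id,embedding_distance,tm_score,rmsd,aligned_residues,sequence_identity,organism`.
TM-score, RMSD and identity are written with 4 decimals; unscored hits are
excluded; a missing organism is an empty field.

## Synthetic data

The generator emulates the regimes the search must cope with: ideal
α-helices (r = 2.3 Å, 100° twist, 1.5 Å rise), extended strands (3.5 Å rise,
±0.9 Å zigzag), and self-avoiding random-walk coils (3.8 Å steps, 3.0 Å
clash cutoff) standing in for unstructured chains. A benchmark family is
one seed chain plus members derived by Gaussian coordinate noise and a
random rigid motion. Because helix and strand geometry is deterministic,
each family seed additionally receives a fixed 5 Å coordinate jitter so two
families of the same secondary-structure class remain distinct folds —
without it, "different families" of helices would be the same structure and
family labels would be meaningless for recall evaluation.

Default study conditions: 20 families × 50 members, lengths uniform in
50–200 residues, member noise σ = 1 Å. All generators are pure functions of
their arguments including the seed. What this emulates — and what it does
not: synthetic families are isotropic Gaussian clouds around one fold, so
they lack the continuous fold gradients, domain insertions and length
variation of real family members; passing the recall benchmark shows the
index machinery is sound, not that real-database recall equals the measured
value.

## Reproducibility

Every stochastic stage (database generation, k-means, router init, query
sampling) draws its seed from a named SHA-256 substream of one master seed,
so CLI rebuilds are bit-identical (equal manifest digests) and the
acceptance script is deterministic given `--seed`. Problem sizes used in
tests and the acceptance script (1000-chain database, K = 64, 50 queries,
50 scored hits per search) are desk-scale choices that keep a full pipeline
rebuild in tens of seconds while exercising every stage at the workflow's
real constants (cap 1000, probe 10, page 50, expansion ≤ 300).
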