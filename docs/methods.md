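# Methods

This note documents the models implemented in `smilesim`, the choices
made where the design was genuinely open, and what the synthetic tests
do and do not demonstrate.

## Preprocessing

String kernels compare SMILES character by character, so atoms written
with two characters would otherwise contribute two spurious character
matches.  The collapsing table defaults to `{Cl→L, Br→R, Si→A, Se→Z}`;
the replacement characters were chosen to be outside the SMILES
organic-subset symbol set, and the constructor rejects any table whose
values collide with existing symbols.  The table is configurable and is
echoed into run metadata, because there is no community-standard
mapping.  Whitespace is stripped before any processing (spaces are not
legal SMILES tokens).  Canonicalization is *not* performed: inputs are
assumed to be canonical/unique SMILES produced by a cheminformatics
toolkit, and the CLI help says so.

Ring-digit zeroing (for the LINGO family) replaces every digit outside
square-bracket atom blocks with `0`; digits inside `[...]` (isotopes,
H-counts, charges) are untouched, and `%nn` two-digit closures become
`%00`.  This is a pure character transform — it preserves string
length, is idempotent, and raises on unbalanced brackets, the only
structural validity check the package performs.

## Whole-string kernels

Edit similarity, NLCS, NMCLCS₁, NMCLCSₙ and their CLCS combination are
standard dynamic programs.  Three details are worth recording:

- **CLCS weights are literally 0.33** each (not 1/3), so identical
  strings score 0.99.  Components are combined unrounded; any rounding
  happens only at display time.
- **NMCLCS₁ on equal-length strings** takes the larger of the two
  prefix directions, which keeps the function symmetric; for unequal
  lengths it is the longest prefix of the shorter string found
  contiguously in the longer, which is what the worked example implies
  (prefix `O` of `OC(O)=O` inside `CCCCC(O)=C4`).
- **The substring kernel's default is the raw inner product.**  Raw
  inner products grow with molecule size, so the kernel registry (the
  path used for similarity matrices and prediction) enables cosine
  normalization by default instead; the raw form remains the
  function-level default for direct calls.

Substring profiles contain O(n²) substrings; a length cap (2000
characters, far above typical drug SMILES of ≤ ~400) guards
pathological input.

## LINGO, TF and TF-IDF kernels

A LINGO is a q-character substring of the ring-zeroed SMILES; q = 4 by
default, with q ∈ {3,4,5} exposed for sweeps.  LINGOsim is the
per-term count Tanimoto averaged over the union of the two profiles'
unique LINGOs.

The TF and TF-IDF cosine kernels treat compounds as documents and
LINGOs as terms.  TF weight is `1 + log10(tf)`; IDF is `log10(N/df)`
with **no smoothing** — a term present in every compound genuinely gets
weight zero, which is the desired stop-word behavior.  Consequences
worth knowing: the TF-IDF self-similarity of a compound made entirely
of ubiquitous LINGOs is 0 (zero vector), and a single-document corpus
degenerates to all-zero vectors.  These degeneracies are tested, not
patched away.

The vocabulary is built over the **full compound set** of a data set by
default, matching the document-corpus framing of the kernel (all
compounds are known up front; no interaction labels are involved, so
this leaks nothing about test-fold *interactions*).  Scoring a compound
against a vocabulary that does not contain some of its LINGOs simply
drops the unseen terms (logged at debug level), which is what happens
if a caller restricts the vocabulary to training folds instead.
Vocabulary term order is the insertion order of first appearance over
the corpus, making vectors and reports reproducible byte for byte.

## SMILES fingerprints

The 34-symbol alphabet is not standardized in one canonical list; the
shipped default covers 15 atoms (C c N n O o S s P p F I Cl Br B), the
bonds `=` `#`, branches, brackets, charges, `H`, ring digits 1–9 and
`%`.  The 38D variant applies the documented edit exactly: drop `%`,
add `@`, `@@`, `.`, `\`, `/`.  Alphabets are plain-text config files
(one symbol per line), loadable via `--alphabet`, and the alphabet used
is echoed into outputs.  Fingerprints are computed on the **raw**
SMILES (before atom collapsing) so that chirality and directional-bond
tokens survive; tokenization is greedy, so `@@` never counts as two
`@`, and `Cl` never contributes a `C`.

City Block distance is turned into a similarity by `1/(1+CBD)` because
the predictor needs similarities in [0,1]; the transform is strictly
monotone in the distance, so AUC-based rankings are unaffected by its
particular shape.

## Similarity matrices and kernel repair

Pairwise matrices are computed on the upper triangle only and mirrored,
giving bit-exact symmetry and half the cost.  Similarity matrices are
repaired into valid kernels by symmetrizing and then adding the minimal
diagonal shift `max(0, ε − λ_min)` with ε = 1e-9: a diagonal shift
preserves every off-diagonal similarity exactly, unlike eigenvalue
clipping.  Composite kernels mix *similarities* (λ·S₂D + (1−λ)·S_f,
default λ = 0.5) before any PSD repair, so the mixed matrix is repaired
once as a whole.

## WNN-GIP

The GIP kernel is `exp(−γ‖yᵢ−yⱼ‖²)` with γ normalized by the mean
squared profile norm; the mean is taken over profiles with nonzero norm
so that all-zero rows (new drugs before imputation) do not deflate the
bandwidth.  WNN imputation ranks training drugs by descending chemical
similarity — ties broken by training order, which is logged and makes
runs deterministic (at the price that predictions are only
permutation-invariant when similarities are tie-free) — and sums
profiles with geometric weights `T^(r−1)`, clipping to [0,1].

Kronecker RLS is solved via the eigendecomposition identity
(O(n³+m³) instead of O(n³m³)); the explicit-Kronecker solver exists
only as a test oracle, where the two routes agree to ≤ 1e-8 on random
instances.  Hyperparameter defaults — `gamma_scale=1`, `alpha=0.5`,
`sigma=1`, `wnn_decay=0.7` — are the conventional values from the
WNN-GIP literature; none are asserted to be optimal and all are
config-exposed and recorded in run metadata.

## Evaluation

Cross-validation is performed **over drugs**: each fold's drugs are
treated as new compounds (adjacency rows hidden, profiles imputed), and
AUCs are computed over all hidden (drug, target) pairs of the fold —
positives are the held-out interactions, negatives the held-out
non-edges.  AUC-ROC is the Mann-Whitney statistic (ties credited ½);
AUC-PR is computed as step-interpolated average precision, avoiding the
optimistic linear interpolation of trapezoidal PR areas.  Repeat r of a
run with master seed s shuffles folds with seed s+r, so one integer
reproduces the entire experiment.  Standard deviations are reported
both over all folds and over repeat means, since the two summaries
answer different questions.  The paired t-test compares per-fold
metrics on matched partitions (same seed and layout); a zero-variance
nonzero difference is degenerate and is reported significant with a
warning rather than as a numeric artifact.

## Synthetic data

The generator plants k compound clusters: each cluster has a random
motif (6 characters by default) inserted into every member's SMILES,
drugs and targets are assigned to clusters round-robin, and edges are
drawn with probability 0.6 inside matched clusters and 0.05 otherwise —
the background rate mirrors the sparsity of real interaction networks,
while the planted blocks provide recoverable signal.  Target similarity
is block-structured (0.8 within / 0.2 across) with small symmetric
Gaussian noise.  Everything derives from `numpy.random.default_rng`
seeded from the spec, so identical specs give byte-identical output.

What this emulates: motif-driven chemical similarity aligned with
binding behavior, sparse adjacency, noisy target similarity.  What it
does not: realistic chemistry (the fragment grammar is a toy — balanced
branches, one ring level, optional stereo tokens), realistic similarity
distributions, hub drugs/targets, or correlated noise between
similarity and adjacency.  Passing the planted-signal tests therefore
shows the pipeline is *wired correctly* and can exploit genuine signal;
it says nothing about absolute performance on real benchmark data sets,
which additionally depends on downloaded interaction data, a 2D
similarity matrix and hyperparameter tuning.
`examples/benchmark_protocol.py` reproduces the full repeated-CV
protocol when those files are supplied.

Problem sizes in the test suite (30–60 drugs, 15–30 targets, 25 CV
folds) were chosen as the smallest sizes at which the planted signal is
statistically unambiguous; the whole suite runs in a few seconds.

## Numerical conventions

- Similarity values are kept at full precision internally; the
  truncating display convention of the worked examples (0.012987 shown
  as 0.012) is applied only when printing.
- Degenerate inputs: empty strings score 0 (similarity 1 only for the
  empty-vs-empty edit case, by identity convention, logged); empty
  LINGO profiles and zero vectors score 0 with a warning; single-class
  CV folds are skipped with a warning rather than fabricating an AUC.
- The eigendecomposition route of Kronecker RLS requires PSD kernels
  and refuses indefinite input with a pointer to `make_kernel`,
  instead of silently producing complex or unstable scores.
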