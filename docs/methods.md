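# Methods

## Problem and data model

Lysine crotonylation is detected experimentally as a set of (protein,
position) pairs. The package casts site prediction as binary
classification of fixed 29-residue windows centered on a candidate K
(14 residues of context per side; shortfalls at protein termini are padded
with `X`). Every lysine of an annotated protein becomes one sample; it is
positive exactly when its position appears in the site table. Negatives
are taken only from annotated proteins — unannotated proteins may simply
never have been measured, so treating their lysines as negatives would
inject label noise.

The residue alphabet is fixed as `ACDEFGHIKLMNPQRSTVWY` + `X` and
serialized into every artifact. `X` stands for absent sequence (and for
rare/ambiguous letters normalized at read time); it is a 21st symbol for
the encoders but belongs to no physicochemical group and never matches
anything in identity computations.

## Curation

*Deduplication.* Windows are clustered greedily at a 40% identity
threshold: samples are visited positives-first (then lexicographically, so
the representative set is deterministic and redundant positives displace
near-identical unannotated windows — the "potential false negative" case);
a window is dropped if it matches a retained representative at more than
`0.40 × 29` positions. Identity uses the full window length 29 as the
denominator. Clustering operates on the windows themselves rather than
whole proteins, which is the natural unit once windows are the samples;
note 40% identity over a 29-mer is a much stricter criterion than the same
percentage over full-length proteins.

*Splitting.* The train/test split is stratified by (species, label): each
stratum is shuffled with the split seed and `floor(ratio·n)` samples go to
the training side. The uniform floor rule is used everywhere; for a
3550-sample stratum at ratio 0.7 the product is exactly 2485, so the
split is 2485/1065. Cross-validation folds come from a seeded shuffle with
round-robin assignment, label-stratified by default (a flag disables
stratification, since published protocols often leave this unstated).

## Encodings

| scheme | shape | notes |
|---|---|---|
| `aac` | 1×21 | residue frequencies, sums to 1 |
| `egaac` | 1×5 | group proportions (GAVLMI / FYW / KRH / DE / STCPNQ); X counts toward no group, so the vector sums to (29−#X)/29 |
| `be` | 29×21 | one-hot; the network default |
| `we` | 29 ints | vocabulary IDs in [0,20]; a trainable 29×10 embedding lives inside the network |
| `aaindex` | 29×29 | 29 physicochemical indices per residue |
| `blosum62` | 29×21 | raw integer substitution-score rows; X uses the standard X row |

The physicochemical table ships as an editable TSV
(`kcrnet/data/aaindex_default.tsv`) holding 29 published residue scales
(Kyte–Doolittle hydropathy, Hopp–Woods hydrophilicity, Eisenberg
consensus, Janin buried fraction, and 25 further literature scales bundled
with Biopython). The precise selection of 29 indices is configuration,
not a constant of the method — published Kcr predictors inherit a
task-selected list that is not fully specified anywhere machine-readable —
so the default is a transparent, documented set with the same shape.
Each index is min-max scaled to [0,1] over the 20 real residues and the X
row is zero, so padding contributes nothing.

## Network

Input 29×21 (one-hot) feeds two parallel branches:

* conv branch: Conv1d(21→32, k5, s1, p2) → Conv1d(32→32, k5, s2, p2) →
  Conv1d(32→29, k5, s2, p2), ReLU and dropout 0.30 after each; positions
  29→29→15→8; flatten 232.
* recurrent branch: BiLSTM over the same input (64 hidden per direction →
  128 per position), dropout 0.90; 8-head scaled-dot-product
  self-attention on the 29×128 sequence, dropout 0.50; flatten 3712.

Concatenation gives the 3944-vector, then Linear 3944→128 + ReLU and
Linear 128→2 + softmax (class 1 = positive).

Derived/decided details:

* **Conv padding = 2 everywhere.** Padding is forced by the stated layer
  arithmetic: kernel 5 with strides (1,2,2) reproduces the published
  position counts 29→15→8 and the fused width 3944 only with padding 2 on
  all three layers (zero padding gives 25→11→4 and 3828). `shape_trace`
  validates this contract without building the network and rejects
  configs whose declared linear input disagrees with the computed flatten.
* **Attention is a bare MHSA block** — no residual connection, layer norm
  or positional encoding (none are part of the architecture description),
  and all 29 positions are kept (required to reach 3712 = 29·128).
* **Dropout 0.9 after the BiLSTM** is unusually aggressive but is the
  stated rate; it is the config default and freely overridable.
* **Softmax on the output layer**, with the focal loss consuming the
  positive-class probability; class index 1 = positive is fixed and
  documented since a two-output softmax ordering is otherwise ambiguous.
* Initialization is uniform fan-in (U(±1/√fan_in)) from a single seeded
  generator, so a model seed fully determines all parameters and dropout
  masks; bias/init schemes beyond that are framework-default territory and
  intentionally unexotic.

Variants for ablation/comparison reuse the same components:
`no_linear` (fused 3944 feeds the output layer directly), `no_cnn`
(attention branch only, 3712), `no_mhsa` (conv + BiLSTM, 3944),
`cnn_only` (conv branch only, 232), plus single-branch comparison nets
(`lstm`, `bilstm`, `cnn_generic`) and `cnn_we` (the conv stack over a
trainable 29×10 embedding of word IDs).

### Implementation

The networks run on a compact reverse-mode autodiff engine written on
NumPy (`kcrnet.nn`): ~20 tensor ops with hand-written backward passes
(including a strided 1-D convolution via sliding windows and a
gate-fused LSTM step), uniform fan-in init, inverted dropout and Adam.
Design choices that matter numerically: float32 compute by default
(float64 in the gradient-check tests); gradient buffers are allocated
once per tensor and written in place for slice gradients; every op's
gradient is verified against central finite differences in
`tests/test_autodiff.py`. A 10-epoch training run on 4,000 windows takes
on the order of a minute on one CPU core.

## Loss

Focal loss with α = 0.7, γ = 1 (defaults), mean-reduced over the batch.
Probabilities are clamped to [1e−7, 1−1e−7] before the log — a numerical
guard, not part of the loss definition; gradients are zeroed where the
clamp is active. γ = 0, α = 0.5 recovers half the standard cross-entropy
exactly, which the tests use as an oracle. Up-sampling positives and
down-sampling negatives are available as optional dataset transforms for
comparison; the loss is the default imbalance remedy.

## Evaluation

Sn, Sp, ACC, F1, MCC from the confusion table at the strict `score > 0.5`
rule (a score of exactly 0.5 is negative). Zero-denominator metrics are
reported as an explicit undefined marker (`None`/JSON `null`), never
silently 0, and are excluded metric-wise from aggregation. AUC is
computed twice — trapezoidal integration of the tie-grouped ROC sweep and
the tie-aware pairwise ranking probability via rank sums — and the two
must agree to 1e−12 (an internal consistency assertion). Aggregation
uses the sample (n−1) standard deviation; with a single value the sd is
undefined.

## Motif statistic

A two-class, pLogo-style enrichment table rather than a rendered logo:
for each offset −14..+14 (excluding the fixed center) and each of the 21
symbols, log-odds `ln((f+c)/(F+21c)) − ln((b+c)/(B+21c))` with
pseudo-count c = 0.5, plus a two-sided binomial p-value of the foreground
count under the background frequency. Background = negative windows (the
two-class logo convention), not proteome composition. P-values are raw;
the number of tested cells (28×21 = 588) is stated in every output row so
callers can apply their preferred multiplicity correction. This is a
ranking/significance statistic; it does not reproduce pLogo's
residue-height algorithm.

## Synthetic data generator

The generator emulates the statistical structure of plant non-histone Kcr
data so every pipeline stage is testable offline:

* 29-mer windows with a central K at positive fraction 0.21 (the curated
  corpus ratio 12,352 : 46,389), across five named species;
* negatives drawn i.i.d. per position from a background composition
  (uniform over the 20 residues by default, user-overridable);
* positives drawn from per-offset distributions = background ×
  (offset, residue) factors, renormalized.

Default factors plant the qualitative neighborhood pattern reported for
plant Kcr sites — D/E strongly over-represented immediately at ±1 and
mildly out to ±4, K over-represented across the flanks with a stronger
upstream bias, R depleted at −1 and P at +1:

| cells | factor |
|---|---|
| (±1, D), (±1, E) | 8.0 |
| (±2..±4, D/E) | 3.0 |
| (−14..−2, K) | 3.5 |
| (+2..+14, K) | 2.5 |
| (−1, R), (+1, P) | 0.1 |

The strengths are calibrated, once, against the discrimination level the
real task exhibits: under these defaults the Bayes-optimal classifier
(exact per-position log-likelihood ratio, evaluated by Monte-Carlo)
attains AUC ≈ 0.94, matching the upper range observed on real per-species
data, so a competent model has headroom to clear the 0.85 learnability
bar. Weaker settings in the same qualitative pattern (e.g. 3× at ±1 only)
cap the Bayes AUC near 0.72 and make that bar unreachable for any model —
the factors are generator parameters chosen for this calibration, not
measured biological quantities.

What the generator does **not** model: protein family structure and
homology (so deduplication is barely exercised by synthetic data —
dedicated tests plant exact redundancy instead), realistic amino-acid
composition (unless supplied), correlations between positions, and
species-specific motif differences (species labels are assigned
round-robin and carry no signal). Passing the synthetic learnability
tests therefore demonstrates that the architecture, loss and training
loop can extract a planted positional signal at realistic imbalance — not
that real-data performance numbers are reproduced. The protein-assembly
path (`generate`) re-draws the ±14 neighborhood of each planted site,
which can itself create or remove flanking lysines; the candidate-site
count at planting time is recorded in the truth file.

Two entry points: `generate` (whole proteins + site TSV + truth JSON,
exercising FASTA/annotation I/O) and `generate_peptide_table` (pre-cut
labeled windows for fast experiments). Identical seeds give byte-identical
outputs.

## Protocols and problem sizes

Cross-validation is 5-fold (stratified by default); independent testing
repeats training over consecutive seeds (10 by default) on a fixed split;
grid search is exhaustive over a user-supplied grid ranked by mean CV AUC
with first-wins tie-breaking. Per-species evaluation partitions a test
set by species; species-specific models train and test on single-species
slices.

The test suite runs the full model at 4,000 train / 1,000 test windows
and 10 epochs for the learnability check (held-out AUC ≥ 0.85), three
3-epoch null-generator runs for the chance control (mean AUC in
[0.45, 0.55]), and 2-epoch runs at 800/400 for the ablation harness;
structural and formula-level tests are exact. These sizes were chosen as
the smallest at which the respective properties are statistically stable.

## Known limitations

* The classical-baseline hyperparameters are library defaults with fixed
  seeds; published comparisons do not specify theirs, so absolute baseline
  numbers on real data will differ.
* The greedy dedup is exact O(n·reps) identity clustering — appropriate
  for fixed-length windows, but it does not reimplement CD-HIT's k-mer
  pre-filter and will be slow beyond ~10^5 windows.
* A 2-epoch network on small data can legitimately predict no positives;
  threshold metrics then carry undefined markers rather than zeros, which
  downstream aggregation must expect.
* `export_activations` provides the raw per-layer matrices (input 609,
  flatten 3944, linear 128) for external embedding tools; no
  dimensionality reduction or plotting is bundled.
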