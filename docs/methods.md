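# Methods

## Scope and problem statement

epinet predicts the CG methylation level of fixed-width genomic bins from
other binned epigenetic features (histone modifications, chromatin
accessibility, transcription), deliberately excluding DNA sequence so that
the fitted models reflect relationships *between* chromatin features. The
model is a regression, not a classifier: per-bin methylation is a fraction
in [0, 1], and performance is the Pearson correlation between actual and
predicted levels over held-out chromosomes.

## Data preparation

**Coordinate conventions.** bedGraph/BED intervals are 0-based half-open;
CpG-report positions are 1-based points (Bismark convention) and map to
interval space as `pos − 1`. CG methylation is treated strand-collapsed by
default; per-strand reports can be merged per site with
`tracks_io.collapse_strands` (opt-in, to avoid silent double counting).

**Binning.** Chromosomes are tiled from 0 in `bin_size` steps (1 kb
default; 50 kb for low-resolution transfer work is just a config value,
not a separate code path). The last bin of a chromosome may be shorter.

**Methylation targets.** A CG site is *informative* when its read coverage
lies in the closed interval [5, 100] — the bounds are inclusive on both
ends, reading "covered by 5–100 reads" as a closed interval. A bin's level
is the unweighted mean of its informative sites' per-site fractions; a
`pool_counts` flag switches to pooled read counts for users who prefer
coverage weighting. Bins with fewer than 5 informative sites are missing:
excluded from training and evaluation but retained for prediction export.

**Feature tracks.** Coverage records distribute their fragment counts over
overlapping bins in proportion to overlapping base pairs (mass-conserving;
verified against a base-pair-level brute force in the tests), then
normalize to FPKM = fragments / (bin kb × mapped reads in millions). The
caller supplies the mapped-read total, so deduplicated fragment counts and
raw read counts are both usable. A bin with no coverage gets raw 0, not
missing: coverage tracks cannot distinguish zero signal from unobserved,
and 0 is the conservative reading.

**Scaling.** Methylation percent is divided by 100. Each feature is mapped
linearly so its 95th percentile (computed per feature over the whole
dataset, linear-interpolation percentile) lands at 0.95, clipping at 1.0
above; an all-zero track scales to all zeros. Scaling anchors are returned
as `ScaleParams` so a second dataset can optionally be scaled with the
first dataset's anchors.

**Neighbor context.** The second input column per feature is the mean over
5 upstream and 5 downstream bins, excluding the bin itself and never
crossing chromosome boundaries; partial windows at chromosome edges use
the neighbors that exist, and a single-bin chromosome falls back to the
bin's own value (so no bin is discarded for lack of context). Neighbor
means are computed on scaled values by default; a `neighbor_from="raw"`
flag scales after averaging instead, for users who want the alternative
order.

## Network

Per bin, the N × 2 matrix `s` passes through: (1) 64 shared width-2
convolution filters, `X[f, i] = ReLU(Σ_k w[f,k] · s[i,k])` — the filter
weights carry no feature index, so each feature row is transformed
identically and permuting feature rows permutes the conv output rows
(tested exactly); (2) feature-major flattening to a 64N-vector Y (any
fixed order is equivalent up to a permutation of the dense weights; ours
is documented and frozen); (3) a 256-unit ReLU dense layer; (4) a 1-unit
ReLU output, so predictions are non-negative by construction. Predictions
are raw by default; clipping to [0, 1] is behind a flag.

**Initialization and optimization.** Glorot-uniform weights and zero
biases, except the output bias which starts at 0.1: with a ReLU output
head, a non-positive initial pre-activation for every input zeroes the
loss gradient (a dead network), and the small positive offset removes that
failure mode without affecting the converged fit. The optimizer is Adam
(learning rate 1e-3, β₁ = 0.9, β₂ = 0.999), batch size 100, mean-squared-
error loss. All randomness (init, epoch shuffling) derives from the seed
in `ModelSpec`; identical seeds give bit-identical runs within one build.

**Early stopping.** After each epoch the validation MSE *F* is computed on
the full validation set; training stops when *F* has not strictly improved
for 20 consecutive epochs (configurable) or at `max_epochs` (default 500,
a safety cap), and the best-epoch weights are restored. The stopping rule
is a standalone `EarlyStopping` object so its exact semantics — stop
exactly `patience` epochs after the last improvement; ties are not
improvements — are testable with stubbed loss sequences.

## Baseline and control

The linear baseline is ordinary least squares on the same flattened N × 2
inputs (least-norm solution with a warning when the design is rank
deficient), so any advantage of the network is attributable to
nonlinearity rather than input differences. The negative control permutes
a feature's bin values genome-wide (not within chromosomes — the strongest
null) with a seeded permutation; raw values are shuffled and then
rescaled, with the order exposed for the alternative.

## Feature-subset sweep

All 2ᴺ − 1 non-empty subsets are enumerated in a deterministic order (by
size, then lexicographically), each trains a freshly initialized model (no
warm starts, so comparisons are independent), and held-out r per subset is
recorded. The best-per-size table takes the maximum r per subset size,
ties broken toward the lexicographically first subset. Per-subset seeds
derive from a master seed via `SeedSequence` spawning. The record table is
written after each subset when a path is given, making an interrupted
sweep resumable. Enumeration is guarded at 16 features; larger feature
sets must pass an explicit subset list. Note that "all combinations" of 8
features is 255 subsets and of 5 features is 31 (= 2⁵ − 1); 63 arises for
6 features.

## Evaluation and transfer

Splits are by whole chromosome, so spatial autocorrelation cannot leak
between partitions; an empty validation set is allowed (with a warning)
for transfer-only application. Region-stratified evaluation assigns each
bin to a region class by its midpoint — unambiguous single-class
assignment even when annotations overlap a bin partially — and computes r
per class, returning a missing value for classes with fewer than 2 bins.

Transfer applies a trained model to another store with the same features
and bin size. The target's features are scaled with the *target* dataset's
own 95th-percentile anchors by default, because each dataset is normalized
to its own distribution during preprocessing before any model sees it;
`scale_from="source"` reuses the training anchors for users who prefer a
fixed mapping. Identity transfer (target = source) reproduces the
within-dataset predictions exactly, which the tests assert bit-level.

## Synthetic data generator

The generator emulates the statistical structure of binned chromatin
tracks, not chromatin biology: what matters for validating the inference
machinery is spatial autocorrelation, cross-feature correlation, a known
feature→methylation rule, and the CpG-level sampling noise of WGBS.

Each feature is a stationary AR(1) latent per chromosome (`z_t = ρ z_{t−1}
+ √(1−ρ²) ε_t`, default ρ = 0.8 — 1-kb chromatin marks decay over a few
kb), shifted and clipped to a non-negative raw signal `scale · max(z + 3,
0)`. The shift-and-clip (rather than exponentiation) keeps the emitted
track's lag-1 autocorrelation at ≈ ρ while clipping fewer than 0.2% of
bins. A feature may be tied to an earlier one with a target correlation r
on the latent scale, planting distractors for the sweep.

The methylation mean is `m = logistic(gain · (Σ αᵢ g(zᵢ) + ε))` with g the
configured crosstalk nonlinearity (identity, hard threshold at 0, or tanh
saturation), ε Gaussian with sd `noise_sd` (default 0.1 — enough to keep
r below 1 without hiding the signal), and gain 1.5 spreading levels over
most of [0, 1] as real methylomes do. Besides the direct means, the
generator emits a binomial CpG realization — 10 sites per bin at coverage
50 (within the 5–100 filter window), methylated reads ~ Binomial(50, m) —
so the depth and site filters are exercised end to end; the expected
binomial RMSE at these settings is ≈ 0.03, and a configurable fraction of
bins emits no sites to emulate unassayable regions. On-disk stores use the
exact external formats the I/O layer parses (genome sizes, bedGraph per
feature, CpG-report TSV) plus a JSON manifest and a ground-truth JSON (α,
causal subset, true means).

**What passing tests show and do not show.** The synthetic tracks have the
right correlation structure but not real marginal distributions, CpG
density variation, mappability artifacts, or copy-number effects; recovery
results on them validate the pipeline's correctness and sensitivity, not
expected performance on any particular organism or assay.

## Reference study conditions

The protocols in `epinet.experiments` fix the package's reference
conditions: 10⁴ 1-kb bins (five 2-Mb chromosomes) for single-feature
recovery with training capped at 150 epochs, and 6 × 10³ bins for the
sweep (patience 10, 60-epoch cap per subset — the planted problems
converge well before it), the thresholded-crosstalk comparison, and the
transfer runs. These sizes keep a full protocol suite around a minute on
one CPU while leaving every planted effect comfortably detectable.

## Known limitations

- Exact reproduction of any previously published network weights is not
  attempted: learning rate, optimizer and initialization are free choices
  here, and only seeded self-consistency is guaranteed.
- The printed bias dimensions in some descriptions of this architecture
  ("1 × 64N", "1 × 256") are dimensionally inconsistent with the stated
  layer outputs; this implementation uses the functionally consistent
  shapes (256-vector hidden bias, scalar output bias).
- FPKM totals are caller-supplied; the package does not decide between
  fragment and read counting.
- No GC-content, mappability or CpG-density correction; no BAM/FASTQ
  handling; bigWig input is out of scope (bedGraph only).
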