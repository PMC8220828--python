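# epinet

Predict genome-wide CG methylation of fixed-size genomic bins from other
binned epigenetic features — histone modifications, chromatin accessibility,
transcription — with a small convolutional regression network, and use the
fitted models to probe epigenetic crosstalk: which feature combinations
carry the information that shapes a methylome, how a model trained on
wildtype data extrapolates to a perturbed epigenome, and how well it
transfers across datasets.

The package is aimed at epigenomics groups who have binned coverage tracks
(ChIP-seq/CUT&RUN, ATAC/DNase, RNA-seq) and WGBS methylation calls for one
condition and want to ask counterfactual questions about another, without
using DNA sequence as an input.

## The model

The genome is tiled into 1-kb (or 50-kb) bins. For each bin, every feature
*i* contributes two scaled inputs: its own value *s*ᵢ₁ and the mean over the
10 nearby bins (5 upstream, 5 downstream) *s*ᵢ₂, giving an *N* × 2 matrix
*s*. Four layers map *s* to the bin's methylation level:

- convolution, 64 width-2 filters shared across features:
  *X*₍f i₎ = ReLU(Σₖ *w*₍f k₎ *s*₍i k₎)
- flatten to a 64 *N*-vector *Y* (feature-major)
- hidden dense layer: *Z* = ReLU(*W*⁽²⁾ *Y* + *b*⁽²⁾), 256 units
- output: *Ĉ* = ReLU(*W*⁽³⁾ *Z* + *b*⁽³⁾), a non-negative predicted level

Training minimizes the validation mean squared error
*F* = (1/V) Σᵥ (*C*ᵥ − *Ĉ*ᵥ)² with minibatch Adam (batch size 100),
stopping once *F* has not improved for 20 epochs and restoring the
best-epoch weights. Evaluation is chromosome-held-out (by default chr1
tests, chr2–3 validate, the rest train) via the Pearson correlation between
actual and predicted methylation.

Preprocessing follows the standard recipe: CG sites kept at 5–100 reads
coverage, bins kept with ≥ 5 informative sites, per-site methylation
fractions averaged per bin, feature FPKM values scaled to [0, 1] with the
95th percentile anchored at 0.95.

Around the model sit an exhaustive feature-subset sweep (all 2ᴺ − 1
combinations, best-per-size reporting), an ordinary-least-squares baseline
on identical inputs, a genome-wide shuffled-track negative control,
region-stratified evaluation (e.g. CpG islands vs gene bodies), transfer
application of a trained model to another dataset, and a synthetic-data
generator with planted crosstalk for end-to-end validation.

## Worked example

Train on a synthetic dataset in which a single autocorrelated feature
(named "H3K36me3" here) drives the methylation mean through a logistic
squash, then evaluate on the held-out chromosome:

```python
import numpy as np
from epinet import (FeatureDef, SyntheticConfig, simulate_store, SplitSpec,
                    split_bins, ModelSpec, train, predict, pearson,
                    fit_linear, predict_linear, shuffle_track, BinnedStore)

cfg = SyntheticConfig(
    chrom_sizes=tuple((f"chr{i}", 2_000_000) for i in range(1, 6)),
    bin_size=1000,
    features=(FeatureDef("H3K36me3", rho=0.8),),
    alpha=(("H3K36me3", 1.0),),
    noise_sd=0.1,
    seed=1,
)
store, truth = simulate_store(cfg)
matrix, targets, scale = store.prepare(("H3K36me3",))

split = SplitSpec(test_chroms=("chr1",), validation_chroms=("chr2", "chr3"))
tr, va, te = (idx[matrix.valid[idx]] for idx in split_bins(store.bins, split))

spec = ModelSpec(n_features=1, seed=1, max_epochs=150)
state, log = train(spec, matrix.data[tr], targets[tr],
                   matrix.data[va], targets[va], feature_names=("H3K36me3",))
r = pearson(targets[te], predict(state, matrix.data[te]))
print(f"held-out Pearson r = {r:.3f}  ({log.epochs_run} epochs, "
      f"best validation F = {log.best_val_loss:.4f})")

null_store = BinnedStore(bins=store.bins, methylation=store.methylation)
null_store.features["H3K36me3"] = shuffle_track(store.features["H3K36me3"], seed=2)
null_matrix, _, _ = null_store.prepare(("H3K36me3",))
print(f"shuffled control r = {pearson(targets[te], predict(state, null_matrix.data[te])):.3f}")

fit_idx = np.concatenate([tr, va])
linear = fit_linear(matrix.data[fit_idx], targets[fit_idx])
print(f"linear baseline r  = {pearson(targets[te], predict_linear(linear, matrix.data[te])):.3f}")
```

Output:

```
held-out Pearson r = 0.991  (150 epochs, best validation F = 0.0012)
shuffled control r = -0.002
linear baseline r  = 0.974
```

The model recovers the planted feature–methylation dependence almost
perfectly (r = 0.991); the same trained model fed a genome-wide permutation
of the feature shows no correlation (r ≈ 0), confirming the signal is not
an artifact of the marginal value distribution. The linear baseline is
close here because the planted rule is nearly monotone; on thresholded
crosstalk the gap widens (see `epinet.experiments.nonlinearity_experiment`).

A command-line interface mirrors the library: `epinet simulate`, `epinet
train`, `epinet evaluate` (with `--shuffle-feature NAME --seed S` for the
control), `epinet sweep`, and `epinet transfer`.

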