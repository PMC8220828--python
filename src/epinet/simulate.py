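"""Synthetic multi-feature epigenome datasets with known crosstalk structure.

The generator emulates the statistical shape of binned chromatin tracks —
spatially autocorrelated, optionally cross-correlated, non-negative signals
— and a methylation track that is a known function of a chosen feature
subset. It emits both direct per-bin methylation means and a binomial
CpG-site realization, so the depth and site filters of the binning stage
are exercised end-to-end, and it writes stores in the exact external
formats the I/O layer consumes.

Model per feature: a stationary AR(1) latent ``z`` per chromosome
(``z_t = rho * z_{t-1} + sqrt(1 - rho^2) * eps_t``) shifted and clipped to a
non-negative raw signal ``scale * max(z + 3, 0)``; the shift keeps the
lag-1 autocorrelation of the emitted track at ~rho. A feature may instead
be tied to a previously generated feature with target correlation r
(``z = r * z_other + sqrt(1 - r^2) * z_own``), giving planted distractors.

Methylation mean per bin: ``m = logistic(gain * (sum_i alpha_i * g(z_i) +
noise))`` where ``g`` is the configured crosstalk nonlinearity (identity,
threshold at 0, or tanh saturation) applied to the standardized feature
signal. CpG realization: ``n_sites`` sites per bin at fixed coverage with
Binomial(coverage, m) methylated reads; a configurable fraction of bins is
dropped to emulate unassayable regions.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .binning import (
    BinnedStore,
    FeatureTrack,
    GenomeBins,
    MethylationTrack,
    bin_methylation,
    compute_fpkm,
    make_bins,
)
from .tracks_io import (
    CpGRecord,
    GenomeAssembly,
    read_bedgraph,
    read_cpg_report,
    read_genome_sizes,
)

__all__ = [
    "FeatureDef",
    "SyntheticConfig",
    "generate_feature_track",
    "generate_methylation",
    "simulate_store",
    "make_dataset",
    "load_dataset",
]

_SHIFT = 3.0  # latent shift before clipping at 0; keeps clipping rare (~0.1%)


@dataclass(frozen=True)
class FeatureDef:
    """One synthetic feature: spatial autocorrelation ``rho``, marginal
    ``scale``, and an optional planted correlation with another feature."""

    name: str
    rho: float = 0.8
    scale: float = 1.0
    corr_with: str | None = None
    corr: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if not -1.0 <= self.corr <= 1.0:
            raise ValueError("corr must be in [-1, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``alpha`` holds the crosstalk weights (features with nonzero weight are
    the causal subset); ``nonlinearity`` is the per-feature transform g
    (none | threshold | saturating); ``noise_sd`` is latent noise before the
    squash; ``gain`` the logistic steepness. CpG emission uses ``n_sites``
    sites per bin at ``coverage`` reads each; ``missing_rate`` of bins emit
    no sites at all.
    """

    chrom_sizes: tuple[tuple[str, int], ...]
    bin_size: int = 1000
    features: tuple[FeatureDef, ...] = (FeatureDef("featA"),)
    alpha: tuple[tuple[str, float], ...] = (("featA", 1.0),)
    nonlinearity: str = "none"
    noise_sd: float = 0.1
    gain: float = 1.5
    missing_rate: float = 0.0
    n_sites: int = 10
    coverage: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nonlinearity not in ("none", "threshold", "saturating"):
            raise ValueError("nonlinearity must be none|threshold|saturating")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not any(a != 0 for _, a in self.alpha):
            raise ValueError("at least one nonzero alpha required")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def assembly(self) -> GenomeAssembly:
        return GenomeAssembly(
            tuple(n for n, _ in self.chrom_sizes),
            tuple(int(s) for _, s in self.chrom_sizes),
        )

    @property
    def causal_features(self) -> tuple[str, ...]:
        return tuple(n for n, a in self.alpha if a != 0)


def _ar1(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    z = np.empty(n)
    z[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(1.0 - rho * rho) if n > 1 else None
    for t in range(1, n):
        z[t] = rho * z[t - 1] + innov[t - 1]
    return z


def _latents(cfg: SyntheticConfig, bins: GenomeBins) -> dict[str, np.ndarray]:
    """Stationary latent z per feature, AR(1) within each chromosome, with
    planted cross-feature correlations applied on the latent scale."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0)))
    latents: dict[str, np.ndarray] = {}
    for feat in cfg.features:
        own = np.concatenate(
            [
                _ar1(rng, int(bins.chrom_offsets[ci + 1] - bins.chrom_offsets[ci]), feat.rho)
                for ci in range(len(bins.assembly.chrom_names))
            ]
        )
        if feat.corr_with is not None:
            if feat.corr_with not in latents:
                raise ValueError(
                    f"{feat.name}: corr_with {feat.corr_with!r} must be generated first"
                )
            r = feat.corr
            own = r * latents[feat.corr_with] + np.sqrt(1.0 - r * r) * own
        latents[feat.name] = own
    return latents


def generate_feature_track(
    cfg: SyntheticConfig, feature: str, latents: dict[str, np.ndarray] | None = None,
    bins: GenomeBins | None = None,
) -> FeatureTrack:
    """Non-negative raw track for one feature (seeded via the config)."""
    bins = bins or make_bins(cfg.assembly, cfg.bin_size)
    latents = latents if latents is not None else _latents(cfg, bins)
    feat = next(f for f in cfg.features if f.name == feature)
    raw = feat.scale * np.maximum(latents[feature] + _SHIFT, 0.0)
    return FeatureTrack(feature, raw)


def _crosstalk(z: np.ndarray, nonlinearity: str) -> np.ndarray:
    if nonlinearity == "none":
        return z
    if nonlinearity == "threshold":
        return (z > 0.0).astype(float)
    return np.tanh(z)


def generate_methylation(
    cfg: SyntheticConfig,
    latents: dict[str, np.ndarray],
    bins: GenomeBins,
) -> tuple[MethylationTrack, list[CpGRecord], np.ndarray]:
    """True per-bin methylation means, a binomial CpG-site realization, and
    the noiseless mean vector (generator ground truth)."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    lin = np.zeros(bins.n_bins)
    for name, a in cfg.alpha:
        lin += a * _crosstalk(latents[name], cfg.nonlinearity)
    clean = 1.0 / (1.0 + np.exp(-cfg.gain * lin))
    noisy_lin = lin + rng.normal(0.0, cfg.noise_sd, bins.n_bins) if cfg.noise_sd > 0 else lin
    m = 1.0 / (1.0 + np.exp(-cfg.gain * noisy_lin))

    missing = rng.random(bins.n_bins) < cfg.missing_rate
    level = np.where(missing, np.nan, m)
    n_informative = np.where(missing, 0, cfg.n_sites).astype(np.int64)

    records: list[CpGRecord] = []
    chrom_names = bins.assembly.chrom_names
    for idx in np.flatnonzero(~missing):
        chrom = chrom_names[bins.chrom_index[idx]]
        start, end = int(bins.starts[idx]), int(bins.ends[idx])
        width = end - start
        step = max(width // (cfg.n_sites + 1), 1)
        meth_counts = rng.binomial(cfg.coverage, m[idx], size=cfg.n_sites)
        for s in range(cfg.n_sites):
            pos1 = start + min((s + 1) * step, width - 1) + 1  # 1-based
            meth = int(meth_counts[s])
            records.append(CpGRecord(chrom, pos1, meth, cfg.coverage - meth))
    return MethylationTrack(level=level, n_informative=n_informative), records, clean


def simulate_store(
    cfg: SyntheticConfig, realize_cpgs: bool = True
) -> tuple[BinnedStore, dict]:
    """Build an in-memory binned store straight from the generator.

    With ``realize_cpgs`` the methylation track is re-derived from the
    binomial CpG realization through the standard depth/site filters (the
    path real data takes); otherwise the true means are used directly.
    Returns the store and a ground-truth dict (alpha, causal subset, true
    per-bin means).
    """
    bins = make_bins(cfg.assembly, cfg.bin_size)
    latents = _latents(cfg, bins)
    store = BinnedStore(bins=bins)
    for feat in cfg.features:
        store.features[feat.name] = generate_feature_track(cfg, feat.name, latents, bins)
    direct, cpgs, clean = generate_methylation(cfg, latents, bins)
    if realize_cpgs:
        store.methylation = bin_methylation(cpgs, bins)
    else:
        store.methylation = direct
    truth = {
        "alpha": {name: a for name, a in cfg.alpha},
        "causal_features": list(cfg.causal_features),
        "nonlinearity": cfg.nonlinearity,
        "true_mean": clean.tolist(),
    }
    return store, truth


def make_dataset(cfg: SyntheticConfig, outdir: str | Path, force: bool = False) -> Path:
    """Write a full on-disk store: genome sizes, one bedGraph per feature
    (per-bin fragment counts), a CpG report, a manifest and the ground
    truth JSON. Refuses an existing directory unless ``force``.
    """
    outdir = Path(outdir)
    if outdir.exists():
        if not force:
            raise FileExistsError(f"{outdir} exists; pass force=True to overwrite")
        shutil.rmtree(outdir)
    outdir.mkdir(parents=True)

    bins = make_bins(cfg.assembly, cfg.bin_size)
    latents = _latents(cfg, bins)
    with open(outdir / "genome.sizes", "w") as handle:
        for name, size in cfg.chrom_sizes:
            handle.write(f"{name}\t{size}\n")

    chrom_names = bins.assembly.chrom_names
    totals: dict[str, float] = {}
    for feat in cfg.features:
        track = generate_feature_track(cfg, feat.name, latents, bins)
        totals[feat.name] = 1e6  # fragment counts written as-is; FPKM = count/kb
        with open(outdir / f"{feat.name}.bedGraph", "w") as handle:
            for idx in range(bins.n_bins):
                if track.values[idx] <= 0:
                    continue
                handle.write(
                    f"{chrom_names[bins.chrom_index[idx]]}\t{bins.starts[idx]}\t"
                    f"{bins.ends[idx]}\t{track.values[idx]:.6f}\n"
                )

    _, cpgs, clean = generate_methylation(cfg, latents, bins)
    with open(outdir / "cpg_report.tsv", "w") as handle:
        for rec in cpgs:
            handle.write(f"{rec.chrom}\t{rec.pos}\t{rec.meth_reads}\t{rec.unmeth_reads}\n")

    manifest = {
        "bin_size": cfg.bin_size,
        "features": [f.name for f in cfg.features],
        "total_mapped_reads": totals,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    truth = {
        "alpha": {name: a for name, a in cfg.alpha},
        "causal_features": list(cfg.causal_features),
        "nonlinearity": cfg.nonlinearity,
        "true_mean": clean.tolist(),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth))
    return outdir


def load_dataset(directory: str | Path) -> BinnedStore:
    """Load a store written by :func:`make_dataset` through the standard
    I/O + binning pipeline (bedGraph -> FPKM, CpG report -> filtered track)."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    assembly = read_genome_sizes(directory / "genome.sizes")
    bins = make_bins(assembly, int(manifest["bin_size"]))
    store = BinnedStore(bins=bins)
    for name in manifest["features"]:
        records = read_bedgraph(directory / f"{name}.bedGraph", assembly)
        store.features[name] = compute_fpkm(
            records, bins, float(manifest["total_mapped_reads"][name]), name
        )
    cpgs = read_cpg_report(directory / "cpg_report.tsv", assembly)
    store.methylation = bin_methylation(cpgs, bins)
    return store
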