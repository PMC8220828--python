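"""Chromosome-held-out splits, Pearson evaluation, region stratification and
transfer application (train on one dataset, predict on another).

The canonical split holds chromosome 1 out as the test set, chromosomes 2
and 3 as the validation set, and trains on the remainder; any chromosome
assignment with disjoint sets is accepted. Performance is the Pearson
correlation between actual and predicted methylation over valid test bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .binning import BinnedStore, FeatureMatrix, GenomeBins, ScaleParams
from .model import ModelState, predict
from .tracks_io import RegionSet

__all__ = [
    "SplitSpec",
    "EvalReport",
    "split_bins",
    "pearson",
    "stratified_eval",
    "transfer_predict",
]


@dataclass(frozen=True)
class SplitSpec:
    """Chromosome-level partition: test and validation sets named, the
    remaining assembly chromosomes train."""

    test_chroms: tuple[str, ...]
    validation_chroms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        overlap = set(self.test_chroms) & set(self.validation_chroms)
        if overlap:
            raise ValueError(f"chromosomes in both test and validation: {sorted(overlap)}")


@dataclass
class EvalReport:
    """Evaluation outcome: overall r, optional per-region r, bin counts and
    the full prediction vector (NaN on bins without features)."""

    pearson_r: float | None
    n_bins: int
    predictions: np.ndarray
    region_r: dict[str, float | None] = field(default_factory=dict)


def split_bins(
    bins: GenomeBins, split: SplitSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition global bin indices into (train, validation, test) by
    chromosome. Every bin lands in exactly one partition."""
    names = bins.assembly.chrom_names
    for chrom in (*split.test_chroms, *split.validation_chroms):
        if chrom not in names:
            raise ValueError(f"split chromosome {chrom!r} not in assembly")
    if not split.validation_chroms:
        warnings.warn("empty validation set (transfer mode)", stacklevel=2)
    train_chroms = [
        c for c in names
        if c not in split.test_chroms and c not in split.validation_chroms
    ]
    to_idx = lambda chroms: np.flatnonzero(bins.chrom_mask(chroms))
    return to_idx(train_chroms), to_idx(split.validation_chroms), to_idx(split.test_chroms)


def pearson(actual: np.ndarray, predicted: np.ndarray) -> float | None:
    """Product-moment correlation; None (with a warning) when undefined
    (fewer than 2 pairs or a constant vector)."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("length mismatch")
    if actual.size < 2:
        warnings.warn("fewer than 2 pairs; correlation undefined", stacklevel=2)
        return None
    if np.ptp(actual) == 0 or np.ptp(predicted) == 0:
        warnings.warn("constant vector; correlation undefined", stacklevel=2)
        return None
    return float(stats.pearsonr(actual, predicted).statistic)


def _region_membership(
    bins: GenomeBins, region_sets: Sequence[RegionSet]
) -> dict[str, np.ndarray]:
    """Per-class boolean membership: a bin belongs to a class when its
    midpoint falls in one of the class's intervals."""
    mids = bins.midpoints()
    chrom_names = bins.assembly.chrom_names
    out: dict[str, np.ndarray] = {}
    for regions in region_sets:
        mask = np.zeros(bins.n_bins, dtype=bool)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in regions.intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in by_chrom.items():
            if chrom not in chrom_names:
                continue
            sl = bins.chrom_slice(chrom)
            m = mids[sl]
            ivals = sorted(ivals)
            starts = np.array([s for s, _ in ivals], dtype=float)
            ends = np.array([e for _, e in ivals], dtype=float)
            pos = np.searchsorted(starts, m, side="right") - 1
            inside = (pos >= 0) & (m < ends[np.clip(pos, 0, len(ends) - 1)])
            mask[sl] = inside
        out[regions.name] = mask
    return out


def stratified_eval(
    bins: GenomeBins,
    actual: np.ndarray,
    predicted: np.ndarray,
    valid: np.ndarray,
    region_sets: Sequence[RegionSet],
) -> dict[str, float | None]:
    """Pearson r per region class over the class's valid member bins.

    Classes with fewer than 2 usable bins get None with a warning.
    """
    membership = _region_membership(bins, region_sets)
    out: dict[str, float | None] = {}
    for name, mask in membership.items():
        use = mask & np.asarray(valid, dtype=bool)
        if use.sum() < 2:
            warnings.warn(f"region class {name!r} has <2 bins; r undefined", stacklevel=2)
            out[name] = None
            continue
        out[name] = pearson(actual[use], predicted[use])
    return out


def transfer_predict(
    state: ModelState,
    target_store: BinnedStore,
    feature_names: Sequence[str] | None = None,
    scale_from: str = "target",
    source_scale_params: ScaleParams | None = None,
    eval_indices: np.ndarray | None = None,
    clip: bool = False,
) -> EvalReport:
    """Apply a trained model to another dataset's feature tracks.

    By default (``scale_from="target"``) the target's features are scaled
    with the target dataset's own 95th-percentile anchors, mirroring the
    preprocessing each dataset receives before any model use;
    ``scale_from="source"`` reuses the training dataset's anchors
    (``source_scale_params`` required). Evaluates r against the target's
    actual methylation wherever it exists (optionally restricted to
    ``eval_indices``).
    """
    names = tuple(feature_names or state.feature_names or target_store.feature_names)
    missing = [n for n in names if n not in target_store.features]
    if missing:
        raise ValueError(f"target store lacks features: {missing}")
    if state.spec.n_features != len(names):
        raise ValueError(
            f"model expects {state.spec.n_features} features, got {len(names)}"
        )
    if scale_from == "target":
        matrix, targets, _ = target_store.prepare(names)
    elif scale_from == "source":
        if source_scale_params is None:
            raise ValueError("scale_from='source' requires source_scale_params")
        matrix, targets, _ = target_store.prepare(names, scale_params=source_scale_params)
    else:
        raise ValueError("scale_from must be 'target' or 'source'")
    preds = predict(state, matrix, clip=clip)
    use = matrix.valid.copy()
    if eval_indices is not None:
        restrict = np.zeros(len(use), dtype=bool)
        restrict[eval_indices] = True
        use &= restrict
    r = pearson(targets[use], preds[use]) if use.sum() >= 2 else None
    return EvalReport(pearson_r=r, n_bins=int(use.sum()), predictions=preds)
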