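"""Binning and input preparation.

Converts raw coverage and CpG records into the model's inputs: fixed-width
genome bins, a depth-filtered per-bin methylation track, FPKM feature
tracks scaled to [0, 1] with the 95th percentile anchored at 0.95, and
per-bin N x 2 feature matrices carrying each feature's own scaled value
next to the mean over its 10 nearby bins (5 upstream, 5 downstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tracks_io import CoverageRecord, CpGRecord, GenomeAssembly

__all__ = [
    "GenomeBins",
    "MethylationTrack",
    "FeatureTrack",
    "FeatureMatrix",
    "ScaleParams",
    "BinnedStore",
    "make_bins",
    "bin_methylation",
    "compute_fpkm",
    "scale_methylation",
    "scale_feature",
    "neighbor_mean",
    "assemble_matrix",
]


@dataclass(frozen=True)
class GenomeBins:
    """Fixed-width tiling of an assembly; the universal prediction unit.

    Bins tile each chromosome from 0 in steps of ``bin_size``; the last bin
    of a chromosome may be shorter. Bins carry a single global index that
    runs through chromosomes in assembly order.
    """

    assembly: GenomeAssembly
    bin_size: int
    chrom_index: np.ndarray  # int index into assembly.chrom_names, per bin
    starts: np.ndarray
    ends: np.ndarray
    chrom_offsets: np.ndarray  # first global bin index per chromosome, + total

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def coords(self, idx: int) -> tuple[str, int, int]:
        return (
            self.assembly.chrom_names[self.chrom_index[idx]],
            int(self.starts[idx]),
            int(self.ends[idx]),
        )

    def chrom_slice(self, chrom: str) -> slice:
        """Global-index slice of all bins on ``chrom``."""
        ci = self.assembly.chrom_names.index(chrom)
        return slice(int(self.chrom_offsets[ci]), int(self.chrom_offsets[ci + 1]))

    def chrom_mask(self, chroms: Iterable[str]) -> np.ndarray:
        mask = np.zeros(self.n_bins, dtype=bool)
        for chrom in chroms:
            mask[self.chrom_slice(chrom)] = True
        return mask

    def bin_of(self, chrom: str, position0: int) -> int:
        """Global bin index of a 0-based coordinate."""
        ci = self.assembly.chrom_names.index(chrom)
        if not (0 <= position0 < self.assembly.chrom_lengths[ci]):
            raise ValueError(f"position {position0} outside {chrom}")
        return int(self.chrom_offsets[ci]) + position0 // self.bin_size

    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0


def make_bins(assembly: GenomeAssembly, bin_size: int) -> GenomeBins:
    """Tile every chromosome into ``bin_size``-bp bins (last bin may be short)."""
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    chrom_index: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    offsets = [0]
    for ci, length in enumerate(assembly.chrom_lengths):
        n = -(-length // bin_size)  # ceil division
        s = np.arange(n, dtype=np.int64) * bin_size
        e = np.minimum(s + bin_size, length)
        chrom_index.append(np.full(n, ci, dtype=np.int32))
        starts.append(s)
        ends.append(e)
        offsets.append(offsets[-1] + n)
    return GenomeBins(
        assembly=assembly,
        bin_size=bin_size,
        chrom_index=np.concatenate(chrom_index),
        starts=np.concatenate(starts),
        ends=np.concatenate(ends),
        chrom_offsets=np.asarray(offsets, dtype=np.int64),
    )


@dataclass
class MethylationTrack:
    """Per-bin methylation level in [0, 1] (NaN where missing) and the
    count of informative CG sites backing each level."""

    level: np.ndarray
    n_informative: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.level)


@dataclass
class FeatureTrack:
    """Per-bin non-negative raw (FPKM-like) values for one feature."""

    feature_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError(f"negative values in feature {self.feature_name!r}")


@dataclass(frozen=True)
class ScaleParams:
    """Per-feature linear-scaling anchors: the raw value mapped to 0.95."""

    percentile_value: dict[str, float]
    percentile: float = 95.0
    anchor: float = 0.95


@dataclass
class FeatureMatrix:
    """Per-bin N x 2 scaled inputs: column 0 the bin's own scaled value,
    column 1 the scaled mean over its nearby bins."""

    feature_names: tuple[str, ...]
    data: np.ndarray  # (n_bins, N, 2), entries in [0, 1]
    valid: np.ndarray  # per-bin flag: has a usable methylation target

    @property
    def n_bins(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(tuple(names), self.data[:, idx, :], self.valid.copy())


def bin_methylation(
    cpgs: Iterable[CpGRecord],
    bins: GenomeBins,
    min_depth: int = 5,
    max_depth: int = 100,
    min_sites: int = 5,
    pool_counts: bool = False,
) -> MethylationTrack:
    """Aggregate CG sites into per-bin methylation levels.

    A site is informative when ``min_depth <= coverage <= max_depth`` (both
    ends inclusive). A bin's level is the unweighted mean of its informative
    sites' per-site fractions (``pool_counts=True`` pools read counts across
    sites instead); bins with fewer than ``min_sites`` informative sites are
    missing (NaN). Site position ``pos`` (1-based) maps to interval space as
    ``pos - 1``.
    """
    n = bins.n_bins
    n_informative = np.zeros(n, dtype=np.int64)
    level_sum = np.zeros(n, dtype=float)
    meth_sum = np.zeros(n, dtype=float)
    cov_sum = np.zeros(n, dtype=float)
    for rec in cpgs:
        cov = rec.meth_reads + rec.unmeth_reads
        if cov < min_depth or cov > max_depth:
            continue
        b = bins.bin_of(rec.chrom, rec.pos - 1)
        n_informative[b] += 1
        level_sum[b] += rec.meth_reads / cov
        meth_sum[b] += rec.meth_reads
        cov_sum[b] += cov
    level = np.full(n, np.nan)
    ok = n_informative >= min_sites
    if pool_counts:
        level[ok] = meth_sum[ok] / cov_sum[ok]
    else:
        level[ok] = level_sum[ok] / n_informative[ok]
    return MethylationTrack(level=level, n_informative=n_informative)


def compute_fpkm(
    records: Iterable[CoverageRecord],
    bins: GenomeBins,
    total_mapped_reads: float,
    feature_name: str = "feature",
) -> FeatureTrack:
    """Overlap-weighted fragment counting normalized to FPKM.

    Each record distributes its ``value`` (fragment count) across the bins
    it overlaps in proportion to the overlapping base pairs, so total
    fragment mass is conserved. FPKM = fragments / (bin length in kb x
    total mapped reads in millions).
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    counts = np.zeros(bins.n_bins, dtype=float)
    bs = bins.bin_size
    names = bins.assembly.chrom_names
    chrom_to_offset = {
        name: int(bins.chrom_offsets[i]) for i, name in enumerate(names)
    }
    for rec in records:
        offset = chrom_to_offset[rec.chrom]
        length = rec.end - rec.start
        first = rec.start // bs
        last = (rec.end - 1) // bs
        if first == last:
            counts[offset + first] += rec.value
            continue
        for b in range(first, last + 1):
            lo = max(rec.start, b * bs)
            hi = min(rec.end, (b + 1) * bs)
            counts[offset + b] += rec.value * (hi - lo) / length
    bin_kb = (bins.ends - bins.starts) / 1000.0
    millions = total_mapped_reads / 1e6
    return FeatureTrack(feature_name, counts / (bin_kb * millions))


def scale_methylation(level_percent: np.ndarray | float) -> np.ndarray | float:
    """Map percent methylation (0-100) onto [0, 1]."""
    arr = np.asarray(level_percent, dtype=float)
    finite = arr[np.isfinite(arr)]
    if np.any(finite < 0) or np.any(finite > 100):
        raise ValueError("methylation percent outside [0, 100]")
    out = arr / 100.0
    return float(out) if np.isscalar(level_percent) else out


def scale_feature(
    track: FeatureTrack,
    percentile: float = 95.0,
    anchor: float = 0.95,
    percentile_value: float | None = None,
) -> tuple[FeatureTrack, float]:
    """Linearly map raw values into [0, 1], anchoring the 95th percentile
    at 0.95; values beyond it clip at 1. Returns the scaled track and the
    anchor's raw value (for reuse when scaling a second dataset with the
    first's parameters). An all-zero track scales to all zeros.
    """
    values = track.values
    if values.size == 0:
        raise ValueError("empty track")
    p = (
        float(np.percentile(values, percentile))
        if percentile_value is None
        else float(percentile_value)
    )
    if p <= 0:
        scaled = np.zeros_like(values)
    else:
        scaled = np.clip(values * anchor / p, 0.0, 1.0)
    return FeatureTrack(track.feature_name, scaled), p


def neighbor_mean(
    values: np.ndarray,
    bins: GenomeBins,
    n_up: int = 5,
    n_down: int = 5,
) -> np.ndarray:
    """Mean over up to ``n_up`` upstream and ``n_down`` downstream bins,
    excluding the bin itself and never crossing a chromosome boundary.

    At chromosome edges the mean runs over however many neighbors exist; a
    single-bin chromosome falls back to the bin's own value.
    """
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for ci in range(len(bins.assembly.chrom_names)):
        lo, hi = int(bins.chrom_offsets[ci]), int(bins.chrom_offsets[ci + 1])
        v = values[lo:hi]
        n = len(v)
        if n == 1:
            out[lo:hi] = v
            continue
        csum = np.concatenate([[0.0], np.cumsum(v)])
        idx = np.arange(n)
        a = np.maximum(idx - n_up, 0)
        b = np.minimum(idx + n_down + 1, n)
        window_sum = csum[b] - csum[a] - v
        window_n = (b - a - 1).astype(float)
        out[lo:hi] = window_sum / window_n
    return out


def assemble_matrix(
    feature_tracks: Sequence[FeatureTrack],
    methylation: MethylationTrack,
    bins: GenomeBins,
    neighbor_means: Sequence[np.ndarray] | None = None,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Stack scaled tracks and their neighbor means into per-bin N x 2
    matrices; return them with the per-bin methylation targets.

    Bins with missing methylation are flagged invalid (excluded from
    training and evaluation) but keep feature rows so they remain
    predictable. If ``neighbor_means`` is omitted it is computed here from
    the given (scaled) tracks.
    """
    n = bins.n_bins
    for t in feature_tracks:
        if len(t.values) != n:
            raise ValueError(
                f"track {t.feature_name!r} has {len(t.values)} bins, expected {n}"
            )
    if len(methylation.level) != n:
        raise ValueError("methylation track on different bins")
    if neighbor_means is None:
        neighbor_means = [neighbor_mean(t.values, bins) for t in feature_tracks]
    data = np.stack(
        [
            np.stack([t.values, nm], axis=1)
            for t, nm in zip(feature_tracks, neighbor_means)
        ],
        axis=1,
    )
    names = tuple(t.feature_name for t in feature_tracks)
    matrix = FeatureMatrix(names, data, methylation.valid.copy())
    return matrix, methylation.level.copy()


@dataclass
class BinnedStore:
    """A binned dataset: raw feature tracks plus the methylation track on a
    shared bin frame. The unit the sweep, training and transfer code loads.
    """

    bins: GenomeBins
    features: dict[str, FeatureTrack] = field(default_factory=dict)
    methylation: MethylationTrack | None = None

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.features)

    def prepare(
        self,
        feature_names: Sequence[str] | None = None,
        scale_params: ScaleParams | None = None,
        neighbor_from: str = "scaled",
    ) -> tuple[FeatureMatrix, np.ndarray, ScaleParams]:
        """Scale features, add neighbor context and assemble model inputs.

        By default each feature is scaled to its own 95th percentile and the
        neighbor mean is taken over scaled values; passing ``scale_params``
        reuses another dataset's anchors (source-scaled transfer mode).
        """
        names = list(feature_names or self.feature_names)
        missing = [n for n in names if n not in self.features]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        if self.methylation is None:
            meth = MethylationTrack(
                level=np.full(self.bins.n_bins, np.nan),
                n_informative=np.zeros(self.bins.n_bins, dtype=np.int64),
            )
        else:
            meth = self.methylation
        scaled_tracks: list[FeatureTrack] = []
        anchors: dict[str, float] = {}
        for name in names:
            pv = scale_params.percentile_value[name] if scale_params else None
            scaled, p = scale_feature(self.features[name], percentile_value=pv)
            scaled_tracks.append(scaled)
            anchors[name] = p
        if neighbor_from == "scaled":
            nms = [neighbor_mean(t.values, self.bins) for t in scaled_tracks]
        elif neighbor_from == "raw":
            raw_nms = [
                neighbor_mean(self.features[n].values, self.bins) for n in names
            ]
            nms = []
            for name, nm in zip(names, raw_nms):
                p = anchors[name]
                nms.append(
                    np.zeros_like(nm) if p <= 0 else np.clip(nm * 0.95 / p, 0, 1)
                )
        else:
            raise ValueError("neighbor_from must be 'scaled' or 'raw'")
        matrix, targets = assemble_matrix(scaled_tracks, meth, self.bins, nms)
        return matrix, targets, ScaleParams(anchors)

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as a TSV: coords, one raw column per feature, then
        methylation level and informative-site count."""
        frame = pd.DataFrame(
            {
                "chrom": [
                    self.bins.assembly.chrom_names[ci] for ci in self.bins.chrom_index
                ],
                "start": self.bins.starts,
                "end": self.bins.ends,
            }
        )
        for name, track in self.features.items():
            frame[name] = track.values
        if self.methylation is not None:
            frame["methylation"] = self.methylation.level
            frame["n_informative"] = self.methylation.n_informative
        frame.to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path: str | Path, bins: GenomeBins) -> "BinnedStore":
        frame = pd.read_csv(path, sep="\t")
        if len(frame) != bins.n_bins:
            raise ValueError("TSV row count does not match bin frame")
        reserved = {"chrom", "start", "end", "methylation", "n_informative"}
        store = cls(bins=bins)
        for col in frame.columns:
            if col in reserved:
                continue
            store.features[col] = FeatureTrack(col, frame[col].to_numpy(float))
        if "methylation" in frame.columns:
            store.methylation = MethylationTrack(
                level=frame["methylation"].to_numpy(float),
                n_informative=frame["n_informative"].to_numpy(np.int64),
            )
        return store
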