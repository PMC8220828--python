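"""Track and annotation I/O: the genomic coordinate frame and the flat-file
formats the tool consumes and emits.

Conventions
-----------
* bedGraph / BED intervals are 0-based, half-open ``[start, end)``.
* CpG-report positions are 1-based points (Bismark convention); converting a
  site at position ``p`` into interval space uses ``p - 1``.
* CG methylation is treated strand-collapsed by default: records are taken
  as given. Callers that hold per-strand reports at adjacent positions can
  request per-site summing via :func:`collapse_strands`.
* Records on chromosomes absent from the assembly are skipped with a logged
  warning rather than raising, so a chr1-only fixture loads against a full
  assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeAssembly",
    "CoverageRecord",
    "CpGRecord",
    "RegionSet",
    "TrackParseError",
    "read_genome_sizes",
    "read_bedgraph",
    "read_cpg_report",
    "read_bed_regions",
    "write_bin_track",
    "collapse_strands",
]


class TrackParseError(ValueError):
    """A flat file violated its format contract; the message names the line."""


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered chromosome names and lengths; the universal coordinate frame.

    Ordering is stable and shared by every downstream binning and split
    operation, so two stores built from the same sizes file align bin-by-bin.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) == 0:
            raise TrackParseError("no chromosomes")
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise TrackParseError("duplicate chromosome names")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("names and lengths differ in length")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if length <= 0:
                raise TrackParseError(f"non-positive length for {name}")

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names


class CoverageRecord(NamedTuple):
    """One bedGraph interval carrying a non-negative coverage value."""

    chrom: str
    start: int
    end: int
    value: float


class CpGRecord(NamedTuple):
    """One CG site from a Bismark-style CpG report (1-based position)."""

    chrom: str
    pos: int
    meth_reads: int
    unmeth_reads: int

    @property
    def coverage(self) -> int:
        return self.meth_reads + self.unmeth_reads

    @property
    def level(self) -> float:
        """Fraction methylated; NaN-free only when coverage > 0."""
        cov = self.coverage
        return self.meth_reads / cov if cov > 0 else float("nan")


@dataclass
class RegionSet:
    """A named collection of (chrom, start, end) intervals, 0-based half-open."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def validate(self, assembly: GenomeAssembly) -> None:
        for chrom, start, end in self.intervals:
            if chrom not in assembly:
                raise ValueError(f"region on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= assembly.length_of(chrom)):
                raise ValueError(
                    f"region {chrom}:{start}-{end} outside chromosome bounds"
                )


def _tokens(line: str) -> list[str]:
    return line.split()


def read_genome_sizes(path: str | Path) -> GenomeAssembly:
    """Parse a two-column (name, length) genome sizes file, order preserved."""
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = _tokens(raw)
            if len(parts) != 2:
                raise TrackParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            name, length_str = parts
            try:
                length = int(length_str)
            except ValueError:
                raise TrackParseError(
                    f"{path}:{lineno}: non-integer length {length_str!r}"
                ) from None
            if name in names:
                raise TrackParseError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            if length <= 0:
                raise TrackParseError(f"{path}:{lineno}: non-positive length {length}")
            names.append(name)
            lengths.append(length)
    if not names:
        raise TrackParseError(f"{path}: no chromosomes")
    return GenomeAssembly(tuple(names), tuple(lengths))


def read_bedgraph(path: str | Path, assembly: GenomeAssembly) -> list[CoverageRecord]:
    """Read a 4-column bedGraph, validating coordinates against the assembly.

    Records on chromosomes not in the assembly are skipped (one warning per
    chromosome). Empty intervals and negative values are hard errors.
    """
    records: list[CoverageRecord] = []
    skipped: set[str] = set()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            stripped = raw.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            parts = _tokens(raw)
            if len(parts) != 4:
                raise TrackParseError(
                    f"{path}:{lineno}: expected 4 columns, got {len(parts)}"
                )
            chrom, start_s, end_s, value_s = parts
            try:
                start, end = int(start_s), int(end_s)
                value = float(value_s)
            except ValueError:
                raise TrackParseError(f"{path}:{lineno}: malformed record") from None
            if chrom not in assembly:
                if chrom not in skipped:
                    logger.warning("%s:%d: skipping unknown chromosome %r", path, lineno, chrom)
                    skipped.add(chrom)
                continue
            if start >= end:
                raise TrackParseError(
                    f"{path}:{lineno}: empty or inverted interval {start}-{end}"
                )
            if start < 0 or end > assembly.length_of(chrom):
                raise TrackParseError(
                    f"{path}:{lineno}: interval {start}-{end} outside {chrom}"
                )
            if value < 0:
                raise TrackParseError(f"{path}:{lineno}: negative value {value}")
            records.append(CoverageRecord(chrom, start, end, value))
    return records


def read_cpg_report(path: str | Path, assembly: GenomeAssembly) -> list[CpGRecord]:
    """Read a CpG report TSV (chrom, 1-based pos, meth count, unmeth count).

    All rows are returned; depth filtering is a separate, testable step in
    the binning module.
    """
    records: list[CpGRecord] = []
    skipped: set[str] = set()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = _tokens(raw)
            if len(parts) != 4:
                raise TrackParseError(
                    f"{path}:{lineno}: expected 4 columns, got {len(parts)}"
                )
            chrom, pos_s, meth_s, unmeth_s = parts
            try:
                pos, meth, unmeth = int(pos_s), int(meth_s), int(unmeth_s)
            except ValueError:
                raise TrackParseError(f"{path}:{lineno}: malformed record") from None
            if chrom not in assembly:
                if chrom not in skipped:
                    logger.warning("%s:%d: skipping unknown chromosome %r", path, lineno, chrom)
                    skipped.add(chrom)
                continue
            if meth < 0 or unmeth < 0:
                raise TrackParseError(f"{path}:{lineno}: negative read count")
            if not (1 <= pos <= assembly.length_of(chrom)):
                raise TrackParseError(f"{path}:{lineno}: position {pos} outside {chrom}")
            records.append(CpGRecord(chrom, pos, meth, unmeth))
    return records


def read_bed_regions(path: str | Path, assembly: GenomeAssembly, name: str | None = None) -> RegionSet:
    """Read a BED3(+) file into a :class:`RegionSet` (extra columns ignored)."""
    regions = RegionSet(name or Path(path).stem)
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            stripped = raw.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            parts = _tokens(raw)
            if len(parts) < 3:
                raise TrackParseError(f"{path}:{lineno}: expected >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if chrom not in assembly:
                logger.warning("%s:%d: skipping unknown chromosome %r", path, lineno, chrom)
                continue
            regions.intervals.append((chrom, start, end))
    regions.validate(assembly)
    return regions


def write_bin_track(bins, values: Sequence[float], path: str | Path) -> int:
    """Write one bedGraph line per bin with a finite value; missing bins
    (NaN/None) are omitted. Returns the number of lines written.

    ``bins`` is a :class:`epinet.binning.GenomeBins`.
    """
    import math

    if len(values) != bins.n_bins:
        raise ValueError(
            f"length mismatch: {len(values)} values for {bins.n_bins} bins"
        )
    n_written = 0
    with open(path, "w") as handle:
        for idx in range(bins.n_bins):
            value = values[idx]
            if value is None or (isinstance(value, float) and math.isnan(value)):
                continue
            chrom, start, end = bins.coords(idx)
            handle.write(f"{chrom}\t{start}\t{end}\t{value:.6f}\n")
            n_written += 1
    return n_written


def collapse_strands(records: Iterable[CpGRecord]) -> list[CpGRecord]:
    """Sum per-strand records at adjacent positions into one record per CpG.

    A record at position ``p+1`` is merged into a record at ``p`` on the same
    chromosome (the CG dinucleotide's two cytosines). Records are returned
    sorted by (chrom order of first appearance, position).
    """
    merged: dict[tuple[str, int], list[int]] = {}
    chrom_order: list[str] = []
    for rec in records:
        if rec.chrom not in chrom_order:
            chrom_order.append(rec.chrom)
        key = (rec.chrom, rec.pos - 1) if (rec.chrom, rec.pos - 1) in merged else (rec.chrom, rec.pos)
        if key not in merged:
            merged[key] = [0, 0]
        merged[key][0] += rec.meth_reads
        merged[key][1] += rec.unmeth_reads
    out = [
        CpGRecord(chrom, pos, meth, unmeth)
        for (chrom, pos), (meth, unmeth) in merged.items()
    ]
    out.sort(key=lambda r: (chrom_order.index(r.chrom), r.pos))
    return out
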