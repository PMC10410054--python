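"""Genome segmentation into candidate methylation regions.

Two region-discovery strategies are provided:

* fixed non-overlapping windows tiling each chromosome (step == size), the
  classic "running window" segmentation; and
* density-based clustering (DBSCAN) of observed CpG positions in one
  dimension, which groups CpGs separated by at most ``eps`` base pairs into
  clusters of at least ``min_pts`` sites, discarding isolated CpGs as noise.

Coordinates are 0-based half-open internally; the canonical region id
``chrom:start:end`` is 1-based inclusive, matching Bismark coverage files and
published clock definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "Region",
    "RegionSet",
    "OverlapReport",
    "make_windows",
    "dbscan_regions",
    "overlap_regions",
]


@dataclass(frozen=True, order=True)
class Region:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def id(self) -> str:
        """Canonical 1-based inclusive id, e.g. ``2:164167686:164169038``."""
        return f"{self.chrom}:{self.start + 1}:{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_id(cls, region_id: str) -> "Region":
        """Parse a 1-based inclusive ``chrom:start:end`` id."""
        parts = region_id.rsplit(":", 2)
        if len(parts) != 3:
            raise ParseError(f"malformed region id {region_id!r}")
        chrom, start_s, end_s = parts
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"malformed region id {region_id!r}") from exc
        if not chrom or start1 < 1 or start1 > end1:
            raise ParseError(
                f"region id {region_id!r}: need chrom and 1 <= start <= end"
            )
        return cls(chrom=chrom, start=start1 - 1, end=end1)

    @classmethod
    def from_1based_inclusive(cls, chrom: str, start1: int, end1: int) -> "Region":
        if start1 < 1 or start1 > end1:
            raise ValidationError(
                f"invalid 1-based interval {chrom}:{start1}:{end1}"
            )
        return cls(chrom=chrom, start=start1 - 1, end=end1)

    def overlap_bp(self, other: "Region") -> int:
        """Clipped intersection length with another region (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class RegionSet:
    """An ordered collection of regions plus discovery provenance.

    ``provenance`` records either ``{"window_size": bp}`` or
    ``{"eps": bp, "min_pts": n}`` (or free-form metadata for imported sets).
    Regions are kept sorted by (chrom, start).
    """

    regions: list[Region] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> Region:
        return self.regions[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.regions]

    def by_chrom(self) -> dict[str, list[Region]]:
        out: dict[str, list[Region]] = {}
        for r in self.regions:
            out.setdefault(r.chrom, []).append(r)
        return out

    @classmethod
    def from_ids(cls, ids: Iterable[str], provenance: dict | None = None) -> "RegionSet":
        return cls([Region.from_id(i) for i in ids], provenance or {})

    def to_bed(self, path) -> None:
        """Write as 3-column BED (0-based half-open)."""
        df = pd.DataFrame(
            [(r.chrom, r.start, r.end) for r in self.regions],
            columns=["chrom", "start", "end"],
        )
        df.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path, provenance: dict | None = None) -> "RegionSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        if df.shape[1] < 3:
            raise ParseError(f"{path}: BED needs at least 3 columns")
        regions = [
            Region(str(c), int(s), int(e))
            for c, s, e in zip(df[0], df[1], df[2])
        ]
        return cls(regions, provenance or {"source": str(path)})


def make_windows(chrom_sizes: Mapping[str, int], window_size: int) -> RegionSet:
    """Tile each chromosome with non-overlapping windows (step == size).

    A truncated final window is emitted when the chromosome length is not a
    multiple of ``window_size``, so every base belongs to exactly one window.
    """
    if window_size < 1:
        raise ValidationError(f"window_size must be >= 1, got {window_size}")
    regions: list[Region] = []
    for chrom, length in chrom_sizes.items():
        if length < 1:
            raise ValidationError(f"chromosome {chrom}: length {length} < 1")
        for start in range(0, length, window_size):
            regions.append(Region(str(chrom), start, min(start + window_size, length)))
    return RegionSet(regions, {"window_size": int(window_size)})


def _dbscan_1d(pos: np.ndarray, eps: int, min_pts: int) -> list[tuple[int, int]]:
    """Classic DBSCAN on sorted 1-D positions; returns (min, max) per cluster.

    A point is core when >= min_pts points (itself included) lie within eps.
    Core points chain into clusters when consecutive cores are <= eps apart
    (in one dimension chains of cores are exactly runs of close neighbours).
    Border (non-core) points within eps of a core join the cluster of the
    nearest core; exact ties go to the lower-coordinate cluster. Noise is
    discarded.
    """
    n = pos.size
    if n == 0:
        return []
    left = np.searchsorted(pos, pos - eps, side="left")
    right = np.searchsorted(pos, pos + eps, side="right")
    core = (right - left) >= min_pts
    core_idx = np.flatnonzero(core)
    if core_idx.size == 0:
        return []
    core_pos = pos[core_idx]
    # split core chain where the gap between consecutive cores exceeds eps
    breaks = np.flatnonzero(np.diff(core_pos) > eps)
    cluster_of_core = np.zeros(core_idx.size, dtype=np.int64)
    for b in breaks:
        cluster_of_core[b + 1:] += 1
    n_clusters = cluster_of_core[-1] + 1
    span_min = np.full(n_clusters, np.iinfo(np.int64).max, dtype=np.int64)
    span_max = np.full(n_clusters, np.iinfo(np.int64).min, dtype=np.int64)
    for cp, cl in zip(core_pos, cluster_of_core):
        span_min[cl] = min(span_min[cl], cp)
        span_max[cl] = max(span_max[cl], cp)
    # border assignment: nearest core, ties toward the lower-coordinate core
    noncore_idx = np.flatnonzero(~core)
    for i in noncore_idx:
        p = pos[i]
        j = np.searchsorted(core_pos, p)
        d_left = p - core_pos[j - 1] if j > 0 else None
        d_right = core_pos[j] - p if j < core_pos.size else None
        best = None
        if d_left is not None and d_left <= eps:
            best = cluster_of_core[j - 1]
        if d_right is not None and d_right <= eps:
            if best is None or (d_left is None or d_right < d_left):
                best = cluster_of_core[j]
        if best is not None:
            span_min[best] = min(span_min[best], p)
            span_max[best] = max(span_max[best], p)
    return [(int(a), int(b)) for a, b in zip(span_min, span_max)]


def dbscan_regions(
    cpg_positions: Mapping[str, Sequence[int]],
    eps: int,
    min_pts: int = 5,
) -> RegionSet:
    """Cluster CpG positions into regions with 1-D DBSCAN per chromosome.

    Parameters
    ----------
    cpg_positions
        Mapping chromosome -> strictly increasing 1-based CpG positions.
    eps
        Neighbourhood radius in base pairs.
    min_pts
        Minimum number of CpGs (the point itself included) within ``eps``
        for a core point; also the minimum cluster size. Default 5 CpGs,
        the standard minimum cluster size for this application.

    Each cluster becomes a region spanning its minimum to maximum member
    position (1-based inclusive); noise CpGs produce no region.
    """
    if eps < 1:
        raise ValidationError(f"eps must be >= 1, got {eps}")
    if min_pts < 1:
        raise ValidationError(f"min_pts must be >= 1, got {min_pts}")
    regions: list[Region] = []
    for chrom, positions in cpg_positions.items():
        pos = np.asarray(positions, dtype=np.int64)
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValidationError(
                f"chromosome {chrom}: positions must be sorted and unique"
            )
        for mn, mx in _dbscan_1d(pos, int(eps), int(min_pts)):
            regions.append(Region.from_1based_inclusive(str(chrom), mn, mx))
    return RegionSet(regions, {"eps": int(eps), "min_pts": int(min_pts)})


@dataclass
class OverlapReport:
    """All >=1 bp intersections between two region sets."""

    pairs: list[tuple[Region, Region, int]]

    @property
    def n_a(self) -> int:
        """Distinct first-set regions involved in at least one pair."""
        return len({a for a, _, _ in self.pairs})

    @property
    def n_b(self) -> int:
        return len({b for _, b, _ in self.pairs})

    def __len__(self) -> int:
        return len(self.pairs)


def overlap_regions(set_a: RegionSet, set_b: RegionSet) -> OverlapReport:
    """Report every pair of regions from the two sets sharing >= 1 bp.

    A region may appear in several pairs (one-to-many overlaps are common
    when windows straddle a cluster).
    """
    by_b = set_b.by_chrom()
    pairs: list[tuple[Region, Region, int]] = []
    for a in set_a:
        for b in by_b.get(a.chrom, ()):
            if b.start >= a.end:
                break
            ov = a.overlap_bp(b)
            if ov >= 1:
                pairs.append((a, b, ov))
    return OverlapReport(pairs)
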