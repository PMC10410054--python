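"""Chromatin-context annotation of clock regions.

Clock regions split into hypermethylating (positive weight: methylation
gains with age) and hypomethylating (negative weight) groups. This module
characterises the two groups by GC content, age gradient of methylation,
CpG-island overlap, and ChromHMM chromatin-state composition expressed as a
log2 fold change against the genomic background actually captured by RRBS
(500-bp tiles retaining at least one covered CpG).

Base-pair overlap between a region and a state interval is computed as the
clipped interval intersection; state intervals bordering a region by exactly
1 bp are discarded, and the "Repressed" state is merged into
"Heterochromatin" before proportions are formed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .covio import ClockModel
from .errors import ValidationError
from .quantitation import RegionMatrix
from .segmentation import Region, RegionSet

__all__ = [
    "AnnotationTrack",
    "ChromatinReport",
    "gc_content",
    "methylation_gradient",
    "cgi_overlap",
    "chromhmm_overlap_bp",
    "chromhmm_log2fc",
    "covered_background_tiles",
]

HETEROCHROMATIN_MERGE = {"Repressed": "Heterochromatin"}


@dataclass
class AnnotationTrack:
    """Labeled genomic intervals (ChromHMM states, CpG islands, ...)."""

    intervals: list[tuple[str, int, int, str]]  # chrom, start, end, label

    def __post_init__(self) -> None:
        for chrom, start, end, label in self.intervals:
            if start >= end:
                raise ValidationError(
                    f"annotation interval {chrom}:{start}-{end}: start >= end"
                )
            if not label:
                raise ValidationError(
                    f"annotation interval {chrom}:{start}-{end}: empty label"
                )
        self.intervals = sorted(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def label_set(self) -> set[str]:
        return {lab for _, _, _, lab in self.intervals}

    def by_chrom(self) -> dict[str, list[tuple[int, int, str]]]:
        out: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, label in self.intervals:
            out.setdefault(chrom, []).append((start, end, label))
        return out

    def relabel(self, mapping: Mapping[str, str]) -> "AnnotationTrack":
        return AnnotationTrack([
            (c, s, e, mapping.get(lab, lab))
            for c, s, e, lab in self.intervals
        ])

    @classmethod
    def from_bed(cls, path, label: str | None = None,
                 chrom_aliases: Mapping[str, str] | None = None) -> "AnnotationTrack":
        """Load a BED / ChromHMM dense BED (label from column 4).

        With ``label`` given, every interval gets that label (CGI tracks
        often have no name column). ``chrom_aliases`` maps track chromosome
        names onto the cov-file naming scheme (e.g. ``{"chr1": "1"}``).
        """
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         dtype={0: str})
        aliases = chrom_aliases or {}
        intervals = []
        for _, row in df.iterrows():
            chrom = aliases.get(str(row[0]), str(row[0]))
            lab = label if label is not None else str(row[3])
            intervals.append((chrom, int(row[1]), int(row[2]), lab))
        return cls(intervals)


def gc_content(region: Region, genome) -> float:
    """Percent G+C of a region's sequence.

    ``genome`` is a pyfaidx.Fasta (or any mapping of chromosome name to a
    sliceable sequence). Ambiguous bases count toward the length but not
    toward G+C, and the computation is strand-symmetric by construction.
    """
    try:
        seq = str(genome[region.chrom][region.start:region.end]).upper()
    except KeyError as exc:
        raise ValidationError(
            f"chromosome {region.chrom} absent from genome"
        ) from exc
    if len(seq) != region.length:
        raise ValidationError(
            f"region {region.id} extends beyond chromosome end"
        )
    gc = seq.count("G") + seq.count("C")
    return 100.0 * gc / region.length


def methylation_gradient(matrix: RegionMatrix, min_points: int = 3) -> dict[str, float]:
    """Per-region OLS slope of methylation on age (beta per month).

    Missing entries are excluded pairwise; regions with fewer than
    ``min_points`` usable samples, or without at least two distinct ages,
    are omitted from the result.
    """
    ages = matrix.ages.to_numpy(dtype=float)
    slopes: dict[str, float] = {}
    for rid in matrix.region_ids:
        y = matrix.values[rid].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < min_points or np.unique(ages[ok]).size < 2:
            continue
        slope, _ = np.polyfit(ages[ok], y[ok], 1)
        slopes[rid] = float(slope)
    return slopes


def _split_by_sign(clock: ClockModel, regions: RegionSet):
    lookup = {r.id: r for r in regions}
    hyper, hypo = [], []
    for term, w in clock.terms.items():
        if term not in lookup:
            raise ValidationError(f"clock term {term} not in region set")
        if w == 0:
            raise ValidationError(f"region {term} has coefficient 0; unsigned")
        (hyper if w > 0 else hypo).append(lookup[term])
    return hyper, hypo


def cgi_overlap(clock: ClockModel, regions: RegionSet, cgi: AnnotationTrack):
    """Count hyper-/hypomethylating clock regions overlapping >= 1 CGI.

    Returns ``(n_hyper, n_hypo, per_region)`` where per_region maps region
    id to the list of overlapping CGI intervals (a region overlapping
    several CGIs still counts once).
    """
    hyper, hypo = _split_by_sign(clock, regions)
    track = cgi.by_chrom()
    per_region: dict[str, list[tuple[int, int]]] = {}

    def hits(region: Region) -> list[tuple[int, int]]:
        found = []
        for start, end, _ in track.get(region.chrom, ()):
            if start < region.end and end > region.start:
                found.append((start, end))
        return found

    n_hyper = n_hypo = 0
    for group, counter in ((hyper, "hyper"), (hypo, "hypo")):
        for region in group:
            h = hits(region)
            per_region[region.id] = h
            if h:
                if counter == "hyper":
                    n_hyper += 1
                else:
                    n_hypo += 1
    return n_hyper, n_hypo, per_region


def chromhmm_overlap_bp(
    regions: RegionSet | Sequence[Region], track: AnnotationTrack
) -> pd.DataFrame:
    """Base pairs of each chromatin state inside each region.

    Clipped interval intersection per (region, state interval) pair; pairs
    sharing exactly 1 bp are treated as borders and discarded. Columns:
    region_id, state, bp.
    """
    by_chrom = track.by_chrom()
    rows = []
    for region in regions:
        for start, end, label in by_chrom.get(region.chrom, ()):
            ov = min(region.end, end) - max(region.start, start)
            if ov <= 0 or ov == 1:
                continue
            rows.append({"region_id": region.id, "state": label, "bp": ov})
    df = pd.DataFrame(rows, columns=["region_id", "state", "bp"])
    return df.groupby(["region_id", "state"], as_index=False)["bp"].sum()


@dataclass
class ChromatinReport:
    """Chromatin-state composition of clock regions vs genomic background.

    ``table`` columns: state, group (hyper/hypo), bp, proportion_pct,
    genomic_pct, log2fc. Proportions are percentages of the group's total
    region bp (background: of total background-overlapping state bp).
    States absent from a group are reported with proportion 0 and, because
    log2(0) is undefined, a log2 fold change substituted with 0.
    """

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def covered_background_tiles(
    cpg_positions: Mapping[str, Sequence[int]],
    chrom_sizes: Mapping[str, int],
    tile_size: int = 500,
) -> RegionSet:
    """Fixed tiles retaining only those containing >= 1 covered CpG.

    The RRBS-captured genomic background: 500-bp windows with step == size,
    keeping tiles where at least one (1-based) CpG position falls.
    """
    regions = []
    for chrom, length in chrom_sizes.items():
        pos = np.asarray(cpg_positions.get(chrom, ()), dtype=np.int64)
        for start in range(0, length, tile_size):
            end = min(start + tile_size, length)
            lo = np.searchsorted(pos, start + 1, side="left")
            hi = np.searchsorted(pos, end, side="right")
            if hi > lo:
                regions.append(Region(str(chrom), start, end))
    return RegionSet(regions, {"tile_size": tile_size, "covered_only": True})


def chromhmm_log2fc(
    clock: ClockModel,
    regions: RegionSet,
    track: AnnotationTrack,
    background: RegionSet,
) -> ChromatinReport:
    """Chromatin-state enrichment of clock regions over the RRBS background.

    Per state and per group (hyper/hypomethylating), the proportion is
    100 x (state bp within the group's regions) / (total bp of the group's
    regions). The genomic proportion is 100 x (state bp within background
    tiles) / (total state bp overlapping any background tile). The report
    is log2(group proportion / genomic proportion) after merging Repressed
    into Heterochromatin; zero proportions on either side yield a reported
    log2 fold change of 0.
    """
    if len(background) == 0:
        raise ValidationError("background region set is empty")
    merged_track = track.relabel(HETEROCHROMATIN_MERGE)
    hyper, hypo = _split_by_sign(clock, regions)

    bg_overlap = chromhmm_overlap_bp(background, merged_track)
    bg_state_bp = bg_overlap.groupby("state")["bp"].sum()
    bg_total = float(bg_state_bp.sum())
    if bg_total == 0:
        raise ValidationError("no chromatin annotation overlaps the background")
    genomic_pct = 100.0 * bg_state_bp / bg_total

    states = sorted(set(merged_track.label_set) | set(bg_state_bp.index))
    rows = []
    for group_name, group_regions in (("hyper", hyper), ("hypo", hypo)):
        group_bp = sum(r.length for r in group_regions)
        ov = chromhmm_overlap_bp(group_regions, merged_track)
        state_bp = ov.groupby("state")["bp"].sum() if len(ov) else pd.Series(dtype=float)
        for state in states:
            bp = float(state_bp.get(state, 0.0))
            prop = 100.0 * bp / group_bp if group_bp else 0.0
            gp = float(genomic_pct.get(state, 0.0))
            if prop > 0 and gp > 0:
                l2fc = float(np.log2(prop / gp))
            else:
                l2fc = 0.0  # log2 of 0 rendered as 0 for reporting
            rows.append({
                "state": state,
                "group": group_name,
                "bp": bp,
                "proportion_pct": prop,
                "genomic_pct": gp,
                "log2fc": l2fc,
            })
    return ChromatinReport(pd.DataFrame(rows))
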