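"""Coverage filtering and region-level methylation quantitation.

The regional methylation value is the *unweighted mean of per-site beta
values* over the covered CpGs inside a region — deliberately not the pooled
read ratio ``sum(meth) / sum(total)``, which would let a few deeply covered
sites dominate the region. A region with no covered CpG in a sample is
MISSING (NaN), never zero: zero-substitution is a prediction-time decision
and lives in the clock module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .covio import CpGSiteRecord, MethylationSample
from .errors import ValidationError
from .segmentation import Region, RegionSet

__all__ = [
    "RegionMatrix",
    "site_beta",
    "filter_low_coverage",
    "region_methylation",
    "build_region_matrix",
]


def site_beta(meth_reads: int, unmeth_reads: int) -> float:
    """Per-site methylation fraction meth / (meth + unmeth)."""
    total = meth_reads + unmeth_reads
    if meth_reads < 0 or unmeth_reads < 0 or total < 1:
        raise ValidationError(
            f"need non-negative counts with >= 1 total read, "
            f"got ({meth_reads}, {unmeth_reads})"
        )
    return meth_reads / total


def filter_low_coverage(
    sample: MethylationSample, min_reads: int = 5
) -> MethylationSample:
    """Drop CpGs with fewer than ``min_reads`` total reads.

    The standard pre-quantitation filter; 5 reads is the conventional
    minimum for a usable beta estimate in RRBS.
    """
    if min_reads < 1:
        raise ValidationError(f"min_reads must be >= 1, got {min_reads}")
    kept = [r for r in sample.sites.values() if r.total_reads >= min_reads]
    return MethylationSample(sample.meta, kept)


def region_methylation(sample: MethylationSample, region: Region) -> float:
    """Mean per-site beta over covered CpGs in ``region``; NaN if none.

    A CpG at 1-based position p is a member iff region.start <= p-1 <
    region.end. The sample should already be coverage-filtered.
    """
    arrays = sample.arrays_by_chrom().get(region.chrom)
    if arrays is None:
        return float("nan")
    pos, betas, _ = arrays
    lo = np.searchsorted(pos, region.start + 1, side="left")
    hi = np.searchsorted(pos, region.end, side="right")
    if hi <= lo:
        return float("nan")
    return float(betas[lo:hi].mean())


@dataclass
class RegionMatrix:
    """Samples x regions mean-methylation matrix with explicit missingness.

    ``values`` is a pandas DataFrame (rows = samples, columns = regions,
    NaN = no covered CpG); ``ages`` is aligned to the rows; ``cpg_counts``
    carries the number of covered CpGs behind each entry.
    """

    values: pd.DataFrame
    ages: pd.Series
    cpg_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.ages.index):
            raise ValidationError("ages index does not match sample rows")
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("beta values must lie in [0, 1]")
        if not np.all(np.isfinite(self.ages.to_numpy(dtype=float))):
            raise ValidationError("ages must be finite")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def region_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, sample_ids: Sequence[str]) -> "RegionMatrix":
        counts = (
            self.cpg_counts.loc[list(sample_ids)]
            if self.cpg_counts is not None else None
        )
        return RegionMatrix(
            self.values.loc[list(sample_ids)],
            self.ages.loc[list(sample_ids)],
            counts,
        )

    def drop_missing_regions(self) -> "RegionMatrix":
        """Drop region columns containing any NaN (training-time rule)."""
        keep = self.values.columns[~self.values.isna().any(axis=0)]
        counts = self.cpg_counts[keep] if self.cpg_counts is not None else None
        return RegionMatrix(self.values[keep], self.ages, counts)

    def to_tsv(self, path) -> None:
        """Write as TSV: sample_id, age_months, then one column per region.

        Missing entries are encoded as ``NaN``.
        """
        out = self.values.copy()
        out.insert(0, "age_months", self.ages)
        out.to_csv(path, sep="\t", index_label="sample_id", na_rep="NaN")

    @classmethod
    def from_tsv(cls, path) -> "RegionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        df.index = df.index.astype(str)
        df.index.name = None
        ages = df.pop("age_months").astype(float)
        return cls(df.astype(float), ages)


def build_region_matrix(
    samples: Iterable[MethylationSample], regions: RegionSet
) -> RegionMatrix:
    """Assemble the samples x regions matrix of mean regional methylation.

    All samples are assumed to have been coverage-filtered with the same
    threshold. NaN marks regions with zero covered CpGs in a sample; the
    per-entry covered-CpG counts are retained as side metadata.
    """
    samples = list(samples)
    ids = [s.meta.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids in cohort")
    region_list = list(regions)
    vals = np.full((len(samples), len(region_list)), np.nan)
    counts = np.zeros((len(samples), len(region_list)), dtype=np.int64)
    by_chrom: dict[str, list[tuple[int, Region]]] = {}
    for j, r in enumerate(region_list):
        by_chrom.setdefault(r.chrom, []).append((j, r))
    for i, sample in enumerate(samples):
        arrays = sample.arrays_by_chrom()
        for chrom, pairs in by_chrom.items():
            if chrom not in arrays:
                continue
            pos, betas, _ = arrays[chrom]
            for j, r in pairs:
                lo = np.searchsorted(pos, r.start + 1, side="left")
                hi = np.searchsorted(pos, r.end, side="right")
                if hi > lo:
                    vals[i, j] = betas[lo:hi].mean()
                    counts[i, j] = hi - lo
    cols = [r.id for r in region_list]
    ages = pd.Series([s.meta.age_months for s in samples], index=ids,
                     name="age_months")
    return RegionMatrix(
        pd.DataFrame(vals, index=ids, columns=cols),
        ages,
        pd.DataFrame(counts, index=ids, columns=cols),
    )
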