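"""I/O for Bismark coverage files, sample metadata and clock definitions.

Coordinate conventions
----------------------
Bismark ``.cov`` files and region ids (``chrom:start:end``) are 1-based
inclusive, as produced by ``bismark2bedGraph`` and as printed in published
clock tables. Internally every interval is 0-based half-open; conversion
happens only at the I/O boundary. Chromosome names are kept verbatim (no
``chr`` prefix normalisation); pass an alias map to annotation joins when
tracks use a different naming scheme.

The percentage-methylation column of a cov file is never trusted: the beta
value is always recomputed from the methylated/unmethylated read counts, so
rounding in upstream tools cannot drift through the pipeline.
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import ParseError, ValidationError
from .segmentation import Region

__all__ = [
    "CpGSiteRecord",
    "SampleMeta",
    "MethylationSample",
    "ClockModel",
    "read_bismark_cov",
    "write_bismark_cov",
    "convert_age_weeks_to_months",
    "parse_region_id",
    "read_clock_definition",
    "write_clock_definition",
    "read_sample_metadata",
    "write_sample_metadata",
]


@dataclass(frozen=True)
class CpGSiteRecord:
    """One CpG site in one sample: 1-based position plus read counts."""

    chrom: str
    pos: int
    meth_reads: int
    unmeth_reads: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.meth_reads < 0 or self.unmeth_reads < 0:
            raise ValidationError(
                f"negative read count at {self.chrom}:{self.pos}"
            )
        if self.meth_reads + self.unmeth_reads < 1:
            raise ValidationError(
                f"site {self.chrom}:{self.pos} has zero total reads"
            )

    @property
    def total_reads(self) -> int:
        return self.meth_reads + self.unmeth_reads

    @property
    def beta(self) -> float:
        """Fraction of methylated reads, recomputed from counts."""
        return self.meth_reads / self.total_reads


@dataclass
class SampleMeta:
    sample_id: str
    age_months: float
    group: str | None = None
    tissue: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.age_months) or self.age_months < 0:
            raise ValidationError(
                f"{self.sample_id}: age_months must be finite and >= 0, "
                f"got {self.age_months}"
            )


class MethylationSample:
    """All CpG records of one sample, keyed by (chrom, pos)."""

    def __init__(self, meta: SampleMeta, sites: Iterable[CpGSiteRecord] = ()):
        self.meta = meta
        self.sites: dict[tuple[str, int], CpGSiteRecord] = {}
        for rec in sites:
            self.add_site(rec)
        self._arrays: dict | None = None

    def add_site(self, rec: CpGSiteRecord) -> None:
        key = (rec.chrom, rec.pos)
        if key in self.sites:
            raise ValidationError(
                f"{self.meta.sample_id}: duplicate site {rec.chrom}:{rec.pos}"
            )
        self.sites[key] = rec
        self._arrays = None

    @property
    def total_reads(self) -> int:
        return sum(r.total_reads for r in self.sites.values())

    def __len__(self) -> int:
        return len(self.sites)

    def arrays_by_chrom(self) -> dict[str, tuple]:
        """Per-chromosome sorted (positions, betas, read totals) arrays.

        Cached; invalidated when sites are added.
        """
        import numpy as np

        if self._arrays is None:
            grouped: dict[str, list[CpGSiteRecord]] = {}
            for rec in self.sites.values():
                grouped.setdefault(rec.chrom, []).append(rec)
            out = {}
            for chrom, recs in grouped.items():
                recs.sort(key=lambda r: r.pos)
                out[chrom] = (
                    np.array([r.pos for r in recs], dtype=np.int64),
                    np.array([r.beta for r in recs], dtype=float),
                    np.array([r.total_reads for r in recs], dtype=np.int64),
                )
            self._arrays = out
        return self._arrays


@dataclass
class ClockModel:
    """A linear epigenetic age clock: intercept plus region weights.

    Predicted age is ``intercept + sum_m weight_m * beta_m`` where ``beta_m``
    is the mean methylation of region ``m`` in the sample being predicted.
    ``terms`` may be empty for an intercept-only model (the LASSO limit under
    a very large penalty), but such a model cannot be serialised.
    """

    intercept: float
    terms: dict[str, float] = field(default_factory=dict)
    feature_kind: str = "region"
    provenance: str = ""

    def __post_init__(self) -> None:
        for region_id in self.terms:
            parse_region_id(region_id)  # raises ParseError on bad ids

    @property
    def n_positive(self) -> int:
        return sum(1 for w in self.terms.values() if w > 0)

    @property
    def n_negative(self) -> int:
        return sum(1 for w in self.terms.values() if w < 0)


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_bismark_cov(path, meta: SampleMeta) -> MethylationSample:
    """Read a Bismark coverage file into a :class:`MethylationSample`.

    Expects six whitespace/tab-delimited columns per row: chromosome, start,
    end, percent methylation, methylated reads, unmethylated reads, with
    start == end (each row one CpG). The percentage column is ignored; beta
    is recomputed from the counts.
    """
    sample = MethylationSample(meta)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                meth, unmeth = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start != end:
                raise ParseError(
                    f"{path}:{lineno}: start != end ({start} != {end}); "
                    "cov rows must be single CpGs"
                )
            try:
                sample.add_site(CpGSiteRecord(chrom, start, meth, unmeth))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return sample


def write_bismark_cov(sample: MethylationSample, path) -> None:
    """Write a sample as a 6-column Bismark coverage file.

    Rows are sorted by (chrom, pos); the percentage column is recomputed as
    ``100 * meth / (meth + unmeth)``.
    """
    with _open_text(path, "wt") as fh:
        for key in sorted(sample.sites):
            rec = sample.sites[key]
            pct = 100.0 * rec.meth_reads / rec.total_reads
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.pos}\t{pct:g}\t"
                f"{rec.meth_reads}\t{rec.unmeth_reads}\n"
            )


def convert_age_weeks_to_months(age_weeks: float) -> float:
    """Convert an age in weeks to months: weeks x 7 days / 30 days-per-month."""
    if age_weeks < 0:
        raise ValidationError(f"age in weeks must be >= 0, got {age_weeks}")
    return age_weeks * 7.0 / 30.0


def parse_region_id(region_id: str) -> Region:
    """Parse a 1-based inclusive ``chrom:start:end`` id into a Region."""
    return Region.from_id(region_id)


_INTERCEPT_KEY = "intercept"


def read_clock_definition(
    path,
    region_col: str = "region_id",
    weight_col: str = "weight",
    feature_kind: str = "region",
) -> ClockModel:
    """Load a clock from TSV: one row per region plus one intercept row.

    The intercept row carries the literal id ``intercept`` (case-insensitive)
    in the region column. Column names are configurable so externally
    published tables with different headers can be ingested directly.
    """
    df = pd.read_csv(path, sep="\t", dtype={region_col: str})
    for col in (region_col, weight_col):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    is_intercept = df[region_col].str.lower() == _INTERCEPT_KEY
    if is_intercept.sum() != 1:
        raise ValidationError(
            f"{path}: expected exactly one intercept row, "
            f"found {int(is_intercept.sum())}"
        )
    intercept = float(df.loc[is_intercept, weight_col].iloc[0])
    terms = {
        str(rid): float(w)
        for rid, w in zip(df.loc[~is_intercept, region_col],
                          df.loc[~is_intercept, weight_col])
    }
    if not terms:
        raise ValidationError(f"{path}: clock has no region terms")
    return ClockModel(intercept=intercept, terms=terms,
                      feature_kind=feature_kind, provenance=f"loaded:{path}")


def write_clock_definition(model: ClockModel, path) -> None:
    """Serialise a clock as region_id/weight TSV with an intercept row."""
    if not model.terms:
        raise ValidationError("refusing to write a clock with no terms")
    rows = [(_INTERCEPT_KEY, model.intercept)]
    rows += sorted(model.terms.items())
    pd.DataFrame(rows, columns=["region_id", "weight"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_sample_metadata(path) -> list[SampleMeta]:
    """Read a metadata TSV (sample_id, age, age_unit, [group], [tissue]).

    Ages with ``age_unit == "weeks"`` are converted to months; metadata
    therefore always carries months downstream.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "age", "age_unit"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    metas = []
    for _, row in df.iterrows():
        unit = str(row["age_unit"]).lower()
        if unit in ("month", "months", "mo"):
            age_mo = float(row["age"])
        elif unit in ("week", "weeks", "wk"):
            age_mo = convert_age_weeks_to_months(float(row["age"]))
        else:
            raise ValidationError(f"{path}: unknown age_unit {unit!r}")
        group = row.get("group")
        tissue = row.get("tissue")
        metas.append(SampleMeta(
            sample_id=str(row["sample_id"]),
            age_months=age_mo,
            group=None if pd.isna(group) else str(group),
            tissue=None if pd.isna(tissue) else str(tissue),
        ))
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate sample ids")
    return metas


def write_sample_metadata(metas: Iterable[SampleMeta], path) -> None:
    df = pd.DataFrame(
        [(m.sample_id, m.age_months, "months", m.group or "", m.tissue or "")
         for m in metas],
        columns=["sample_id", "age", "age_unit", "group", "tissue"],
    )
    df.to_csv(path, sep="\t", index=False)
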