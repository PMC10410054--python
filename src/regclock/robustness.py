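"""Coverage diagnostics and downsampling robustness analysis.

RRBS capture is uneven across studies: a CpG deeply covered in one dataset
can be nearly absent in another, which silently zeroes clock features under
zero-imputation. This module quantifies that failure mode three ways:

* per-feature *relative coverage* — reads in the feature per million total
  reads in the sample, comparable across sequencing depths;
* *downsampling* — drawing a target number of reads without replacement
  from the pooled (site, methylation-state) reads of a sample (multivariate
  hypergeometric), the count-level analogue of subsampling a FASTQ; and
* the *zero-feature count* of a clock on a sample — how many clock terms
  carry methylation zero or are imputed to zero, the quantity that
  saturates as depth falls and pins predictions to the clock intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covio import ClockModel, CpGSiteRecord, MethylationSample
from .errors import ValidationError
from .quantitation import build_region_matrix, filter_low_coverage, region_methylation
from .segmentation import RegionSet
from .clock import evaluate_predictions, predict_age

__all__ = [
    "CoverageProfile",
    "ZeroFeatureResult",
    "relative_coverage",
    "downsample_reads",
    "zero_feature_count",
    "downsample_curve",
]


@dataclass
class CoverageProfile:
    """Per-feature relative coverage: reads_feature / reads_sample x 1e6."""

    coverage: dict[str, float]
    depth_label: int  # total reads of the sample

    def __getitem__(self, feature_id: str) -> float:
        return self.coverage[feature_id]


def relative_coverage(
    sample: MethylationSample, features: RegionSet | None = None
) -> CoverageProfile:
    """Compute relative coverage per feature (region, or per site if None).

    For regions, reads are summed over member CpGs. When features partition
    all sites the profile sums to exactly 1e6.
    """
    total = sample.total_reads
    if total == 0:
        raise ValidationError("sample has no reads")
    scale = 1e6 / total
    cov: dict[str, float] = {}
    if features is None:
        for rec in sample.sites.values():
            cov[f"{rec.chrom}:{rec.pos}:{rec.pos}"] = rec.total_reads * scale
    else:
        arrays = sample.arrays_by_chrom()
        for region in features:
            reads = 0
            if region.chrom in arrays:
                pos, _, totals = arrays[region.chrom]
                lo = np.searchsorted(pos, region.start + 1, side="left")
                hi = np.searchsorted(pos, region.end, side="right")
                reads = int(totals[lo:hi].sum())
            cov[region.id] = reads * scale
    return CoverageProfile(coverage=cov, depth_label=total)


def downsample_reads(
    sample: MethylationSample, target_reads: int, seed: int
) -> MethylationSample:
    """Draw ``target_reads`` reads without replacement from a sample.

    The pooled reads form a multiset over (site, methylated?) categories;
    the retained counts follow the multivariate hypergeometric distribution,
    so per-site counts never exceed the originals and totals are conserved
    exactly. Sites left with zero reads disappear from the sample.
    """
    total = sample.total_reads
    if not (0 <= target_reads <= total):
        raise ValidationError(
            f"target_reads must be in [0, {total}], got {target_reads}"
        )
    recs = [sample.sites[k] for k in sorted(sample.sites)]
    colors = np.empty(2 * len(recs), dtype=np.int64)
    colors[0::2] = [r.meth_reads for r in recs]
    colors[1::2] = [r.unmeth_reads for r in recs]
    rng = np.random.default_rng(seed)
    drawn = rng.multivariate_hypergeometric(colors, target_reads)
    kept: list[CpGSiteRecord] = []
    for i, rec in enumerate(recs):
        m, u = int(drawn[2 * i]), int(drawn[2 * i + 1])
        if m + u > 0:
            kept.append(CpGSiteRecord(rec.chrom, rec.pos, m, u))
    return MethylationSample(sample.meta, kept)


@dataclass
class ZeroFeatureResult:
    count: int
    n_terms: int
    saturated: bool

    @property
    def fraction(self) -> float:
        return self.count / self.n_terms if self.n_terms else 0.0


def zero_feature_count(
    model: ClockModel,
    sample: MethylationSample,
    regions: RegionSet | None = None,
) -> ZeroFeatureResult:
    """Count clock terms with methylation zero (measured or imputed).

    Uncovered features impute to zero under the prediction rule; features
    measured at exactly beta = 0 also contribute nothing. ``saturated``
    flags the limit where every term is zero and the prediction collapses
    to the clock intercept.
    """
    if regions is None:
        regions = RegionSet.from_ids(model.terms.keys())
        lookup = {r.id: r for r in regions}
        ordered = [lookup[t] for t in model.terms]
    else:
        lookup = {r.id: r for r in regions}
        ordered = []
        for term in model.terms:
            if term not in lookup:
                raise ValidationError(f"clock term {term} not in region set")
            ordered.append(lookup[term])
    count = 0
    for region in ordered:
        beta = region_methylation(sample, region)
        if not np.isfinite(beta) or beta == 0.0:
            count += 1
    n_terms = len(model.terms)
    return ZeroFeatureResult(count=count, n_terms=n_terms,
                             saturated=(count == n_terms))


def downsample_curve(
    samples,
    models: dict[str, tuple[ClockModel, RegionSet]],
    depth_grid,
    seed: int,
    min_reads: int = 5,
    refilter: bool = True,
) -> pd.DataFrame:
    """Re-run the full pipeline at each depth and score every clock.

    For each depth (descending) every sample is downsampled to that many
    reads, the coverage filter re-applied (unless ``refilter=False``), the
    region matrix rebuilt, and each clock applied and evaluated. Output has
    one row per (depth, model) with columns adj_r2, mae, mean zero-feature
    count and the number of saturated samples.
    """
    samples = list(samples)
    depth_grid = list(depth_grid)
    if any(b > a for a, b in zip(depth_grid, depth_grid[1:])):
        raise ValidationError("depth_grid must be sorted descending")
    for s in samples:
        if depth_grid and depth_grid[0] > s.total_reads:
            raise ValidationError(
                f"depth {depth_grid[0]} exceeds total reads of "
                f"{s.meta.sample_id} ({s.total_reads})"
            )
    ages = np.array([s.meta.age_months for s in samples])
    rows = []
    for d_i, depth in enumerate(depth_grid):
        sub = [
            downsample_reads(s, int(depth), seed=seed + 1000 * d_i + j)
            for j, s in enumerate(samples)
        ]
        if refilter:
            sub = [filter_low_coverage(s, min_reads) for s in sub]
        for name, (model, regions) in models.items():
            matrix = build_region_matrix(sub, regions)
            pred = predict_age(model, matrix)
            ev = evaluate_predictions(pred.e_age, ages)
            zf = [zero_feature_count(model, s, regions) for s in sub]
            rows.append({
                "depth": int(depth),
                "model": name,
                "adj_r2": ev.adj_r2,
                "mae": ev.mae_months,
                "mean_zero_features": float(np.mean([z.count for z in zf])),
                "n_saturated_samples": int(sum(z.saturated for z in zf)),
            })
    return pd.DataFrame(rows)
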