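"""Synthetic RRBS cohorts with the structure the regional method assumes.

The generator emulates three properties of real reduced-representation
bisulfite data that the regional clock methodology exploits or must survive:

* CpGs arrive in *clusters* (MspI fragments concentrate CpG-dense DNA), so
  density-based segmentation has real structure to find;
* a subset of regions drift in methylation linearly with age — these are
  the "clock regions" a LASSO fit should recover — while the rest hold an
  age-independent baseline;
* per-site read depth is negative-binomially overdispersed and sites can
  drop out entirely per sample or per study, producing the uneven coverage
  that breaks single-CpG clocks on external data.

Within a cluster, a sample's per-site beta values are Beta-distributed
around the region mean mu(age) = clip(baseline + slope * age, 0, 1), and
observed methylated read counts are Binomial(reads, beta) — so recomputed
betas are valid by construction. All randomness flows from a single numpy
Generator seeded by the config, making cov output byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .covio import (
    CpGSiteRecord,
    MethylationSample,
    SampleMeta,
    write_bismark_cov,
    write_sample_metadata,
)
from .errors import ValidationError
from .segmentation import Region, RegionSet

__all__ = [
    "SimConfig",
    "CohortTruth",
    "simulate_cohort",
    "simulate_coverage_shift",
    "write_cohort",
]

_MU_EPS = 1e-3  # keep Beta parameters strictly positive


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a desk-scale cohort: 60 blood samples aged 3-30
    months, 50 CpG clusters of 20 CpGs (30 bp apart within a cluster,
    2 kb between clusters) on 2 chromosomes, of which 5 clusters drift
    with age at 0.01-0.02 beta/month (half gaining, half losing
    methylation). Depth is negative binomial with mean 30 reads/site.
    """

    n_chroms: int = 2
    chrom_length_bp: int = 200_000
    n_cpg_clusters: int = 50
    cpgs_per_cluster: int = 20
    intra_cluster_spacing_bp: int = 30
    inter_cluster_gap_bp: int = 2000
    n_samples: int = 60
    age_range_months: tuple[float, float] = (3.0, 30.0)
    n_clock_regions: int = 5
    slope_range: tuple[float, float] = (0.01, 0.02)
    baseline_beta_range: tuple[float, float] = (0.25, 0.75)
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0
    beta_concentration: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_chroms, self.chrom_length_bp, self.n_cpg_clusters,
                  self.cpgs_per_cluster, self.intra_cluster_spacing_bp,
                  self.inter_cluster_gap_bp, self.n_samples,
                  self.n_clock_regions)
        if any(c < 1 for c in counts):
            raise ValidationError("all counts/sizes must be >= 1")
        if self.n_clock_regions > self.n_cpg_clusters:
            raise ValidationError("more clock regions than clusters")
        lo, hi = self.age_range_months
        if not (0 <= lo < hi):
            raise ValidationError(f"bad age range ({lo}, {hi})")
        mag = max(abs(s) for s in self.slope_range)
        if mag * hi > 1.0:
            raise ValidationError(
                "slope range can push beta outside [0, 1] over the age range"
            )

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {str(i + 1): self.chrom_length_bp for i in range(self.n_chroms)}


@dataclass
class CohortTruth:
    """Ground truth behind a simulated cohort, for recovery tests."""

    clusters: RegionSet            # every generating CpG cluster
    clock_regions: RegionSet       # the age-informative subset
    slopes: dict[str, float]       # clock region id -> beta/month
    baselines: dict[str, float]    # clock region id -> beta at age 0
    cpg_positions: dict[str, list[int]] = field(default_factory=dict)


def _layout(cfg: SimConfig):
    """Place clusters round-robin across chromosomes; 1-based positions."""
    span = (cfg.cpgs_per_cluster - 1) * cfg.intra_cluster_spacing_bp
    pitch = span + cfg.inter_cluster_gap_bp
    per_chrom = math.ceil(cfg.n_cpg_clusters / cfg.n_chroms)
    if 1000 + per_chrom * pitch > cfg.chrom_length_bp:
        raise ValidationError(
            f"{per_chrom} clusters of pitch {pitch} bp exceed chromosome "
            f"length {cfg.chrom_length_bp}"
        )
    chroms, positions, cluster_of_site = [], [], []
    clusters: list[Region] = []
    for k in range(cfg.n_cpg_clusters):
        chrom = str(k % cfg.n_chroms + 1)
        idx_on_chrom = k // cfg.n_chroms
        start1 = 1001 + idx_on_chrom * pitch
        pos = [start1 + i * cfg.intra_cluster_spacing_bp
               for i in range(cfg.cpgs_per_cluster)]
        clusters.append(Region.from_1based_inclusive(chrom, pos[0], pos[-1]))
        chroms += [chrom] * len(pos)
        positions += pos
        cluster_of_site += [k] * len(pos)
    return clusters, np.array(chroms), np.array(positions), np.array(cluster_of_site)


def simulate_cohort(
    cfg: SimConfig,
    age_offset_months: float = 0.0,
    sample_prefix: str = "S",
    group: str = "control",
) -> tuple[list[MethylationSample], CohortTruth]:
    """Generate a cohort of Bismark-style samples plus its ground truth.

    ``age_offset_months`` shifts the *methylation-generating* age relative
    to the recorded chronological age — a biological age offset, e.g. -3.0
    emulates an intervention decelerating the methylome by three months.
    """
    rng = np.random.default_rng(cfg.seed)
    clusters, chroms, positions, cluster_of_site = _layout(cfg)

    # pick informative clusters, split signs half/half
    chosen = np.sort(rng.choice(cfg.n_cpg_clusters, cfg.n_clock_regions,
                                replace=False))
    signs = np.ones(cfg.n_clock_regions)
    signs[: cfg.n_clock_regions // 2] = -1.0
    rng.shuffle(signs)
    lo_s, hi_s = cfg.slope_range
    mags = rng.uniform(lo_s, hi_s, cfg.n_clock_regions)
    slopes_arr = signs * mags
    max_age = cfg.age_range_months[1]
    baselines_arr = np.where(
        slopes_arr > 0,
        rng.uniform(0.10, 0.95 - mags * max_age, cfg.n_clock_regions),
        rng.uniform(0.05 + mags * max_age, 0.90, cfg.n_clock_regions),
    )

    # per-site baseline: informative sites inherit their region baseline,
    # background sites hold their own age-independent level
    site_base = rng.uniform(*cfg.baseline_beta_range, positions.size)
    site_slope = np.zeros(positions.size)
    for j, k in enumerate(chosen):
        mask = cluster_of_site == k
        site_base[mask] = baselines_arr[j]
        site_slope[mask] = slopes_arr[j]

    ages = rng.uniform(*cfg.age_range_months, cfg.n_samples)
    r = cfg.depth_dispersion
    p_nb = r / (r + cfg.depth_mean)
    nu = cfg.beta_concentration

    samples: list[MethylationSample] = []
    for i in range(cfg.n_samples):
        gen_age = max(0.0, ages[i] + age_offset_months)
        mu = np.clip(site_base + site_slope * gen_age, _MU_EPS, 1 - _MU_EPS)
        reads = rng.negative_binomial(r, p_nb, positions.size)
        beta_site = rng.beta(mu * nu, (1 - mu) * nu)
        meth = rng.binomial(reads, beta_site)
        keep = reads > 0
        meta = SampleMeta(
            sample_id=f"{sample_prefix}{i:03d}",
            age_months=float(ages[i]),
            group=group,
            tissue="blood",
        )
        recs = [
            CpGSiteRecord(str(c), int(p), int(m), int(t - m))
            for c, p, m, t in zip(chroms[keep], positions[keep],
                                  meth[keep], reads[keep])
        ]
        samples.append(MethylationSample(meta, recs))

    clock_regions = RegionSet([clusters[k] for k in chosen],
                              {"simulated": True})
    truth = CohortTruth(
        clusters=RegionSet(list(clusters), {"simulated": True}),
        clock_regions=clock_regions,
        slopes={clusters[k].id: float(s) for k, s in zip(chosen, slopes_arr)},
        baselines={clusters[k].id: float(b)
                   for k, b in zip(chosen, baselines_arr)},
        cpg_positions={
            c: sorted(positions[chroms == c].tolist())
            for c in np.unique(chroms)
        },
    )
    return samples, truth


def simulate_coverage_shift(
    samples: list[MethylationSample], retention: float, seed: int
) -> list[MethylationSample]:
    """Emulate an external study capturing only a subset of sites.

    Each site of each sample is independently retained with probability
    ``retention``; dropped sites vanish entirely (as if never captured).
    """
    if not (0.0 < retention <= 1.0):
        raise ValidationError(f"retention must be in (0, 1], got {retention}")
    rng = np.random.default_rng(seed)
    shifted = []
    for sample in samples:
        keys = sorted(sample.sites)
        keep = rng.random(len(keys)) < retention
        recs = [sample.sites[k] for k, kp in zip(keys, keep) if kp]
        shifted.append(MethylationSample(sample.meta, recs))
    return shifted


def write_cohort(
    samples: list[MethylationSample], truth: CohortTruth, outdir
) -> None:
    """Write cov files, metadata TSV and ground-truth TSV to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample in samples:
        write_bismark_cov(sample, outdir / f"{sample.meta.sample_id}.cov")
    write_sample_metadata([s.meta for s in samples], outdir / "metadata.tsv")
    pd.DataFrame(
        [(rid, truth.slopes[rid], truth.baselines[rid])
         for rid in truth.clock_regions.ids],
        columns=["region_id", "slope", "baseline"],
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    truth.clusters.to_bed(outdir / "clusters.bed")
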