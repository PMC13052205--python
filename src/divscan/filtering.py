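"""Hard site filters and greedy pairwise-r2 LD pruning.

Filter rules are applied in a fixed order (chromosome exclude -> quality ->
depth -> missingness -> MAF) and each dropped site is attributed to the first
rule it fails, so the per-rule drop counts sum to the number of dropped sites.

The MAF rule applies to variant sites only: invariant records carry no minor
allele and are retained as callable sites for the diversity denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

FILTER_ORDER = ["excluded_chrom", "qual", "depth", "missingness", "maf"]


@dataclass
class FilterConfig:
    """Thresholds for hard site filtering.

    Defaults mirror the common resequencing choices (QUAL >= 30, site depth
    within [1/3x, 2x] of the dataset mean, per-site missingness <= 0.10,
    MAF >= 0.05); each can be disabled by passing ``None``.
    """

    min_qual: float | None = 30.0
    depth_bounds: tuple[float, float] | None = (1 / 3, 2.0)
    min_maf: float | None = 0.05
    max_missing_fraction: float | None = 0.10
    exclude_chroms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.min_maf is not None and not (0 <= self.min_maf <= 0.5):
            raise ValueError(f"min_maf must be in [0, 0.5], got {self.min_maf}")
        if self.max_missing_fraction is not None and not (
            0 <= self.max_missing_fraction <= 1
        ):
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if self.depth_bounds is not None and not (
            0 <= self.depth_bounds[0] < self.depth_bounds[1]
        ):
            raise ValueError(f"bad depth bounds {self.depth_bounds}")


@dataclass
class PruneConfig:
    """PLINK ``--indep-pairwise``-style window/step/threshold (50 10 0.2)."""

    window_size_snps: int = 50
    step_snps: int = 10
    r2_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.step_snps > self.window_size_snps:
            raise ValueError("step must be <= window size")
        if not (0 < self.r2_threshold < 1):
            raise ValueError("r2_threshold must be in (0, 1)")


def allele_counts(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt allele count, called allele count) over all samples."""
    calls = matrix.calls
    called = calls != MISSING
    alt = np.where(called, calls, 0).sum(axis=1)
    n = 2 * called.sum(axis=1)
    return alt.astype(float), n.astype(float)


def compute_maf(matrix: GenotypeMatrix, site: int | None = None):
    """Minor allele frequency min(p, 1-p); NaN where every call is missing.

    Returns the full per-site array, or a scalar when ``site`` is given.
    """
    alt, n = allele_counts(matrix)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    maf[n == 0] = np.nan
    if site is not None:
        return float(maf[site])
    return maf


def missing_fraction(matrix: GenotypeMatrix) -> np.ndarray:
    if matrix.n_samples == 0:
        return np.zeros(matrix.n_sites)
    return (matrix.calls == MISSING).mean(axis=1)


def apply_site_filters(
    matrix: GenotypeMatrix, config: FilterConfig
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply hard filters; returns (filtered matrix, per-rule drop counts).

    Depth bounds are multipliers of the mean site depth of the input matrix
    (computed over sites with a depth annotation).
    """
    n = matrix.n_sites
    fail_rule = np.full(n, -1, dtype=int)  # index into FILTER_ORDER, -1 = pass

    chroms = matrix.sites["chrom"].to_numpy()
    if config.exclude_chroms:
        excluded = np.isin(chroms, list(config.exclude_chroms))
        fail_rule[excluded & (fail_rule < 0)] = 0

    if config.min_qual is not None:
        qual = matrix.sites["qual"].to_numpy(dtype=float)
        bad = np.isfinite(qual) & (qual < config.min_qual)
        fail_rule[bad & (fail_rule < 0)] = 1

    if config.depth_bounds is not None:
        depth = matrix.sites["depth"].to_numpy(dtype=float)
        finite = np.isfinite(depth)
        if finite.any():
            mean_depth = depth[finite].mean()
            lo = config.depth_bounds[0] * mean_depth
            hi = config.depth_bounds[1] * mean_depth
            bad = finite & ((depth < lo) | (depth > hi))
            fail_rule[bad & (fail_rule < 0)] = 2

    if config.max_missing_fraction is not None:
        bad = missing_fraction(matrix) > config.max_missing_fraction
        fail_rule[bad & (fail_rule < 0)] = 3

    if config.min_maf is not None:
        maf = compute_maf(matrix)
        is_variant = matrix.sites["is_variant"].to_numpy(dtype=bool)
        with np.errstate(invalid="ignore"):
            bad = is_variant & (np.isnan(maf) | (maf < config.min_maf))
        fail_rule[bad & (fail_rule < 0)] = 4

    drops = {
        rule: int((fail_rule == i).sum()) for i, rule in enumerate(FILTER_ORDER)
    }
    kept = fail_rule < 0
    logger.info(
        "site filters: %d/%d retained; drops %s", int(kept.sum()), n, drops
    )
    return matrix.subset_sites(kept), drops


def dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of genotype dosages on pairwise-complete samples.

    Returns NaN when fewer than 2 complete pairs or either dosage is constant.
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    vx = xs.var()
    vy = ys.var()
    if vx == 0 or vy == 0:
        return np.nan
    cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_prune(matrix: GenotypeMatrix, config: PruneConfig | None = None) -> np.ndarray:
    """Greedy windowed LD pruning; returns indices of retained sites.

    Within each window of ``window_size_snps`` consecutive SNPs (advancing by
    ``step_snps``), every retained pair with dosage r^2 above the threshold has
    its later-positioned member removed. Deterministic for a fixed input.
    """
    if config is None:
        config = PruneConfig()
    if not matrix.is_sorted():
        raise ValueError("matrix sites must be sorted by (chrom, pos)")
    keep = np.ones(matrix.n_sites, dtype=bool)
    calls = matrix.calls
    chroms = matrix.sites["chrom"].to_numpy()

    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        m = len(idx)
        start = 0
        while start < m:
            window = idx[start : start + config.window_size_snps]
            for a_pos in range(len(window)):
                i = window[a_pos]
                if not keep[i]:
                    continue
                for b_pos in range(a_pos + 1, len(window)):
                    j = window[b_pos]
                    if not keep[j]:
                        continue
                    r2 = dosage_r2(calls[i], calls[j])
                    if np.isfinite(r2) and r2 > config.r2_threshold:
                        keep[j] = False
            if start + config.window_size_snps >= m:
                break
            start += config.step_snps
    return np.flatnonzero(keep)
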