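"""Method-of-moments IBD relatedness (PI_HAT) and LD-decay profiling.

PI_HAT follows the PLINK ``--genome`` approach: per pair, identity-by-state
counts (IBS0/1/2) over called biallelic sites are equated to their expected
values under the three identity-by-descent states, using allele frequencies
from the sample panel, and solved sequentially for P(IBD=0), P(IBD=1),
P(IBD=2). Negative solutions are clamped to zero and the triple renormalized;
PI_HAT = P2 + P1/2 and dissimilarity = 1 - PI_HAT.

Pooling allele frequencies across strongly diverged populations inflates
apparent within-population relatedness (shared population-specific alleles
look like IBD); pooled frequencies are nonetheless the default because a
single mixed panel is the common single-run setup. Pass ``freqs`` computed per
population to remove that inflation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .formats import MISSING, GenotypeMatrix, PopulationMap
from .filtering import dosage_r2

logger = logging.getLogger(__name__)

MIN_INFORMATIVE_SITES = 50


@dataclass
class RelatednessEstimate:
    sample_a: str
    sample_b: str
    n_sites: int
    ibs0: int
    ibs1: int
    ibs2: int
    p0: float
    p1: float
    p2: float
    pi_hat: float
    low_confidence: bool = False

    @property
    def dissimilarity(self) -> float:
        return 1.0 - self.pi_hat


def panel_allele_freqs(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-site alt-allele frequency over all samples; NaN when uncalled."""
    called = matrix.calls != MISSING
    n = 2 * called.sum(axis=1)
    alt = np.where(called, matrix.calls, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, alt / np.maximum(n, 1), np.nan)


def estimate_pi_hat(
    matrix: GenotypeMatrix,
    pair: tuple[int | str, int | str],
    allele_freqs: np.ndarray | None = None,
) -> RelatednessEstimate:
    """Method-of-moments IBD estimate for one sample pair.

    Sites used are variant, called in both samples, and polymorphic in the
    frequency panel (0 < p < 1). Pairs with fewer than 50 informative sites
    are flagged ``low_confidence``.
    """
    ia = matrix.samples.index(pair[0]) if isinstance(pair[0], str) else pair[0]
    ib = matrix.samples.index(pair[1]) if isinstance(pair[1], str) else pair[1]
    if allele_freqs is None:
        allele_freqs = panel_allele_freqs(matrix)
    p = np.asarray(allele_freqs, dtype=float)

    ga = matrix.calls[:, ia].astype(int)
    gb = matrix.calls[:, ib].astype(int)
    ok = (
        (ga != MISSING)
        & (gb != MISSING)
        & matrix.sites["is_variant"].to_numpy(dtype=bool)
        & np.isfinite(p)
        & (p > 0)
        & (p < 1)
    )
    ga, gb, p = ga[ok], gb[ok], p[ok]
    n = ga.size
    ibs = 2 - np.abs(ga - gb)
    n0 = int((ibs == 0).sum())
    n1 = int((ibs == 1).sum())
    n2 = int((ibs == 2).sum())

    q = 1 - p
    e_ibs0_ibd0 = float((2 * p**2 * q**2).sum())
    e_ibs1_ibd0 = float((4 * p**3 * q + 4 * p * q**3).sum())
    e_ibs2_ibd0 = float(n) - e_ibs0_ibd0 - e_ibs1_ibd0
    e_ibs1_ibd1 = float((2 * p * q).sum())
    e_ibs2_ibd1 = float(n) - e_ibs1_ibd1

    p0 = n0 / e_ibs0_ibd0 if e_ibs0_ibd0 > 0 else 0.0
    p1 = (n1 - p0 * e_ibs1_ibd0) / e_ibs1_ibd1 if e_ibs1_ibd1 > 0 else 0.0
    p2 = (n2 - p0 * e_ibs2_ibd0 - p1 * e_ibs2_ibd1) / n if n > 0 else 0.0

    # bound the sequential solution: an IBD-state estimate above 1 (possible
    # when the pair is LESS similar than random panel draws, e.g. across
    # diverged populations) pins that state and zeroes the others
    if p0 > 1:
        p0, p1, p2 = 1.0, 0.0, 0.0
    elif p1 > 1:
        p0, p1, p2 = 0.0, 1.0, 0.0
    elif p2 > 1:
        p0, p1, p2 = 0.0, 0.0, 1.0
    probs = np.clip([p0, p1, p2], 0.0, None)
    total = probs.sum()
    probs = probs / total if total > 0 else np.array([1.0, 0.0, 0.0])
    pi_hat = float(np.clip(probs[2] + probs[1] / 2, 0.0, 1.0))

    low = n < MIN_INFORMATIVE_SITES
    if low:
        logger.warning(
            "pair (%s, %s): only %d informative sites; estimate is low-confidence",
            pair[0], pair[1], n,
        )
    return RelatednessEstimate(
        sample_a=matrix.samples[ia],
        sample_b=matrix.samples[ib],
        n_sites=n,
        ibs0=n0,
        ibs1=n1,
        ibs2=n2,
        p0=float(probs[0]),
        p1=float(probs[1]),
        p2=float(probs[2]),
        pi_hat=pi_hat,
        low_confidence=bool(low),
    )


def relatedness_matrix(
    matrix: GenotypeMatrix,
    popmap: PopulationMap | None = None,
    freq_mode: str = "pooled",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs PI_HAT table and symmetric dissimilarity matrix (zero diagonal).

    ``freq_mode`` "pooled" uses panel-wide allele frequencies; "per_population"
    (requires ``popmap``) uses each population's own frequencies for
    within-population pairs and pooled frequencies for cross pairs.
    """
    if matrix.n_samples < 2:
        raise ValueError("need >= 2 samples")
    if freq_mode not in ("pooled", "per_population"):
        raise ValueError(f"unknown freq_mode {freq_mode!r}")
    pooled = panel_allele_freqs(matrix)
    per_pop: dict[str, np.ndarray] = {}
    if freq_mode == "per_population":
        if popmap is None:
            raise ValueError("per_population mode requires a population map")
        for pop in popmap.populations:
            idx = popmap.indices_of(pop, matrix.samples)
            per_pop[pop] = panel_allele_freqs(matrix.subset_samples(
                [matrix.samples[i] for i in idx]
            ))

    rows = []
    names = matrix.samples
    dis = pd.DataFrame(0.0, index=names, columns=names)
    for ia, ib in combinations(range(len(names)), 2):
        freqs = pooled
        if freq_mode == "per_population":
            pa = popmap.assignments[names[ia]]
            pb = popmap.assignments[names[ib]]
            if pa == pb:
                freqs = per_pop[pa]
        est = estimate_pi_hat(matrix, (ia, ib), allele_freqs=freqs)
        rows.append(
            {
                "sample_a": est.sample_a,
                "sample_b": est.sample_b,
                "n_sites": est.n_sites,
                "ibs0": est.ibs0,
                "ibs1": est.ibs1,
                "ibs2": est.ibs2,
                "p0": est.p0,
                "p1": est.p1,
                "p2": est.p2,
                "pi_hat": est.pi_hat,
                "dissimilarity": est.dissimilarity,
                "low_confidence": est.low_confidence,
            }
        )
        dis.iloc[ia, ib] = est.dissimilarity
        dis.iloc[ib, ia] = est.dissimilarity
    return pd.DataFrame(rows), dis


def pairwise_r2(
    matrix: GenotypeMatrix,
    max_dist: int = 1_000_000,
    min_maf: float = 0.10,
) -> pd.DataFrame:
    """Same-chromosome dosage r^2 for site pairs within ``max_dist`` bp.

    Sites are restricted to variant sites with MAF >= ``min_maf``; pairs at
    distance 0 and pairs involving a zero-variance dosage are skipped.
    """
    from .filtering import compute_maf

    if not matrix.is_sorted():
        raise ValueError("matrix sites must be sorted by (chrom, pos)")
    maf = compute_maf(matrix)
    is_variant = matrix.sites["is_variant"].to_numpy(dtype=bool)
    with np.errstate(invalid="ignore"):
        use = is_variant & np.isfinite(maf) & (maf >= min_maf)
    idx = np.flatnonzero(use)
    chroms = matrix.sites["chrom"].to_numpy()[idx]
    pos = matrix.sites["pos"].to_numpy()[idx]
    calls = matrix.calls[idx]

    rows = []
    for start in range(len(idx)):
        for j in range(start + 1, len(idx)):
            if chroms[j] != chroms[start]:
                break
            dist = int(pos[j] - pos[start])
            if dist > max_dist:
                break
            if dist == 0:
                continue
            r2 = dosage_r2(calls[start], calls[j])
            if np.isfinite(r2):
                rows.append((chroms[start], int(pos[start]), int(pos[j]), dist, r2))
    return pd.DataFrame(rows, columns=["chrom", "pos_a", "pos_b", "dist", "r2"])


def ld_decay_bins(
    pairs: pd.DataFrame, bin_size: int = 10_000, max_dist: int = 1_000_000
) -> pd.DataFrame:
    """Mean r^2 in right-closed distance bins ((k-1)*bin, k*bin]; empty bins n=0."""
    n_bins = int(np.ceil(max_dist / bin_size))
    edges_hi = (np.arange(n_bins) + 1) * bin_size
    out = pd.DataFrame(
        {
            "bin_start": edges_hi - bin_size,
            "bin_end": edges_hi,
            "n": 0,
            "mean_r2": np.nan,
        }
    )
    if len(pairs):
        k = np.ceil(pairs["dist"].to_numpy() / bin_size).astype(int)  # 1-based bin
        ok = (k >= 1) & (k <= n_bins)
        grp = pd.DataFrame({"bin": k[ok], "r2": pairs["r2"].to_numpy()[ok]}).groupby("bin")
        counts = grp.size()
        means = grp["r2"].mean()
        out.loc[counts.index - 1, "n"] = counts.to_numpy()
        out.loc[means.index - 1, "mean_r2"] = means.to_numpy()
    return out


def population_ld_decay(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    population: str,
    max_dist: int = 1_000_000,
    min_maf: float = 0.10,
    bin_size: int = 10_000,
    force: bool = False,
) -> pd.DataFrame:
    """LD-decay bins for one population's samples.

    Refuses populations with fewer than 4 samples unless ``force``: with n = 2
    diploids nearly every polymorphic pair yields r^2 near 1 at all distances,
    so the decay curve carries no information.
    """
    samples = popmap.samples_of(population)
    if len(samples) < 4 and not force:
        raise ValueError(
            f"population {population!r} has {len(samples)} samples; LD decay is "
            "uninformative below 4 (r^2 ~ 1 at all distances) — pass force=True to override"
        )
    sub = matrix.subset_samples(samples)
    pairs = pairwise_r2(sub, max_dist=max_dist, min_maf=min_maf)
    return ld_decay_bins(pairs, bin_size=bin_size, max_dist=max_dist)
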