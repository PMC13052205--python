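"""Sliding-window nucleotide diversity, absolute divergence and Fst.

pi and Dxy use missing-data-aware denominators: each site contributes its own
pair count (``n*(n-1)/2`` within a population, ``n1*n2`` between populations)
computed from the alleles actually called there, and invariant sites contribute
zero to the numerator but fully to the denominator. This is the estimator
popularised by pixy and requires all-sites input for absolute per-bp values; a
"window-length" denominator mode is provided for variant-only VCFs and is
labelled as such in the output.

Fst is the Weir & Cockerham (1984) two-level diploid estimator: per-site
variance components a (among populations), b (among individuals within
populations) and c (within individuals), combined per window as the ratio of
sums sum(a) / sum(a + b + c) — the "weighted" windowed estimate reported by
vcftools. Negative values are retained, not clamped, so the empirical outlier
threshold downstream is unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import MISSING, GenomicInterval, GenotypeMatrix, PopulationMap


@dataclass(frozen=True)
class Window:
    interval: GenomicInterval
    index: int


def make_windows(
    chrom_lengths: dict[str, int], size: int = 50_000, step: int = 10_000
) -> list[Window]:
    """Sliding windows per chromosome: starts 0, step, 2*step, ... < length.

    The last windows are truncated at the chromosome end.
    """
    if step > size:
        raise ValueError(f"step ({step}) > window size ({size}) leaves gaps")
    windows: list[Window] = []
    i = 0
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        start = 0
        while start < length:
            end = min(start + size, length)
            windows.append(Window(GenomicInterval(chrom, start, end), i))
            i += 1
            start += step
    return windows


def windows_frame(windows: list[Window]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "window": [w.index for w in windows],
            "chrom": [w.interval.chrom for w in windows],
            "start": [w.interval.start for w in windows],
            "end": [w.interval.end for w in windows],
        }
    )


def site_pi(c, n):
    """Per-site diversity: mean pairwise difference c*(n-c) / (n choose 2)."""
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    pairs = n * (n - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(pairs > 0, c * (n - c) / np.where(pairs > 0, pairs, 1), np.nan)
    return out if out.ndim else float(out)


def site_dxy(c1, n1, c2, n2):
    """Per-site divergence: cross-population mean pairwise difference."""
    c1, n1 = np.asarray(c1, dtype=float), np.asarray(n1, dtype=float)
    c2, n2 = np.asarray(c2, dtype=float), np.asarray(n2, dtype=float)
    cross = n1 * n2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(
            cross > 0,
            (c1 * (n2 - c2) + c2 * (n1 - c1)) / np.where(cross > 0, cross, 1),
            np.nan,
        )
    return out if out.ndim else float(out)


def wc_site_components(genotype_counts) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham variance components for biallelic diploid sites.

    ``genotype_counts`` has shape (2, 3) for one site or (S, 2, 3) for S sites:
    per population, counts of (hom-ref, het, hom-alt) genotypes. Returns the
    per-site components (a, b, c): among-population, among-individual-within-
    population, and within-individual. Sites where any population has no called
    genotype, or with mean sample size <= 1, yield NaN components.
    """
    g = np.asarray(genotype_counts, dtype=float)
    scalar = g.ndim == 2
    if scalar:
        g = g[None]
    if g.shape[1] != 2 or g.shape[2] != 3:
        raise ValueError("expected genotype counts of shape (S, 2, 3)")
    r = 2.0
    n_i = g.sum(axis=2)  # (S, 2) called genotypes per population
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = (g[:, :, 1] + 2 * g[:, :, 2]) / (2 * n_i)
        h_i = g[:, :, 1] / n_i
    n_bar = n_i.mean(axis=1)
    n_tot = n_i.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (n_tot - (n_i**2).sum(axis=1) / n_tot) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=1) / n_tot
        s2 = (n_i * (p_i - p_bar[:, None]) ** 2).sum(axis=1) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=1) / n_tot

        inner = p_bar * (1 - p_bar) - ((r - 1) / r) * s2
        a = (n_bar / n_c) * (s2 - (inner - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (inner - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar)
        c = h_bar / 2

    bad = (n_i == 0).any(axis=1) | (n_bar <= 1) | ~np.isfinite(n_c) | (n_c == 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    if scalar:
        return float(a[0]), float(b[0]), float(c[0])
    return a, b, c


def _pop_counts(matrix: GenotypeMatrix, idx: np.ndarray):
    """Per-site (alt count, called alleles, genotype count triple) for samples idx."""
    calls = matrix.calls[:, idx]
    called = calls != MISSING
    n_geno = called.sum(axis=1).astype(float)
    alt = np.where(called, calls, 0).sum(axis=1).astype(float)
    het = (calls == 1).sum(axis=1).astype(float)
    hom_alt = (calls == 2).sum(axis=1).astype(float)
    hom_ref = n_geno - het - hom_alt
    counts = np.stack([hom_ref, het, hom_alt], axis=1)
    return alt, 2 * n_geno, counts


def _window_sums(values: np.ndarray, pos0: np.ndarray, lo: int, hi: int) -> float:
    """Sum of ``values`` over sites with lo <= pos0 < hi (pos0 sorted)."""
    a = np.searchsorted(pos0, lo, side="left")
    b = np.searchsorted(pos0, hi, side="left")
    return float(values[a:b].sum())


def summarize_windows(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    windows: list[Window],
    min_variant_sites: int = 1,
    denominator: str = "callable",
) -> pd.DataFrame:
    """Per-window pi (each population), Dxy, and ratio-of-sums W-C Fst.

    ``denominator``: "callable" divides pi/Dxy by the summed per-site pair
    counts over callable sites (requires all-sites input for absolute values);
    "window_length" divides summed per-site diversities by the window length
    (variant-only fallback, labelled in the ``denominator`` output column).
    Windows with fewer than ``min_variant_sites`` variant sites get Fst NaN.
    """
    if denominator not in ("callable", "window_length"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    pop1, pop2 = popmap.require_two()
    popmap.validate_against(matrix.samples)
    idx1 = popmap.indices_of(pop1, matrix.samples)
    idx2 = popmap.indices_of(pop2, matrix.samples)
    if len(idx1) == 0 or len(idx2) == 0:
        raise ValueError("both populations must have samples in the matrix")

    sites = matrix.sites
    is_variant = sites["is_variant"].to_numpy(dtype=bool)
    alt1, n1, counts1 = _pop_counts(matrix, idx1)
    alt2, n2, counts2 = _pop_counts(matrix, idx2)

    # Per-site numerators/denominators; a site enters a denominator only when
    # callable there (>=2 alleles within-pop, >=1 per pop between-pops).
    pi1_num = alt1 * (n1 - alt1)
    pi1_den = n1 * (n1 - 1) / 2.0
    pi2_num = alt2 * (n2 - alt2)
    pi2_den = n2 * (n2 - 1) / 2.0
    dxy_num = alt1 * (n2 - alt2) + alt2 * (n1 - alt1)
    dxy_den = n1 * n2

    pi1_num[pi1_den <= 0] = 0
    pi1_den[pi1_den <= 0] = 0
    pi2_num[pi2_den <= 0] = 0
    pi2_den[pi2_den <= 0] = 0
    dxy_num[dxy_den <= 0] = 0
    dxy_den[dxy_den <= 0] = 0

    gcounts = np.stack([counts1, counts2], axis=1)  # (S, 2, 3)
    a = np.zeros(matrix.n_sites)
    b = np.zeros(matrix.n_sites)
    c = np.zeros(matrix.n_sites)
    if is_variant.any():
        av, bv, cv = wc_site_components(gcounts[is_variant])
        av, bv, cv = (np.nan_to_num(x, nan=0.0) for x in (av, bv, cv))
        a[is_variant], b[is_variant], c[is_variant] = av, bv, cv

    records = []
    chrom_groups = {
        chrom: np.flatnonzero(sites["chrom"].to_numpy() == chrom)
        for chrom in sites["chrom"].unique()
    }
    for w in windows:
        chrom = w.interval.chrom
        lo, hi = w.interval.start, w.interval.end
        gidx = chrom_groups.get(chrom, np.array([], dtype=int))
        pos0 = sites["pos"].to_numpy()[gidx] - 1
        order = gidx  # sites within a chromosome assumed position-sorted

        def wsum(values: np.ndarray) -> float:
            return _window_sums(values[order], pos0, lo, hi)

        nvar = wsum(is_variant.astype(float))
        ncall1 = wsum((pi1_den > 0).astype(float))
        ncall2 = wsum((pi2_den > 0).astype(float))
        s_pi1n, s_pi1d = wsum(pi1_num), wsum(pi1_den)
        s_pi2n, s_pi2d = wsum(pi2_num), wsum(pi2_den)
        s_dxyn, s_dxyd = wsum(dxy_num), wsum(dxy_den)
        s_a, s_b, s_c = wsum(a), wsum(b), wsum(c)

        if denominator == "callable":
            pi1 = s_pi1n / s_pi1d if s_pi1d > 0 else np.nan
            pi2 = s_pi2n / s_pi2d if s_pi2d > 0 else np.nan
            dxy = s_dxyn / s_dxyd if s_dxyd > 0 else np.nan
        else:
            length = hi - lo
            with np.errstate(invalid="ignore", divide="ignore"):
                pi1 = wsum(np.where(pi1_den > 0, pi1_num / np.maximum(pi1_den, 1), 0)) / length
                pi2 = wsum(np.where(pi2_den > 0, pi2_num / np.maximum(pi2_den, 1), 0)) / length
                dxy = wsum(np.where(dxy_den > 0, dxy_num / np.maximum(dxy_den, 1), 0)) / length

        abc = s_a + s_b + s_c
        fst = s_a / abc if (nvar >= min_variant_sites and abc != 0) else np.nan
        records.append(
            {
                "window": w.index,
                "chrom": chrom,
                "start": lo,
                "end": hi,
                "n_variant_sites": int(nvar),
                "n_callable_pop1": int(ncall1),
                "n_callable_pop2": int(ncall2),
                "pi_pop1": pi1,
                "pi_pop2": pi2,
                "dxy": dxy,
                "fst_a": s_a,
                "fst_abc": abc,
                "fst": fst,
            }
        )
    out = pd.DataFrame.from_records(records)
    out.attrs["denominator"] = denominator
    out.attrs["populations"] = (pop1, pop2)
    return out


def individual_heterozygosity(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample heterozygosity: het calls / non-missing calls.

    With all-sites input this is per callable site; with variant-only input it
    is per called SNP (the denominator choice is the caller's to interpret).
    Samples with zero called sites get NaN.
    """
    if matrix.n_sites == 0:
        raise ValueError("empty matrix")
    calls = matrix.calls
    n_called = (calls != MISSING).sum(axis=0)
    n_het = (calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
    return pd.DataFrame(
        {
            "sample": matrix.samples,
            "n_het": n_het,
            "n_called": n_called,
            "het_rate": rate,
        }
    )


def wc_fst(matrix: GenotypeMatrix, popmap: PopulationMap) -> float:
    """Genome-wide ratio-of-sums Weir-Cockerham Fst over all variant sites."""
    pop1, pop2 = popmap.require_two()
    idx1 = popmap.indices_of(pop1, matrix.samples)
    idx2 = popmap.indices_of(pop2, matrix.samples)
    is_variant = matrix.sites["is_variant"].to_numpy(dtype=bool)
    _, _, counts1 = _pop_counts(matrix, idx1)
    _, _, counts2 = _pop_counts(matrix, idx2)
    g = np.stack([counts1, counts2], axis=1)[is_variant]
    a, b, c = wc_site_components(g)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    return float(a[ok].sum() / denom) if denom != 0 else float("nan")


def genomewide_fst(window_table: pd.DataFrame) -> float:
    """Ratio-of-sums Fst over all windows' summed components."""
    a = window_table["fst_a"].sum()
    abc = window_table["fst_abc"].sum()
    return float(a / abc) if abc != 0 else float("nan")
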