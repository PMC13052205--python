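"""Synthetic two-population genotype data with known ground truth.

The core generator is a Balding-Nichols model: each variant site has an
ancestral allele frequency p drawn from a configured range; each population's
frequency is a Beta(p(1-F)/F, (1-p)(1-F)/F) draw, so E[Fst] ~ F; genotypes
are Binomial(2, p_pop) per diploid sample. Divergence islands are intervals
where the dispersion parameter F is raised from the background value to an
island value, planting contiguous high-Fst/high-Dxy regions whose coordinates
are recorded in the truth table. Invariant sites are emitted as all-sites
records so the callable-site denominators of pi/Dxy can be exercised, and
genotype missingness is MCAR.

Default sampling design mirrors a two-range resequencing study with a strongly
asymmetric sample: 7 individuals in population "GLG" and 2 in "WL". The
mutation rate (6e-9 per site per generation) and generation time (3 years) are
carried for split-depth scaling only and do not enter the Balding-Nichols
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .formats import (
    MISSING,
    GenomicInterval,
    GenotypeMatrix,
    PopulationMap,
    write_popmap,
    write_table,
    write_vcf,
)


def _default_chroms() -> dict[str, int]:
    return {"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000}


def _default_islands() -> list[GenomicInterval]:
    # two 150-kb islands = 5% of the 6-Mb default genome
    return [
        GenomicInterval("chr1", 500_000, 650_000),
        GenomicInterval("chr2", 1_200_000, 1_350_000),
    ]


@dataclass
class SimulationConfig:
    """Parameters of the two-population Balding-Nichols generator.

    ``f_background``/``f_island`` may be a single F shared by both populations
    or a (F1, F2) pair for asymmetric drift. ``site_density`` is all-sites
    records per bp; ``variant_fraction`` of them are SNP records, the rest
    invariant. Constant QUAL/DP annotations are synthesized above the default
    hard-filter thresholds.
    """

    seed: int
    n_pop1: int = 7
    n_pop2: int = 2
    pop1_name: str = "GLG"
    pop2_name: str = "WL"
    chrom_lengths: dict[str, int] = dc_field(default_factory=_default_chroms)
    site_density: float = 1 / 400
    variant_fraction: float = 0.5
    freq_range: tuple[float, float] = (0.10, 0.90)
    f_background: float | tuple[float, float] = 0.05
    f_island: float | tuple[float, float] = 0.60
    islands: list[GenomicInterval] = dc_field(default_factory=_default_islands)
    missing_rate: float = 0.05
    mutation_rate: float = 6.0e-9
    generation_time: float = 3.0
    qual: float = 60.0
    depth: float = 90.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for f in (*_as_pair(self.f_background), *_as_pair(self.f_island)):
            if not (0 < f < 1):
                raise ValueError(f"divergence parameter F must be in (0, 1), got {f}")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 < self.variant_fraction <= 1):
            raise ValueError("variant_fraction must be in (0, 1]")
        for isl in self.islands:
            length = self.chrom_lengths.get(isl.chrom)
            if length is None or isl.end > length:
                raise ValueError(f"island {isl} outside chromosome bounds")

    @property
    def sample_names(self) -> list[str]:
        return [f"{self.pop1_name}_{i+1}" for i in range(self.n_pop1)] + [
            f"{self.pop2_name}_{i+1}" for i in range(self.n_pop2)
        ]

    def population_map(self) -> PopulationMap:
        out = {f"{self.pop1_name}_{i+1}": self.pop1_name for i in range(self.n_pop1)}
        out.update({f"{self.pop2_name}_{i+1}": self.pop2_name for i in range(self.n_pop2)})
        return PopulationMap(out)


def _as_pair(f) -> tuple[float, float]:
    if isinstance(f, (tuple, list)):
        return float(f[0]), float(f[1])
    return float(f), float(f)


@dataclass
class TruthTable:
    """Ground truth for every emitted site plus planted structure."""

    sites: pd.DataFrame  # chrom,pos,is_variant,p_anc,p_pop1,p_pop2,f_pop1,f_pop2,in_island
    islands: list[GenomicInterval]
    pedigree: dict[tuple[str, str], str]
    config: SimulationConfig


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Population frequencies around ancestral p with dispersion F."""
    lam = (1 - f) / f
    return rng.beta(p * lam, (1 - p) * lam)


def simulate_two_pop(config: SimulationConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """Draw a two-population all-sites genotype matrix with planted islands."""
    rng = np.random.default_rng(config.seed)
    f1_bg, f2_bg = _as_pair(config.f_background)
    f1_isl, f2_isl = _as_pair(config.f_island)

    frames = []
    calls_parts = []
    n_samples = config.n_pop1 + config.n_pop2
    for chrom, length in config.chrom_lengths.items():
        n_sites = int(round(config.site_density * length))
        pos0 = np.sort(rng.choice(length, size=n_sites, replace=False))
        is_variant = rng.random(n_sites) < config.variant_fraction

        in_island = np.zeros(n_sites, dtype=bool)
        for isl in config.islands:
            if isl.chrom == chrom:
                in_island |= (pos0 >= isl.start) & (pos0 < isl.end)

        lo, hi = config.freq_range
        p_anc = np.where(is_variant, rng.uniform(lo, hi, size=n_sites), 0.0)
        f1 = np.where(in_island, f1_isl, f1_bg)
        f2 = np.where(in_island, f2_isl, f2_bg)
        p1 = np.zeros(n_sites)
        p2 = np.zeros(n_sites)
        v = is_variant
        p1[v] = _balding_nichols(rng, p_anc[v], f1[v])
        p2[v] = _balding_nichols(rng, p_anc[v], f2[v])

        g1 = rng.binomial(2, p1[:, None], size=(n_sites, config.n_pop1))
        g2 = rng.binomial(2, p2[:, None], size=(n_sites, config.n_pop2))
        calls = np.concatenate([g1, g2], axis=1).astype(np.int8)
        if config.missing_rate > 0:
            mask = rng.random(calls.shape) < config.missing_rate
            calls[mask] = MISSING

        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos0 + 1,
                    "is_variant": is_variant,
                    "p_anc": p_anc,
                    "p_pop1": p1,
                    "p_pop2": p2,
                    "f_pop1": np.where(v, f1, np.nan),
                    "f_pop2": np.where(v, f2, np.nan),
                    "in_island": in_island,
                }
            )
        )
        calls_parts.append(calls)

    truth_sites = pd.concat(frames, ignore_index=True)
    calls = np.vstack(calls_parts) if calls_parts else np.empty((0, n_samples), dtype=np.int8)

    sites = pd.DataFrame(
        {
            "chrom": truth_sites["chrom"],
            "pos": truth_sites["pos"],
            "ref": "A",
            "alt": np.where(truth_sites["is_variant"], "G", "."),
            "qual": config.qual,
            "depth": config.depth,
            "is_variant": truth_sites["is_variant"],
        }
    )
    matrix = GenotypeMatrix(sites=sites, samples=config.sample_names, calls=calls)
    truth = TruthTable(
        sites=truth_sites, islands=list(config.islands), pedigree={}, config=config
    )
    return matrix, truth


RELATIONSHIPS = ("MZ", "PO", "FS", "UN")
EXPECTED_PI_HAT = {"MZ": 1.0, "PO": 0.5, "FS": 0.5, "UN": 0.0}


def simulate_relatives(
    config: SimulationConfig,
    relationship: str,
    n_sites: int = 5_000,
) -> tuple[GenotypeMatrix, dict]:
    """Simulate one genotype pair with a known pedigree relationship.

    MZ copies one genotype vector; PO transmits one allele from a simulated
    parent (Mendelian) and draws the other from the founder frequency; FS draws
    two children of the same two parents; UN draws two independent genotypes.
    Returns the pair matrix and a truth dict holding the founder allele
    frequencies (the panel frequencies an estimator should use) and the
    pedigree expectation for PI_HAT.
    """
    if relationship not in RELATIONSHIPS:
        raise ValueError(f"unknown relationship {relationship!r}; expected one of {RELATIONSHIPS}")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.freq_range
    p = rng.uniform(lo, hi, size=n_sites)

    def draw_genotype() -> np.ndarray:
        return rng.binomial(2, p)

    def transmit(parent: np.ndarray) -> np.ndarray:
        # one allele per site: het parents transmit alt with probability 1/2
        return np.where(parent == 1, rng.integers(0, 2, size=parent.size), parent // 2)

    if relationship == "MZ":
        a = draw_genotype()
        b = a.copy()
    elif relationship == "PO":
        parent = draw_genotype()
        a = parent
        b = transmit(parent) + rng.binomial(1, p)
    elif relationship == "FS":
        father = draw_genotype()
        mother = draw_genotype()
        a = transmit(father) + transmit(mother)
        b = transmit(father) + transmit(mother)
    else:  # UN
        a = draw_genotype()
        b = draw_genotype()

    calls = np.stack([a, b], axis=1).astype(np.int8)
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_sites + 1) * 100,
            "ref": "A",
            "alt": "G",
            "qual": config.qual,
            "depth": config.depth,
            "is_variant": True,
        }
    )
    matrix = GenotypeMatrix(sites=sites, samples=["A", "B"], calls=calls)
    truth = {
        "relationship": relationship,
        "expected_pi_hat": EXPECTED_PI_HAT[relationship],
        "founder_freqs": p,
    }
    return matrix, truth


def simulate_ld_haplotypes(
    config: SimulationConfig,
    recomb_rate: float,
    n_founders: int = 8,
    n_samples: int | None = None,
    mutation_flip: float = 1e-3,
) -> GenotypeMatrix:
    """Recombining haplotypes copied from a founder pool (LD decays with distance).

    Each sample haplotype walks along the sites of each chromosome copying a
    founder haplotype, switching to a random founder between adjacent sites
    with probability 1 - exp(-recomb_rate * distance); alleles then flip with
    probability ``mutation_flip``. Nearby sites share founder origin more often
    than distant ones, so dosage r^2 declines with distance toward the 1/n
    sampling floor.
    """
    if recomb_rate <= 0:
        raise ValueError("recomb_rate must be > 0")
    if n_founders < 2:
        raise ValueError("founder pool must have >= 2 haplotypes")
    rng = np.random.default_rng(config.seed)
    if n_samples is None:
        n_samples = config.n_pop1 + config.n_pop2
    n_hap = 2 * n_samples

    frames = []
    calls_parts = []
    for chrom, length in config.chrom_lengths.items():
        n_sites = int(round(config.site_density * length))
        pos0 = np.sort(rng.choice(length, size=n_sites, replace=False))
        lo, hi = config.freq_range
        p = rng.uniform(lo, hi, size=n_sites)
        founders = (rng.random((n_founders, n_sites)) < p).astype(np.int8)

        hap = np.empty((n_hap, n_sites), dtype=np.int8)
        origin = rng.integers(0, n_founders, size=n_hap)
        hap[:, 0] = founders[origin, 0]
        for s in range(1, n_sites):
            d = pos0[s] - pos0[s - 1]
            p_switch = 1.0 - np.exp(-recomb_rate * d)
            switch = rng.random(n_hap) < p_switch
            if switch.any():
                origin[switch] = rng.integers(0, n_founders, size=int(switch.sum()))
            hap[:, s] = founders[origin, s]
        flips = rng.random(hap.shape) < mutation_flip
        hap = np.where(flips, 1 - hap, hap)

        calls = (hap[0::2] + hap[1::2]).T.astype(np.int8)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos0 + 1,
                    "ref": "A",
                    "alt": "G",
                    "qual": config.qual,
                    "depth": config.depth,
                    "is_variant": True,
                }
            )
        )
        calls_parts.append(calls)
    sites = pd.concat(frames, ignore_index=True)
    calls = np.vstack(calls_parts)
    samples = [f"S{i+1}" for i in range(n_samples)]
    return GenotypeMatrix(sites=sites, samples=samples, calls=calls)


def truth_window_f(truth: TruthTable, windows) -> pd.DataFrame:
    """Per-window mean planted F over variant sites (the expected Fst level)."""
    rows = []
    t = truth.sites
    for w in windows:
        sel = (
            (t["chrom"] == w.interval.chrom)
            & (t["pos"] - 1 >= w.interval.start)
            & (t["pos"] - 1 < w.interval.end)
            & t["is_variant"]
        )
        f_mean = float(t.loc[sel, ["f_pop1", "f_pop2"]].to_numpy().mean()) if sel.any() else np.nan
        rows.append(
            {
                "window": w.index,
                "chrom": w.interval.chrom,
                "start": w.interval.start,
                "end": w.interval.end,
                "expected_f": f_mean,
                "n_variant_sites": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def emit_fixtures(
    matrix: GenotypeMatrix,
    truth: TruthTable,
    outdir: str | Path,
    overwrite: bool = False,
    gene_spacing: int = 20_000,
    gene_length: int = 10_000,
    n_background_terms: int = 20,
) -> dict[str, Path]:
    """Write the simulated dataset in the pipeline's input formats.

    Emits an all-sites VCF, popmap, a GFF3 with genes tiled every
    ``gene_spacing`` bp (so planted islands overlap known genes), a gene->term
    TSV in which one planted term covers exactly the island genes and
    background terms partition the rest, the truth table, and the island
    intervals as BED. Refuses an existing output directory unless
    ``overwrite``.
    """
    outdir = Path(outdir)
    if outdir.exists() and not overwrite:
        raise FileExistsError(f"{outdir} exists; pass overwrite=True to replace")
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = truth.config

    paths = {
        "vcf": outdir / "sim.vcf",
        "popmap": outdir / "popmap.tsv",
        "gff3": outdir / "genes.gff3",
        "terms": outdir / "gene_terms.tsv",
        "truth": outdir / "truth.tsv",
        "islands_bed": outdir / "islands.bed",
    }
    write_vcf(matrix, paths["vcf"], chrom_lengths=cfg.chrom_lengths)
    write_popmap(cfg.population_map(), paths["popmap"])

    # genes tiled along every chromosome
    genes: list[tuple[str, int, int, str]] = []
    for chrom, length in cfg.chrom_lengths.items():
        k = 0
        start = 0
        while start + gene_length <= length:
            genes.append((chrom, start, start + gene_length, f"{chrom}_g{k:04d}"))
            k += 1
            start += gene_spacing
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, start, end, gid in genes:
            fh.write(
                f"{chrom}\tdivscan_sim\tgene\t{start + 1}\t{end}\t.\t+\t.\tID={gid}\n"
            )

    island_genes = [
        gid
        for chrom, start, end, gid in genes
        if any(i.chrom == chrom and start < i.end and i.start < end for i in truth.islands)
    ]
    rng = np.random.default_rng(cfg.seed + 7)
    with open(paths["terms"], "w") as fh:
        for gid in island_genes:
            fh.write(f"{gid}\tT_ISLAND\n")
        for chrom, start, end, gid in genes:
            for t in rng.choice(n_background_terms, size=2, replace=False):
                fh.write(f"{gid}\tT_BG{t:02d}\n")

    write_table(truth.sites, paths["truth"])
    with open(paths["islands_bed"], "w") as fh:
        for isl in truth.islands:
            fh.write(f"{isl.chrom}\t{isl.start}\t{isl.end}\n")
    return paths
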