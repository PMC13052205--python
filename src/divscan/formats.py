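"""Readers/writers for the standard formats the pipeline touches.

Internal coordinate convention is 0-based half-open (BED). VCF ``POS`` (1-based)
and GFF3 (1-based closed) are converted at ingest, so a SNP at VCF position ``p``
falls in window ``[s, e)`` iff ``s <= p - 1 < e``.

Genotypes are diploid dosage codes: 0 = hom-ref, 1 = het, 2 = hom-alt, and
``MISSING`` (-1) for uncalled or half-called genotypes. Phase is ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "depth", "is_variant"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end), 0-based."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_pos(self, pos0: int) -> bool:
        """Membership of a 0-based position."""
        return self.start <= pos0 < self.end


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    interval: GenomicInterval
    strand: str = "."


@dataclass
class PopulationMap:
    """Sample -> population assignment (two populations for divergence ops)."""

    assignments: dict[str, str]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop, None)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def indices_of(self, population: str, samples: Sequence[str]) -> np.ndarray:
        members = set(self.samples_of(population))
        return np.array([i for i, s in enumerate(samples) if s in members], dtype=int)

    def require_two(self) -> tuple[str, str]:
        pops = self.populations
        if len(pops) != 2:
            raise ValueError(f"expected exactly 2 populations, found {len(pops)}: {pops}")
        return pops[0], pops[1]

    def validate_against(self, samples: Iterable[str]) -> None:
        missing = [s for s in samples if s not in self.assignments]
        if missing:
            raise ValueError(f"samples absent from population map: {missing}")


@dataclass
class GenotypeMatrix:
    """Per-sample, per-site diploid genotype codes with explicit missingness.

    ``sites`` is a DataFrame with columns ``chrom, pos (1-based), ref, alt,
    qual, depth, is_variant``; ``calls`` is an int8 array of shape
    (n_sites, n_samples) holding dosage codes with -1 for missing.
    """

    sites: pd.DataFrame
    samples: list[str]
    calls: np.ndarray
    ingest_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def pos0(self) -> np.ndarray:
        """0-based site positions."""
        return self.sites["pos"].to_numpy() - 1

    def subset_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            calls=self.calls[idx],
        )

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        cols = [index[s] for s in keep]
        return GenotypeMatrix(
            sites=self.sites.copy(),
            samples=list(keep),
            calls=self.calls[:, cols],
        )

    def is_sorted(self) -> bool:
        s = self.sites
        for _, grp in s.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                return False
        return True


def read_vcf(
    path: str | Path,
    region: GenomicInterval | None = None,
    exclude_chroms: Sequence[str] = (),
) -> GenotypeMatrix:
    """Read biallelic SNP and invariant records from a VCF into a GenotypeMatrix.

    Multiallelic and indel records are skipped (counts logged and stored in
    ``ingest_counts``). Half-missing genotypes are coded missing; phase is
    ignored. ``region`` filters by position (half-open, 0-based).
    """
    path = Path(path)
    vcf = VCF(str(path), gts012=True)
    fmt_ids = {h.info().get("ID") for h in vcf.header_iter() if h.type == "FORMAT"}
    if "GT" not in fmt_ids:
        raise FormatError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.samples)
    exclude = set(exclude_chroms)

    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    qual: list[float] = []
    depth: list[float] = []
    is_variant: list[bool] = []
    rows: list[np.ndarray] = []
    counts = {"multiallelic": 0, "indel": 0, "excluded_chrom": 0, "kept": 0}

    for v in vcf:
        if v.CHROM in exclude:
            counts["excluded_chrom"] += 1
            continue
        if region is not None:
            if v.CHROM != region.chrom or not region.contains_pos(v.POS - 1):
                continue
        alts = [a for a in v.ALT if a not in (".", "<NON_REF>")]
        if len(alts) > 1:
            counts["multiallelic"] += 1
            continue
        variant = len(alts) == 1
        if len(v.REF) != 1 or (variant and len(alts[0]) != 1):
            counts["indel"] += 1
            continue
        gts = np.asarray(v.genotypes, dtype=int)
        alleles = gts[:, :2]
        row = alleles.sum(axis=1).astype(np.int8)
        row[(alleles < 0).any(axis=1)] = MISSING
        chroms.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(alts[0] if variant else ".")
        qual.append(v.QUAL if v.QUAL is not None else np.nan)
        dp = v.INFO.get("DP")
        depth.append(float(dp) if dp is not None else np.nan)
        is_variant.append(variant)
        rows.append(row)
        counts["kept"] += 1

    if counts["multiallelic"] or counts["indel"]:
        logger.info(
            "%s: skipped %d multiallelic and %d indel records",
            path.name,
            counts["multiallelic"],
            counts["indel"],
        )
    sites = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "pos": pd.Series(pos, dtype=np.int64),
            "ref": pd.Series(ref, dtype=str),
            "alt": pd.Series(alt, dtype=str),
            "qual": pd.Series(qual, dtype=float),
            "depth": pd.Series(depth, dtype=float),
            "is_variant": pd.Series(is_variant, dtype=bool),
        }
    )
    calls = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(sites=sites, samples=samples, calls=calls, ingest_counts=counts)


def read_popmap(path: str | Path) -> PopulationMap:
    """Read a two-column whitespace-delimited sample -> population map."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            sample, pop = parts
            if sample in assignments:
                raise FormatError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignments[sample] = pop
    if not assignments:
        raise FormatError(f"{path}: empty population map")
    return PopulationMap(assignments=assignments)


def _gff3_attr(attributes: str, key: str) -> str | None:
    for part in attributes.strip().split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def read_gff3_genes(path: str | Path) -> list[GeneRecord]:
    """Extract ``gene`` features from a GFF3 file as 0-based half-open records."""
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            if ftype != "gene":
                continue
            start1, end1 = int(start_s), int(end_s)
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start ({start_s} > {end_s})")
            gene_id = _gff3_attr(attrs, "ID") or f"{chrom}:{start_s}-{end_s}"
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    interval=GenomicInterval(chrom, start1 - 1, end1),
                    strand=strand,
                )
            )
    return genes


def write_bed(regions: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED3 (sorted by chrom, start)."""
    regions = sorted(regions)
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, *_ = line.split("\t")
            out.append(GenomicInterval(chrom, int(start), int(end)))
    return out


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as a TSV with header; floats keep full precision."""
    records.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF (fixture/subset output).

    Invariant sites are emitted as all-sites records with ALT='.'. Contig
    lengths default to the maximum observed position per chromosome.
    """
    sites = matrix.sites
    if chrom_lengths is None:
        chrom_lengths = (
            sites.groupby("chrom", sort=False)["pos"].max().to_dict() if len(sites) else {}
        )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=divscan\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={int(length)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        chroms = sites["chrom"].to_numpy()
        pos = sites["pos"].to_numpy()
        ref = sites["ref"].to_numpy()
        alt = sites["alt"].to_numpy()
        qual = sites["qual"].to_numpy()
        depth = sites["depth"].to_numpy()
        for i in range(len(sites)):
            q = "." if not np.isfinite(qual[i]) else f"{qual[i]:g}"
            info = "." if not np.isfinite(depth[i]) else f"DP={int(depth[i])}"
            gts = "\t".join(_GT_STRINGS[int(g)] for g in matrix.calls[i])
            fh.write(
                f"{chroms[i]}\t{pos[i]}\t.\t{ref[i]}\t{alt[i]}\t{q}\tPASS\t{info}\tGT\t{gts}\n"
            )


def write_popmap(popmap: PopulationMap | Mapping[str, str], path: str | Path) -> None:
    items = popmap.assignments if isinstance(popmap, PopulationMap) else popmap
    with open(path, "w") as fh:
        for sample, pop in items.items():
            fh.write(f"{sample}\t{pop}\n")
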