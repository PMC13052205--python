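"""Stage orchestration: each stage reads its inputs from disk, writes TSV/BED
outputs plus a JSON manifest, and is individually re-runnable. ``run_all``
chains the stages in dependency order. Manifests carry parameters, inputs,
outputs and bookkeeping counts (no timestamps), so identical inputs reproduce
byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import enrich_terms, read_term_map
from .filtering import FilterConfig, PruneConfig, apply_site_filters, ld_prune
from .formats import (
    GenomicInterval,
    read_gff3_genes,
    read_popmap,
    read_table,
    read_vcf,
    write_bed,
    write_table,
    write_vcf,
)
from .islands import (
    core_islands,
    empirical_top_fraction,
    genes_in_regions,
    merge_outlier_windows,
    regions_cover_subset,
    regions_frame,
)
from .relatedness import population_ld_decay, relatedness_matrix
from .simulate import SimulationConfig, emit_fixtures, simulate_two_pop
from .windows import Window, make_windows, summarize_windows

logger = logging.getLogger(__name__)

STAGES = ["simulate", "filter", "windows", "islands", "relatedness", "ldscan", "enrich"]


@dataclass
class RunConfig:
    """Flat run configuration; CLI flags override file values override defaults."""

    outdir: str = "divscan_out"
    seed: int = 0
    vcf: str | None = None
    popmap: str | None = None
    gff3: str | None = None
    terms: str | None = None
    # filtering
    min_qual: float | None = 30.0
    depth_low: float | None = 1 / 3
    depth_high: float | None = 2.0
    min_maf: float | None = 0.05
    max_missing: float | None = 0.10
    exclude_chroms: tuple[str, ...] = ()
    # pruning
    prune_window: int = 50
    prune_step: int = 10
    prune_r2: float = 0.2
    # windows
    window_size: int = 50_000
    window_step: int = 10_000
    denominator: str = "callable"
    min_variant_sites: int = 1
    # islands
    outlier_fraction: float = 0.01
    merge_gap: int = 10_000
    # relatedness / LD
    freq_mode: str = "pooled"
    ld_max_dist: int = 1_000_000
    ld_min_maf: float = 0.10
    ld_bin: int = 10_000
    ld_force: bool = False
    # enrichment
    min_term_size: int = 5
    display_p: float = 0.10

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "exclude_chroms" in data and data["exclude_chroms"] is not None:
            data["exclude_chroms"] = tuple(data["exclude_chroms"])
        return cls(**data)

    def filter_config(self) -> FilterConfig:
        bounds = None
        if self.depth_low is not None and self.depth_high is not None:
            bounds = (self.depth_low, self.depth_high)
        return FilterConfig(
            min_qual=self.min_qual,
            depth_bounds=bounds,
            min_maf=self.min_maf,
            max_missing_fraction=self.max_missing,
            exclude_chroms=tuple(self.exclude_chroms),
        )

    def prune_config(self) -> PruneConfig:
        return PruneConfig(
            window_size_snps=self.prune_window,
            step_snps=self.prune_step,
            r2_threshold=self.prune_r2,
        )

    def path(self, *parts: str) -> Path:
        p = Path(self.outdir).joinpath(*parts)
        p.parent.mkdir(parents=True, exist_ok=True)
        return p


class StageError(RuntimeError):
    """A stage precondition failed (names the missing input)."""


def _write_manifest(cfg: RunConfig, stage: str, inputs, outputs, params, counts) -> Path:
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "seed": cfg.seed,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "outputs": {k: str(v) for k, v in outputs.items()},
        "params": params,
        "counts": counts,
    }
    path = cfg.path("manifests", f"{stage}.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _require(path: Path | str | None, what: str, stage: str) -> Path:
    if path is None or not Path(path).exists():
        raise StageError(f"{stage}: required input {what} not found at {path!r}")
    return Path(path)


def stage_simulate(cfg: RunConfig) -> dict[str, Path]:
    sim_cfg = SimulationConfig(seed=cfg.seed)
    matrix, truth = simulate_two_pop(sim_cfg)
    paths = emit_fixtures(matrix, truth, Path(cfg.outdir) / "sim", overwrite=True)
    cfg.vcf = cfg.vcf or str(paths["vcf"])
    cfg.popmap = cfg.popmap or str(paths["popmap"])
    cfg.gff3 = cfg.gff3 or str(paths["gff3"])
    cfg.terms = cfg.terms or str(paths["terms"])
    _write_manifest(
        cfg,
        "simulate",
        inputs={},
        outputs=paths,
        params={"seed": cfg.seed, "config": "SimulationConfig defaults"},
        counts={"n_sites": matrix.n_sites, "n_samples": matrix.n_samples},
    )
    return paths


def stage_filter(cfg: RunConfig) -> dict[str, Path]:
    vcf_path = _require(cfg.vcf, "VCF", "filter")
    matrix = read_vcf(vcf_path, exclude_chroms=cfg.exclude_chroms)
    filtered, drops = apply_site_filters(matrix, cfg.filter_config())
    out_vcf = cfg.path("filtered.vcf")
    write_vcf(filtered, out_vcf)
    drops_tsv = cfg.path("filter_drop_counts.tsv")
    write_table(
        pd.DataFrame({"rule": list(drops), "n_dropped": list(drops.values())}), drops_tsv
    )
    outputs = {"filtered_vcf": out_vcf, "drop_counts": drops_tsv}
    _write_manifest(
        cfg,
        "filter",
        inputs={"vcf": vcf_path},
        outputs=outputs,
        params=dataclasses.asdict(cfg.filter_config()),
        counts={"input_sites": matrix.n_sites, "retained_sites": filtered.n_sites, **drops},
    )
    return outputs


def _load_filtered(cfg: RunConfig, stage: str):
    vcf_path = _require(cfg.path("filtered.vcf"), "filtered VCF (run the filter stage first)", stage)
    popmap_path = _require(cfg.popmap, "population map", stage)
    return read_vcf(vcf_path), read_popmap(popmap_path)


def _chrom_lengths_from(matrix) -> dict[str, int]:
    return matrix.sites.groupby("chrom", sort=False)["pos"].max().to_dict()


def stage_windows(cfg: RunConfig) -> dict[str, Path]:
    matrix, popmap = _load_filtered(cfg, "windows")
    windows = make_windows(
        _chrom_lengths_from(matrix), size=cfg.window_size, step=cfg.window_step
    )
    table = summarize_windows(
        matrix,
        popmap,
        windows,
        min_variant_sites=cfg.min_variant_sites,
        denominator=cfg.denominator,
    )
    out = cfg.path("window_stats.tsv")
    write_table(table, out)
    outputs = {"window_stats": out}
    _write_manifest(
        cfg,
        "windows",
        inputs={"filtered_vcf": cfg.path("filtered.vcf"), "popmap": cfg.popmap},
        outputs=outputs,
        params={
            "window_size": cfg.window_size,
            "window_step": cfg.window_step,
            "denominator": cfg.denominator,
            "min_variant_sites": cfg.min_variant_sites,
        },
        counts={"n_windows": len(table)},
    )
    return outputs


def _windows_from_table(table: pd.DataFrame) -> list[Window]:
    return [
        Window(GenomicInterval(r.chrom, int(r.start), int(r.end)), int(r.window))
        for r in table.itertuples()
    ]


def stage_islands(cfg: RunConfig) -> dict[str, Path]:
    wpath = _require(
        cfg.path("window_stats.tsv"), "window statistics table (run the windows stage first)", "islands"
    )
    table = read_table(wpath)
    windows = _windows_from_table(table)
    nwin = int(table["window"].max()) + 1
    fst = np.full(nwin, np.nan)
    dxy = np.full(nwin, np.nan)
    fst[table["window"].to_numpy()] = table["fst"].to_numpy()
    dxy[table["window"].to_numpy()] = table["dxy"].to_numpy()

    fst_flags, fst_thresh = empirical_top_fraction(fst, cfg.outlier_fraction)
    dxy_flags, dxy_thresh = empirical_top_fraction(dxy, cfg.outlier_fraction)
    fst_regions = merge_outlier_windows(windows, fst_flags, fst, cfg.merge_gap, source="fst")
    dxy_regions = merge_outlier_windows(windows, dxy_flags, dxy, cfg.merge_gap, source="dxy")
    cores = core_islands(fst_flags, dxy_flags, windows, values=fst, max_gap=cfg.merge_gap)
    assert regions_cover_subset(cores, fst_regions), "core islands must lie inside Fst regions"
    assert regions_cover_subset(cores, dxy_regions), "core islands must lie inside Dxy regions"

    outputs: dict[str, Path] = {}
    gene_counts = {}
    genes = read_gff3_genes(_require(cfg.gff3, "GFF3 annotation", "islands"))
    for name, regions in (("fst", fst_regions), ("dxy", dxy_regions), ("core", cores)):
        _, union = genes_in_regions(regions, genes)
        bed = cfg.path(f"outliers_{name}.bed")
        write_bed([r.interval for r in regions], bed)
        tsv = cfg.path(f"outliers_{name}.tsv")
        write_table(regions_frame(regions), tsv)
        gene_list = cfg.path(f"genes_{name}.txt")
        gene_list.write_text("".join(g + "\n" for g in union))
        outputs.update({f"{name}_bed": bed, f"{name}_tsv": tsv, f"{name}_genes": gene_list})
        gene_counts[f"n_{name}_regions"] = len(regions)
        gene_counts[f"n_{name}_genes"] = len(union)

    _write_manifest(
        cfg,
        "islands",
        inputs={"window_stats": wpath, "gff3": cfg.gff3},
        outputs=outputs,
        params={
            "outlier_fraction": cfg.outlier_fraction,
            "merge_gap": cfg.merge_gap,
            "fst_threshold": fst_thresh,
            "dxy_threshold": dxy_thresh,
        },
        counts=gene_counts,
    )
    return outputs


def stage_relatedness(cfg: RunConfig) -> dict[str, Path]:
    matrix, popmap = _load_filtered(cfg, "relatedness")
    variant = matrix.subset_sites(matrix.sites["is_variant"].to_numpy(dtype=bool))
    kept = ld_prune(variant, cfg.prune_config())
    pruned = variant.subset_sites(kept)
    bed = cfg.path("pruned_sites.bed")
    with open(bed, "w") as fh:
        for chrom, pos in zip(pruned.sites["chrom"], pruned.sites["pos"]):
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\n")
    pairs, dis = relatedness_matrix(pruned, popmap, freq_mode=cfg.freq_mode)
    pairs_tsv = cfg.path("relatedness_pairs.tsv")
    write_table(pairs, pairs_tsv)
    dis_tsv = cfg.path("dissimilarity.tsv")
    dis.to_csv(dis_tsv, sep="\t")
    outputs = {"pruned_bed": bed, "pairs": pairs_tsv, "dissimilarity": dis_tsv}
    _write_manifest(
        cfg,
        "relatedness",
        inputs={"filtered_vcf": cfg.path("filtered.vcf"), "popmap": cfg.popmap},
        outputs=outputs,
        params={**dataclasses.asdict(cfg.prune_config()), "freq_mode": cfg.freq_mode},
        counts={
            "variant_sites": variant.n_sites,
            "pruned_sites": pruned.n_sites,
            "n_pairs": len(pairs),
        },
    )
    return outputs


def stage_ldscan(cfg: RunConfig) -> dict[str, Path]:
    matrix, popmap = _load_filtered(cfg, "ldscan")
    variant = matrix.subset_sites(matrix.sites["is_variant"].to_numpy(dtype=bool))
    outputs: dict[str, Path] = {}
    counts: dict[str, int] = {}
    for pop in popmap.populations:
        n = len(popmap.samples_of(pop))
        if n < 4 and not cfg.ld_force:
            logger.warning(
                "ldscan: skipping population %s (n=%d < 4): with so few samples r^2 "
                "is ~1 at all distances and the decay curve is uninformative",
                pop,
                n,
            )
            counts[f"skipped_{pop}"] = n
            continue
        bins = population_ld_decay(
            variant,
            popmap,
            pop,
            max_dist=cfg.ld_max_dist,
            min_maf=cfg.ld_min_maf,
            bin_size=cfg.ld_bin,
            force=cfg.ld_force,
        )
        out = cfg.path(f"ld_decay_{pop}.tsv")
        write_table(bins, out)
        outputs[f"ld_{pop}"] = out
        counts[f"n_bins_{pop}"] = len(bins)
    _write_manifest(
        cfg,
        "ldscan",
        inputs={"filtered_vcf": cfg.path("filtered.vcf"), "popmap": cfg.popmap},
        outputs=outputs,
        params={
            "max_dist": cfg.ld_max_dist,
            "min_maf": cfg.ld_min_maf,
            "bin_size": cfg.ld_bin,
        },
        counts=counts,
    )
    return outputs


def stage_enrich(cfg: RunConfig) -> dict[str, Path]:
    genes_path = _require(
        cfg.path("genes_fst.txt"), "candidate gene list (run the islands stage first)", "enrich"
    )
    terms_path = _require(cfg.terms, "gene-term map", "enrich")
    candidates = [g for g in genes_path.read_text().splitlines() if g]
    term_map, meta = read_term_map(terms_path)
    result = enrich_terms(
        candidates,
        term_map,
        term_meta=meta,
        min_term_size=cfg.min_term_size,
        display_p=cfg.display_p,
    )
    out = cfg.path("enrichment.tsv")
    write_table(result, out)
    outputs = {"enrichment": out}
    _write_manifest(
        cfg,
        "enrich",
        inputs={"candidates": genes_path, "terms": terms_path},
        outputs=outputs,
        params={"min_term_size": cfg.min_term_size, "display_p": cfg.display_p},
        counts={"n_candidates": len(candidates), "n_terms_tested": len(result)},
    )
    return outputs


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "filter": stage_filter,
    "windows": stage_windows,
    "islands": stage_islands,
    "relatedness": stage_relatedness,
    "ldscan": stage_ldscan,
    "enrich": stage_enrich,
}


def run_all(cfg: RunConfig, simulate: bool | None = None) -> dict[str, Path]:
    """Chain every stage in order; starts with simulation unless a VCF is given."""
    outputs: dict[str, Path] = {}
    do_sim = simulate if simulate is not None else cfg.vcf is None
    order = STAGES if do_sim else STAGES[1:]
    for stage in order:
        outputs.update({f"{stage}.{k}": v for k, v in STAGE_FUNCS[stage](cfg).items()})
    return outputs
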