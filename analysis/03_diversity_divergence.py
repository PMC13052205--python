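#!/usr/bin/env python
"""Per-individual heterozygosity and the 50-kb / 10-kb sliding-window scan:
pi per population, Dxy and Weir-Cockerham Fst with callable-site denominators.
"""

import argparse
from pathlib import Path

import pandas as pd

from divscan.formats import read_popmap, read_vcf, write_table
from divscan.pipeline import RunConfig, stage_windows
from divscan.windows import genomewide_fst, individual_heterozygosity

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

cfg = RunConfig(outdir=str(args.outdir), seed=args.seed,
                popmap=str(args.outdir / "data" / "popmap.tsv"))
stage_windows(cfg)

matrix = read_vcf(args.outdir / "filtered.vcf")
popmap = read_popmap(cfg.popmap)
het = individual_heterozygosity(matrix)
het["population"] = het["sample"].map(popmap.assignments)
write_table(het, args.outdir / "heterozygosity.tsv")

table = pd.read_csv(args.outdir / "window_stats.tsv", sep="\t")
pop1, pop2 = popmap.require_two()
print(f"windows: {len(table)}  genome-wide Fst (ratio of sums): {genomewide_fst(table):.4f}")
print(f"mean pi per callable site  {pop1}: {table.pi_pop1.mean():.4f}   {pop2}: {table.pi_pop2.mean():.4f}")
print(f"mean Dxy: {table.dxy.mean():.4f}")
print(het.groupby("population")["het_rate"].mean().rename("mean het rate"))
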