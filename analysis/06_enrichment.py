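#!/usr/bin/env python
"""Hypergeometric over-representation of functional terms among the genes in
the merged top-Fst outlier regions (terms with < 5 genes excluded, no
multiple-testing correction; display threshold p < 0.10 marks reporting only).
"""

import argparse
from pathlib import Path

import pandas as pd

from divscan.pipeline import RunConfig, stage_enrich

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

cfg = RunConfig(outdir=str(args.outdir), seed=args.seed,
                terms=str(args.outdir / "data" / "gene_terms.tsv"))
stage_enrich(cfg)

table = pd.read_csv(args.outdir / "enrichment.tsv", sep="\t")
print(f"tested {len(table)} terms over a universe of {table.N.iloc[0] if len(table) else 0} genes")
cols = ["term_id", "k", "K", "n", "N", "p_value"]
print(table.head(5)[cols].to_string(index=False))
planted = table[table.term_id == "T_ISLAND"]
if len(planted):
    rank = planted.index[0] + 1
    print(f"planted island term rank: {rank} (p = {planted.p_value.iloc[0]:.3g})")
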