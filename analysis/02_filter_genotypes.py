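#!/usr/bin/env python
"""Hard-filter the cohort VCF: site quality, mean-relative depth,
per-site missingness (<= 0.10) and MAF (>= 0.05 on SNPs only), then write
the filtered all-sites VCF and the per-rule drop accounting.
"""

import argparse
from pathlib import Path

from divscan.pipeline import RunConfig, stage_filter

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

cfg = RunConfig(outdir=str(args.outdir), seed=args.seed, vcf=str(args.outdir / "data" / "sim.vcf"),
                popmap=str(args.outdir / "data" / "popmap.tsv"))
outputs = stage_filter(cfg)
print((args.outdir / "filter_drop_counts.tsv").read_text())
print(f"filtered VCF: {outputs['filtered_vcf']}")
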