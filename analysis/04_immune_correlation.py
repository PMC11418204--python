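#!/usr/bin/env python
"""Correlate cecal B-vitamin concentrations with immune-cell frequencies.

Reads the cecal metabolome and immune-frequency tables from
results/inputs/, restricts the metabolome to the eight B-vitamin
metabolites, log10-transforms the concentrations, computes the Pearson
matrix against population frequencies (matched pairing by sample ID), and
flags cells significant after BH adjustment across the whole matrix.
Writes results/correlation/correlations.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from fibervit.integration import ImmuneFrequencyTable, bvitamin_immune_correlation
from fibervit.metabolome import MetabolomeTable

parser = argparse.ArgumentParser()
parser.add_argument("--inputs", type=Path, default=Path("results/inputs"))
parser.add_argument("--outdir", type=Path, default=Path("results/correlation"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

data = pd.read_csv(args.inputs / "metabolome_cecum.tsv", sep="\t", index_col=0)
meta = pd.read_csv(args.inputs / "metabolome_cecum_meta.tsv", sep="\t").set_index("sample_id")
imm_data = pd.read_csv(args.inputs / "immune.tsv", sep="\t", index_col=0)

bvit_rows = [m for m in data.index if "(B" in m]
bvit = MetabolomeTable(data.loc[bvit_rows, imm_data.columns], meta)
imm = ImmuneFrequencyTable(imm_data, sample_meta=meta)

corr = bvitamin_immune_correlation(bvit, imm)
long = corr.to_long()
long.to_csv(args.outdir / "correlations.tsv", sep="\t", index=False)

sig = long[long["significant"]].sort_values("r")
print(f"{len(sig)} of {len(long)} vitamin-population cells significant after BH")
print("strongest negative correlations:")
for _, r in sig.head(5).iterrows():
    print(f"  {r['vitamin']} vs {r['population']}: r = {r['r']:+.2f} (adj p = {r['p_adj']:.2g})")
print(f"table written to {args.outdir}")
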