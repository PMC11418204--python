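#!/usr/bin/env python
"""Generate the synthetic study cohort and write every pipeline input.

Produces the taxon-stratified gene-family table (IN/SC2/FF diets, SPF, n=4
per group), the cecal and serum concentration tables (5 diets x SPF plus
SC1/FF x 14SM/GF, n=4), and the immune-frequency table, all under
results/inputs/.  The planted ground truth (S/D effects, microbiota-
dependent metabolites, vitamin-immune correlations) is saved alongside as
JSON so the later stages can be checked against it.
"""

import argparse
import json
from pathlib import Path

from fibervit.synthdata import (
    SimConfig,
    gen_immune,
    gen_metabolome,
    gen_metatranscriptome,
    write_genefamilies_tsv,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results/inputs"))
args = parser.parse_args()

out = args.outdir
out.mkdir(parents=True, exist_ok=True)
cfg = SimConfig(seed=args.seed)

table, sd_truth = gen_metatranscriptome(cfg)
write_genefamilies_tsv(table, out / "genefamilies.tsv")
table.sample_meta.reset_index().to_csv(out / "metatranscriptome_meta.tsv", sep="\t", index=False)
print(f"gene families: {table.totals().shape[0]} features x {len(table.sample_ids)} samples")

met_tables, met_truth = gen_metabolome(cfg)
for comp, t in met_tables.items():
    t.data.reset_index(names="metabolite").to_csv(out / f"metabolome_{comp}.tsv", sep="\t", index=False)
    t.sample_meta.reset_index().to_csv(out / f"metabolome_{comp}_meta.tsv", sep="\t", index=False)
print(f"metabolome: {met_tables['cecum'].data.shape[0]} metabolites, "
      f"{len(met_truth['microbiota_dependent'])} planted microbiota-dependent")

imm = gen_immune(cfg, (met_tables, met_truth))
imm.data.reset_index(names="population").to_csv(out / "immune.tsv", sep="\t", index=False)
print(f"immune: {imm.data.shape[0]} populations x {imm.data.shape[1]} samples")

truth = {
    "seed": args.seed,
    "planted_sd_effects": {
        v: {"delta": d["delta"], "mechanism": d["mechanism"]}
        for v, d in sd_truth["planted_sd_effects"].items()
    },
    "microbiota_dependent": sorted(met_truth["microbiota_dependent"]),
    "planted_correlations": [list(c) for c in cfg.planted_correlations],
}
(out / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
print(f"inputs and ground truth written to {out}")
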