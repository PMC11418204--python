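"""End-to-end pipeline assembly and report bundle.

``run_pipeline`` chains the stages in analysis order — gene-family table →
CPM → vitamin-role aggregation → log2 S/D ratio → group tests → taxon
contributions; metabolome → prevalence filter → normalize/log/autoscale →
differential ranking → Ward ordering → detection sets → colonized-only
metabolites; B-vitamin × immune correlation — and writes tidy TSVs, a JSON
run manifest and a plain-text summary into the output directory.  All
tables are assembled in memory first, so a failing stage leaves no partial
output behind.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import builtin_demo_annotation, load_annotation
from .integration import ImmuneFrequencyTable, bvitamin_immune_correlation
from .metabolome import (
    MetabolomeTable,
    colonized_only,
    detection_sets,
    differential_rank,
    normalize_log_scale,
    prevalence_filter,
    ward_order,
)
from .statcore import bh_adjust
from .synthdata import SimConfig, gen_immune, gen_metabolome, gen_metatranscriptome
from .transcripts import (
    aggregate_vitamin_roles,
    compare_sd,
    log2_sd_ratio,
    read_genefamilies,
    taxon_contributions,
    to_cpm,
)

logger = logging.getLogger(__name__)

OUTPUT_FILES = [
    "sd_ratio.tsv",
    "sd_tests.tsv",
    "taxon_contributions.tsv",
    "metabolome_filtered.tsv",
    "scaled_matrix.tsv",
    "differential.tsv",
    "set_regions.tsv",
    "correlations.tsv",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """One pipeline run: either simulate or supply input paths."""

    outdir: str | Path = "results"
    simulate: SimConfig | None = None
    genefamilies: str | Path | None = None
    annotation: str | Path | None = None
    metabolome_csv: str | Path | None = None
    immune_tsv: str | Path | None = None
    metadata_tsv: str | Path | None = None
    pseudocount_scale: str = "relab"
    moderation: bool = False
    pairing_default: str = "matched"
    top_k: int = 50
    alpha: float = 0.05
    sd_comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [("IN", "FF"), ("SC2", "FF")]
    )
    set_diets: list[str] = field(default_factory=lambda: ["SC1", "FF"])

    def validate(self) -> None:
        real = [self.genefamilies, self.metabolome_csv, self.metadata_tsv]
        if self.simulate is not None and any(p is not None for p in real):
            raise ValueError("exactly one of simulate or input paths may be active")
        if self.simulate is None:
            missing = [
                name
                for name, p in [
                    ("genefamilies", self.genefamilies),
                    ("metabolome_csv", self.metabolome_csv),
                    ("metadata_tsv", self.metadata_tsv),
                ]
                if p is None
            ]
            if missing:
                raise ValueError(f"real-data mode requires paths: {missing}")
            for name, p in [
                ("genefamilies", self.genefamilies),
                ("annotation", self.annotation),
                ("metabolome_csv", self.metabolome_csv),
                ("immune_tsv", self.immune_tsv),
                ("metadata_tsv", self.metadata_tsv),
            ]:
                if p is not None and not Path(p).exists():
                    raise ValueError(f"{name} path does not exist: {p}")
        if self.pseudocount_scale not in ("relab", "cpm"):
            raise ValueError("pseudocount_scale must be relab or cpm")


def _load_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    return meta.set_index("sample_id")


def _split_by_colonization(table: MetabolomeTable) -> dict[str, MetabolomeTable]:
    out = {}
    for col, ids in table.sample_meta.loc[table.data.columns].groupby("colonization").groups.items():
        out[str(col)] = MetabolomeTable(table.data[list(ids)], table.sample_meta)
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a dict of the in-memory results keyed by output name.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    results: dict = {}
    outputs: dict[str, pd.DataFrame] = {}

    def stage(name):
        logger.info("stage %s", name)

    try:
        stage("load")
        if cfg.simulate is not None:
            ann = builtin_demo_annotation()
            gf_table, sd_truth = gen_metatranscriptome(cfg.simulate, ann)
            met_tables, met_truth = gen_metabolome(cfg.simulate)
            immune = gen_immune(cfg.simulate, (met_tables, met_truth))
            cecum = met_tables["cecum"]
            bvit_rows = list(met_truth["bvitamin_metabolites"].values())
            results["ground_truth"] = {"sd": sd_truth, "metabolome": met_truth}
        else:
            ann = (
                load_annotation(cfg.annotation) if cfg.annotation else builtin_demo_annotation()
            )
            meta = _load_meta(cfg.metadata_tsv)
            gf_table = read_genefamilies(cfg.genefamilies, sample_meta=meta)
            met_data = pd.read_csv(cfg.metabolome_csv, sep="\t", index_col=0)
            cecum = MetabolomeTable(met_data, meta)
            bvit_rows = [m for m in met_data.index if "(B" in m]
            immune = None
            if cfg.immune_tsv:
                imm_data = pd.read_csv(cfg.immune_tsv, sep="\t", index_col=0)
                immune = ImmuneFrequencyTable(imm_data, sample_meta=meta)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("load", e) from e

    try:
        stage("sd_ratio")
        cpm = to_cpm(gf_table) if gf_table.units == "counts" else gf_table
        vra = aggregate_vitamin_roles(cpm, ann)
        sdr = log2_sd_ratio(vra, pseudocount_scale=cfg.pseudocount_scale)
        outputs["sd_ratio.tsv"] = sdr.table
        results["sd_ratio"] = sdr

        test_rows = []
        for a, b in cfg.sd_comparisons:
            try:
                tests = compare_sd(sdr, a, b)
            except ValueError as e:
                logger.warning("comparison %s vs %s skipped: %s", a, b, e)
                continue
            vits = sorted(tests)
            padj = bh_adjust([tests[v].p_raw for v in vits])
            for v, pa in zip(vits, padj):
                t = tests[v]
                t.p_adj = float(pa)
                test_rows.append(
                    (f"{a}_vs_{b}", v, t.test_used, t.statistic, t.p_raw, t.p_adj, t.direction)
                )
        outputs["sd_tests.tsv"] = pd.DataFrame(
            test_rows,
            columns=["comparison", "vitamin", "test_used", "statistic", "p_raw", "p_adj", "direction"],
        )
        results["sd_tests"] = outputs["sd_tests.tsv"]

        contrib = taxon_contributions(vra, "B2", "S")
        contrib.insert(0, "vitamin", "B2")
        contrib.insert(1, "role", "S")
        outputs["taxon_contributions.tsv"] = contrib
        results["taxon_contributions"] = contrib
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("sd_ratio", e) from e

    try:
        stage("metabolome")
        filt = prevalence_filter(cecum)
        z = normalize_log_scale(filt)
        groups = filt.group_of()
        ref = "SPF:FF" if "SPF:FF" in set(groups) else sorted(set(groups))[0]
        diff = differential_rank(z, groups, ref, k=cfg.top_k, moderate=cfg.moderation)
        order = ward_order(z)
        outputs["metabolome_filtered.tsv"] = filt.data.reset_index(names="metabolite")
        outputs["scaled_matrix.tsv"] = z.data.iloc[order].reset_index(names="metabolite")
        outputs["differential.tsv"] = diff
        results["scaled"] = z
        results["differential"] = diff

        by_col = _split_by_colonization(cecum)
        region_rows = []
        results["colonized_only"] = {}
        if {"SPF", "14SM", "GF"} <= set(by_col):
            for diet in cfg.set_diets:
                sets = detection_sets(by_col, diet=diet)
                mset, count = colonized_only(sets)
                results["colonized_only"][diet] = (mset, count)
                for region, members in sorted(sets.regions.items()):
                    region_rows.append((diet, region, len(members)))
        else:
            logger.warning("skipping detection sets: need SPF, 14SM and GF samples")
        outputs["set_regions.tsv"] = pd.DataFrame(
            region_rows, columns=["diet", "region", "count"]
        )
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("metabolome", e) from e

    try:
        stage("correlate")
        if immune is not None and bvit_rows:
            bvit = MetabolomeTable(cecum.data.loc[bvit_rows], cecum.sample_meta)
            corr = bvitamin_immune_correlation(
                bvit, immune, default_mode=cfg.pairing_default, alpha=cfg.alpha
            )
            long = corr.to_long()
            long["pairing_mode"] = ";".join(f"{g}={m}" for g, m in sorted(corr.pairing_mode.items()))
            outputs["correlations.tsv"] = long
            results["correlation"] = corr
        else:
            outputs["correlations.tsv"] = pd.DataFrame(
                columns=["vitamin", "population", "r", "p_raw", "p_adj", "significant", "pairing_mode"]
            )
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("correlate", e) from e

    stage("write")
    outdir.mkdir(parents=True, exist_ok=True)
    for name in OUTPUT_FILES:
        outputs[name].to_csv(outdir / name, sep="\t", index=False)
    manifest = {
        "fibervit_version": __version__,
        "mode": "simulate" if cfg.simulate is not None else "files",
        "seed": cfg.simulate.seed if cfg.simulate is not None else None,
        "flags": {
            "pseudocount_scale": cfg.pseudocount_scale,
            "moderation": cfg.moderation,
            "pairing_default": cfg.pairing_default,
            "top_k": cfg.top_k,
            "alpha": cfg.alpha,
        },
        "outputs": OUTPUT_FILES,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    lines = [
        f"fibervit {__version__} run summary",
        f"samples (metatranscriptome): {len(results['sd_ratio'].table['sample'].unique())}",
        f"vitamins with S/D ratios: {sorted(results['sd_ratio'].table['vitamin'].unique())}",
    ]
    for diet, (_, count) in results.get("colonized_only", {}).items():
        lines.append(f"colonized-only metabolites ({diet} diet): {count}")
    if "correlation" in results:
        sig = int(results["correlation"].significant.values.sum())
        lines.append(f"significant vitamin-immune correlations: {sig}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    results["outputs"] = outputs
    return results
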