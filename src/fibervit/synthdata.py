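"""Synthetic cohort generator with planted ground truth.

Every pipeline input — the taxon-stratified gene-family table, the cecal
and serum concentration tables, and the immune-population frequency table —
can be generated here with the statistical structure the analysis assumes:

* overdispersed (gamma-Poisson) gene-family counts with per-sample depth
  variation, where the synthesis (S) and downstream (D) features of chosen
  vitamins encode a planted log2 S/D group difference δ between
  fiber-rich-like and fiber-free-like diets (downstream elevation for
  B2/B3/B7, synthesis reduction for B9, matching the directions the
  analysis is meant to recover);
* taxon strata over a small panel including mucin-associated taxa enriched
  under fiber deprivation, plus an "unclassified" remainder;
* log-normal metabolite concentrations with detection dropout, a planted
  set of microbiota-dependent metabolites absent in germ-free samples, and
  B vitamins elevated in colonized fiber-rich groups;
* immune frequencies with planted Pearson correlations against the log10
  B-vitamin concentrations via a shared latent factor.

All randomness flows from one integer seed through named substreams, so an
identical config reproduces identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import VitaminAnnotationTable, builtin_demo_annotation
from .integration import ImmuneFrequencyTable
from .metabolome import MetabolomeTable
from .transcripts import TOTAL, UNCLASSIFIED, StratifiedAbundanceTable

FIBER_RICH_DIETS = ("SC1", "SC2", "IN", "FS")
FF_LIKE_DIETS = ("FF",)

# directions the planted effects take in the fiber-free-like group
D_ELEVATED_IN_FF = ("B2", "B3", "B7")
S_REDUCED_IN_FF = ("B9",)

TAXON_PANEL = (
    "g__Bacteroides.s__Bacteroides_caccae",
    "g__Akkermansia.s__Akkermansia_muciniphila",
    "g__Eubacterium.s__Eubacterium_rectale",
    "g__Roseburia.s__Roseburia_intestinalis",
    "g__Lactobacillus.s__Lactobacillus_johnsonii",
)
MUCIN_TAXA = TAXON_PANEL[:2]

IMMUNE_POPULATIONS = (
    "Mast cells",
    "NK cells",
    "Th17",
    "Tregs",
    "B cells",
    "CD4 T cells",
    "CD8 T cells",
    "Macrophages",
    "Dendritic cells",
    "Neutrophils",
)
_BASE_FREQ = {
    "Mast cells": 1.5,
    "NK cells": 4.0,
    "Th17": 2.0,
    "Tregs": 3.0,
    "B cells": 25.0,
    "CD4 T cells": 20.0,
    "CD8 T cells": 12.0,
    "Macrophages": 8.0,
    "Dendritic cells": 3.0,
    "Neutrophils": 5.0,
}

METATRANSCRIPTOME_GROUPS = [("IN", "SPF", 4), ("SC2", "SPF", 4), ("FF", "SPF", 4)]
METABOLOME_GROUPS = [(d, "SPF", 4) for d in ("SC1", "SC2", "IN", "FS", "FF")] + [
    (d, c, 4) for c in ("14SM", "GF") for d in ("SC1", "FF")
]
# 24 colonized samples with both vitamin and immune measurements
CORRELATION_GROUPS = [(d, "SPF", 4) for d in ("SC1", "SC2", "IN", "FS", "FF")] + [
    ("SC1", "14SM", 4)
]


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort.

    ``planted_sd_effects`` maps vitamin code to the log2 S/D difference δ
    between fiber-rich-like and fiber-free-like groups (positive δ: the
    ratio is lower under fiber deprivation).  ``groups`` is a list of
    ``(diet, colonization, n)``; generators fall back to study-shaped
    palettes when it is None.
    """

    seed: int = 1
    groups: list[tuple[str, str, int]] | None = None
    n_features: int = 120
    n_metabolites: int = 150
    planted_sd_effects: dict[str, float] = field(
        default_factory=lambda: {"B2": 2.0, "B3": 2.0, "B7": 2.0, "B9": 2.0}
    )
    frac_microbiota_dependent: float = 0.3
    planted_correlations: list[tuple[str, str, float]] = field(
        default_factory=lambda: [
            ("B2", "Mast cells", -0.8),
            ("B3", "NK cells", -0.8),
            ("B5", "Th17", -0.8),
        ]
    )
    nb_dispersion: float = 0.03
    lognormal_sigma: float = 0.35
    detect_dropout: float = 0.10

    def __post_init__(self) -> None:
        if self.n_features <= 0 or self.n_metabolites <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.frac_microbiota_dependent <= 1.0:
            raise ValueError("frac_microbiota_dependent must lie in [0,1]")
        for vit, delta in self.planted_sd_effects.items():
            if not np.isfinite(delta):
                raise ValueError(f"non-finite delta for {vit}")
        for vit, pop, r in self.planted_correlations:
            if not abs(r) < 1.0:
                raise ValueError(f"target |r| must be < 1, got {r} for ({vit}, {pop})")
        if self.groups is not None:
            for d, c, n in self.groups:
                if n <= 0:
                    raise ValueError(f"group ({d},{c}) has n={n}")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def _expand(groups: list[tuple[str, str, int]]) -> pd.DataFrame:
    rows = []
    for diet, col, n in groups:
        for i in range(n):
            rows.append((f"{col}_{diet}_{i + 1}", diet, col, 1))
    meta = pd.DataFrame(rows, columns=["sample_id", "diet_group", "colonization", "batch"])
    return meta.set_index("sample_id")


def _is_ff_like(diet: str) -> bool:
    return diet in FF_LIKE_DIETS


def gen_metatranscriptome(
    cfg: SimConfig, ann: VitaminAnnotationTable | None = None
) -> tuple[StratifiedAbundanceTable, dict]:
    """Generate a taxon-stratified gene-family count table.

    Counts are gamma-Poisson with per-sample depth variation.  For each
    vitamin in ``cfg.planted_sd_effects``, the D features' expected share
    is multiplied by 2**δ in fiber-free-like samples (B2/B3/B7 style), or
    the S features' share by 2**−δ (B9 style), so the group difference in
    log2(S/D) equals δ in expectation.
    """
    ann = ann or builtin_demo_annotation()
    missing = set(cfg.planted_sd_effects) - ann.vitamins_covered
    if missing:
        raise ValueError(f"planted vitamins not covered by annotation: {sorted(missing)}")
    meta = _expand(cfg.groups or METATRANSCRIPTOME_GROUPS)
    rng = cfg.rng(1)

    bg_ids = [f"UniRef90_BG{i:05d}" for i in range(cfg.n_features)]
    ann_ids = sorted({r.feature_id for r in ann.records})
    features = bg_ids + ann_ids

    # baseline expected relative weights: heavy-tailed background,
    # moderate fixed shares for annotated features (S above D at baseline)
    base = {f: w for f, w in zip(bg_ids, rng.lognormal(0.0, 1.5, size=len(bg_ids)))}
    bg_total = sum(base.values())
    # scale background so it carries ~99% of the transcriptome
    for f in bg_ids:
        base[f] *= 0.99 * 1e6 / bg_total
    for rec in ann.records:
        n_role = max(len(ann.by_role(rec.vitamin, rec.role)), 1)
        share = {"S": 400.0, "D": 100.0, "T": 30.0}[rec.role] / n_role
        base[rec.feature_id] = base.get(rec.feature_id, 0.0) + share

    planted_truth = {}
    mean_matrix = np.empty((len(features), len(meta)))
    for j, (sid, row) in enumerate(meta.iterrows()):
        mult = {f: 1.0 for f in features}
        if _is_ff_like(row["diet_group"]):
            for vit, delta in cfg.planted_sd_effects.items():
                if vit in S_REDUCED_IN_FF:
                    for f in ann.by_role(vit, "S"):
                        mult[f] *= 2.0 ** (-delta)
                else:
                    for f in ann.by_role(vit, "D"):
                        mult[f] *= 2.0**delta
        mean_matrix[:, j] = [base[f] * mult[f] for f in features]
    for vit, delta in cfg.planted_sd_effects.items():
        planted_truth[vit] = {
            "delta": delta,
            "mechanism": "S_reduced_in_FF" if vit in S_REDUCED_IN_FF else "D_elevated_in_FF",
            "s_features": ann.by_role(vit, "S"),
            "d_features": ann.by_role(vit, "D"),
        }

    depth = rng.uniform(1e6, 4e6, size=len(meta))
    comp = mean_matrix / mean_matrix.sum(axis=0, keepdims=True)
    lam_mean = comp * depth[None, :]
    shape = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(shape, lam_mean / shape)
    counts = rng.poisson(lam).astype(float)

    # taxon strata: Dirichlet shares over the panel + unclassified;
    # mucin-associated taxa up-weighted under fiber deprivation.
    # Dirichlet drawn as normalized gammas, vectorized over features.
    n_tax = len(TAXON_PANEL)
    alpha_base = np.array([2.0, 1.5, 2.0, 1.5, 1.0, 2.0])  # panel + unclassified
    props = np.empty((len(features), n_tax + 1, len(meta)))
    for j, (_, mrow) in enumerate(meta.iterrows()):
        alpha = alpha_base.copy()
        if _is_ff_like(mrow["diet_group"]):
            alpha[:2] *= 3.0
        g = rng.gamma(alpha[None, :], 1.0, size=(len(features), n_tax + 1))
        props[:, :, j] = g / g.sum(axis=1, keepdims=True)

    rows, index = [], []
    for i, feat in enumerate(features):
        index.append((feat, TOTAL))
        rows.append(counts[i])
        strata = counts[i][None, :] * props[i, :n_tax, :]
        for t, tax in enumerate(TAXON_PANEL):
            index.append((feat, tax))
            rows.append(strata[t])
        index.append((feat, UNCLASSIFIED))
        rows.append(np.clip(counts[i] - strata.sum(axis=0), 0.0, None))

    data = pd.DataFrame(
        np.vstack(rows),
        index=pd.MultiIndex.from_tuples(index, names=["feature_id", "taxon"]),
        columns=list(meta.index),
    )
    table = StratifiedAbundanceTable(data, units="counts", sample_meta=meta)
    truth = {
        "planted_sd_effects": planted_truth,
        "ff_enriched_taxa": list(MUCIN_TAXA),
        "background_features": bg_ids,
    }
    return table, truth


BVITAMIN_METABOLITES = {
    "B1": "Thiamine",
    "B2": "Riboflavin",
    "B3": "Nicotinate",
    "B5": "Pantothenate",
    "B6": "Pyridoxal",
    "B7": "Biotin",
    "B9": "Folate",
    "B12": "Cobalamin",
}


def gen_metabolome(cfg: SimConfig) -> tuple[dict[str, MetabolomeTable], dict]:
    """Generate cecal and serum concentration tables.

    Log-normal concentrations with detection dropout; a planted fraction of
    metabolites is microbiota-dependent (never detected in germ-free
    samples, detected in at least one colonized sample); the eight
    B-vitamin metabolites are elevated in colonized fiber-rich groups and
    depressed in fiber-free/-supplemented-base groups and germ-free mice.
    """
    meta = _expand(cfg.groups or METABOLOME_GROUPS)
    rng = cfg.rng(2)

    bvit_names = [f"{name} ({code})" for code, name in BVITAMIN_METABOLITES.items()]
    n_bg = max(cfg.n_metabolites - len(bvit_names), 0)
    bg_names = [f"met_{i:04d}" for i in range(n_bg)]
    metabolites = bvit_names + bg_names

    n_md = int(round(cfg.frac_microbiota_dependent * n_bg))
    md_set = set(rng.choice(bg_names, size=n_md, replace=False)) if n_md else set()

    base_conc = pd.Series(rng.lognormal(np.log(50.0), 1.0, size=len(metabolites)), index=metabolites)

    tables: dict[str, MetabolomeTable] = {}
    latent: dict[str, pd.DataFrame] = {}
    for compartment in ("cecum", "serum"):
        conc = np.empty((len(metabolites), len(meta)))
        for j, (sid, row) in enumerate(meta.iterrows()):
            mult = np.ones(len(metabolites))
            colonized = row["colonization"] != "GF"
            fiber_rich = row["diet_group"] in ("SC1", "SC2", "IN")
            for i, m in enumerate(metabolites):
                if m in bvit_names:
                    if not colonized:
                        mult[i] = 0.5
                    elif fiber_rich:
                        mult[i] = 4.0
                    else:  # colonized FF / FS
                        mult[i] = 1.0
            conc[:, j] = base_conc.values * mult * rng.lognormal(0.0, cfg.lognormal_sigma, len(metabolites))
        frame = pd.DataFrame(conc, index=metabolites, columns=list(meta.index))
        latent[compartment] = frame.copy()

        # detection dropout, then structural missingness for the planted set
        drop = rng.random(frame.shape) < cfg.detect_dropout
        observed = frame.mask(drop)
        gf_cols = [c for c in frame.columns if meta.loc[c, "colonization"] == "GF"]
        col_cols = [c for c in frame.columns if meta.loc[c, "colonization"] != "GF"]
        if gf_cols:
            observed.loc[list(md_set), gf_cols] = np.nan
        # guarantees that keep the planted detection truth exact: every
        # non-dependent metabolite stays detected somewhere in each
        # colonization group, every dependent one somewhere in the
        # colonized samples of each diet it should appear under
        for group, cols in meta.groupby("colonization").groups.items():
            cols = list(cols)
            sub = observed.loc[:, cols]
            restorable = [m for m in metabolites if m not in md_set or group != "GF"]
            all_missing = sub.loc[restorable].isna().all(axis=1)
            for m in all_missing.index[all_missing]:
                observed.loc[m, cols[0]] = frame.loc[m, cols[0]]
        if col_cols:
            for diet, cols in meta.loc[col_cols].groupby("diet_group").groups.items():
                cols = list(cols)
                sub = observed.loc[list(md_set), cols]
                all_missing = sub.isna().all(axis=1)
                for m in all_missing.index[all_missing]:
                    observed.loc[m, cols[0]] = frame.loc[m, cols[0]]

        if compartment == "cecum":
            sf = rng.uniform(0.15, 0.35, size=len(meta))
        else:
            sf = rng.uniform(20.0, 40.0, size=len(meta))
        smeta = meta.copy()
        smeta["compartment"] = compartment
        smeta["size_factor"] = sf
        tables[compartment] = MetabolomeTable(observed, smeta)

    truth = {
        "microbiota_dependent": md_set,
        "bvitamin_metabolites": dict(zip(BVITAMIN_METABOLITES, bvit_names)),
        "latent_cecum": latent["cecum"],
    }
    return tables, truth


def gen_immune(
    cfg: SimConfig, metabolome: tuple[dict[str, MetabolomeTable], dict] | None = None
) -> ImmuneFrequencyTable:
    """Generate immune-population frequencies (% of CD45+ cells).

    Planted correlations are induced against the log10 cecal B-vitamin
    concentrations through a shared latent factor: for target correlation r
    the population is ``r·z + sqrt(1−r²)·ε`` on the standardized scale.
    Multiple targets on one population must satisfy Σr² < 1, otherwise the
    request is refused with the attainable bound.
    """
    if metabolome is None:
        metabolome = gen_metabolome(cfg)
    tables, truth = metabolome
    latent = truth["latent_cecum"]
    bmap = truth["bvitamin_metabolites"]
    rng = cfg.rng(3)
    samples = list(latent.columns)
    n = len(samples)

    by_pop: dict[str, list[tuple[str, float]]] = {}
    for vit, pop, r in cfg.planted_correlations:
        if pop not in IMMUNE_POPULATIONS:
            raise ValueError(f"unknown population {pop!r}")
        if vit not in bmap:
            raise ValueError(f"unknown vitamin {vit!r}")
        by_pop.setdefault(pop, []).append((vit, r))
    for pop, targets in by_pop.items():
        ssq = sum(r * r for _, r in targets)
        if ssq >= 1.0:
            raise ValueError(
                f"requested correlations for {pop!r} unattainable: sum r^2 = {ssq:.3f} "
                f"(attainable bound: sum r^2 < 1)"
            )

    def zscore(v: np.ndarray) -> np.ndarray:
        return (v - v.mean()) / v.std(ddof=0)

    freq = np.empty((len(IMMUNE_POPULATIONS), n))
    cv = 0.25
    for i, pop in enumerate(IMMUNE_POPULATIONS):
        eps = rng.standard_normal(n)
        if pop in by_pop:
            signal = np.zeros(n)
            ssq = 0.0
            for vit, r in by_pop[pop]:
                z = zscore(np.log10(latent.loc[bmap[vit]].to_numpy()))
                signal += r * z
                ssq += r * r
            std_val = signal + np.sqrt(1.0 - ssq) * eps
        else:
            std_val = eps
        freq[i] = _BASE_FREQ[pop] * (1.0 + cv * std_val)
    freq = np.clip(freq, 0.01, 100.0)
    data = pd.DataFrame(freq, index=list(IMMUNE_POPULATIONS), columns=samples)
    smeta = tables["cecum"].sample_meta.copy()
    return ImmuneFrequencyTable(data, sample_meta=smeta)


def write_genefamilies_tsv(table: StratifiedAbundanceTable, path) -> None:
    """Write the profiler-dialect TSV the reader consumes (round-trip safe)."""
    ids = [
        f if t == TOTAL else f"{f}|{t}"
        for f, t in table.data.index
    ]
    out = table.data.copy()
    out.insert(0, "# Gene Family", ids)
    out.to_csv(path, sep="\t", index=False)
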