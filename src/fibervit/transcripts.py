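"""Taxon-stratified metatranscriptome analysis of B-vitamin gene families.

The pipeline stage implemented here consumes the joined gene-family table a
metatranscriptome profiler emits (one row per gene family, with optional
per-taxon stratum rows written as ``FEATURE|taxon``), renormalizes it to
counts per million (CPM), aggregates annotated features into per-sample,
per-vitamin synthesis (S) and downstream-utilization (D) relative
abundances, forms the per-sample log2 S/D ratio with the plus-one
pseudocount rule, and compares groups with unpaired t tests.  Taxon
attribution is preserved throughout, with the unattributed remainder kept
as an explicit "unclassified" stratum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import VitaminAnnotationTable
from .statcore import GroupTestResult

logger = logging.getLogger(__name__)

TOTAL = "TOTAL"
UNCLASSIFIED = "unclassified"
_REL_TOL = 1e-6


def group_label(meta_row: pd.Series) -> str:
    """Canonical group label, e.g. ``SPF:FF``."""
    return f"{meta_row['colonization']}:{meta_row['diet_group']}"


@dataclass
class StratifiedAbundanceTable:
    """Feature-by-sample abundances with optional per-taxon strata.

    ``data`` is indexed by ``(feature_id, taxon)`` where the sentinel
    ``TOTAL`` marks the unstratified row; ``units`` is one of ``counts``,
    ``cpm`` or ``relab``.
    """

    data: pd.DataFrame
    units: str = "counts"
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.MultiIndex):
            raise ValueError("data must be indexed by (feature_id, taxon)")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.data.values < 0).any():
            raise ValueError("abundances must be nonnegative")
        self._validate_strata()

    def _validate_strata(self) -> None:
        strata = self.data[self.data.index.get_level_values("taxon") != TOTAL]
        if strata.empty:
            return
        ssum = strata.groupby(level="feature_id").sum()
        if TOTAL not in self.data.index.get_level_values("taxon"):
            raise ValueError(f"stratum rows without a TOTAL row: {sorted(ssum.index)}")
        totals = self.data.xs(TOTAL, level="taxon")
        missing = ssum.index.difference(totals.index)
        if len(missing):
            raise ValueError(f"stratum rows without a TOTAL row: {sorted(missing)}")
        tot = totals.loc[ssum.index]
        bad = (ssum.values > tot.values * (1 + _REL_TOL) + 1e-12).any(axis=1)
        if bad.any():
            raise ValueError(
                "stratified values exceed their TOTAL row for features: "
                f"{sorted(ssum.index[bad])}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def totals(self) -> pd.DataFrame:
        return self.data.xs(TOTAL, level="taxon")

    def strata(self) -> pd.DataFrame:
        return self.data[self.data.index.get_level_values("taxon") != TOTAL]


def read_genefamilies(
    path: str | Path, sample_meta: pd.DataFrame | None = None, units: str = "counts"
) -> StratifiedAbundanceTable:
    """Parse a profiler-style gene-family TSV.

    The first column holds feature IDs, with strata encoded as
    ``FEATURE|taxon`` (the header cell conventionally begins
    ``# Gene Family``); remaining columns are numeric, one per sample.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 1:
        raise ValueError("empty gene-family file")
    first = df.columns[0]
    ids = df[first].astype(str)
    values = df.drop(columns=[first])
    num = values.apply(pd.to_numeric, errors="coerce")
    if num.isna().values.any() and not values.isna().values.any():
        bad = np.argwhere(num.isna().values)
        r, c = bad[0]
        raise ValueError(
            f"malformed numeric cell at data row {r + 1}, sample {values.columns[c]!r}: "
            f"{values.iloc[r, c]!r}"
        )
    feats, taxa = [], []
    for fid in ids:
        if "|" in fid:
            f, t = fid.split("|", 1)
            feats.append(f)
            taxa.append(t)
        else:
            feats.append(fid)
            taxa.append(TOTAL)
    idx = pd.MultiIndex.from_arrays([feats, taxa], names=["feature_id", "taxon"])
    if idx.duplicated().any():
        dups = sorted(set(idx[idx.duplicated()]))
        raise ValueError(f"duplicated (feature, taxon) rows: {dups}")
    num.index = idx
    return StratifiedAbundanceTable(num.astype(float), units=units, sample_meta=sample_meta)


def to_cpm(table: StratifiedAbundanceTable) -> StratifiedAbundanceTable:
    """Rescale so each sample's TOTAL rows sum to 1e6 (counts per million).

    Stratum rows are scaled by the same per-sample factor, preserving the
    taxon decomposition.  Refuses tables already in CPM or relab units.
    """
    if table.units != "counts":
        raise ValueError(f"to_cpm expects counts, got units={table.units!r}")
    colsum = table.totals().sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero):
        raise ValueError(f"samples with zero total counts: {list(zero.index)}")
    scaled = table.data.div(colsum, axis=1) * 1e6
    return StratifiedAbundanceTable(scaled, units="cpm", sample_meta=table.sample_meta)


@dataclass
class VitaminRoleAbundance:
    """Per-sample, per-vitamin S and D relative abundances (% scale).

    ``unstratified``: long frame (sample, vitamin, role, relab);
    ``stratified``: the same with a taxon column, the "unclassified"
    stratum carrying the unattributed remainder.
    """

    unstratified: pd.DataFrame
    stratified: pd.DataFrame
    sample_meta: pd.DataFrame | None = None


def aggregate_vitamin_roles(
    table: StratifiedAbundanceTable,
    ann: VitaminAnnotationTable,
    transport_as_downstream: bool = False,
) -> VitaminRoleAbundance:
    """Sum annotated features into per-vitamin S and D relative abundances.

    With CPM input, a role's relative abundance for a sample is
    ``100 × (sum of CPM of its features) / 1e6`` — percent of all non-host
    mapped transcripts.  Transport (T) records are excluded unless
    ``transport_as_downstream`` merges them into D.  Taxon strata are summed
    per taxon; per feature, TOTAL minus the named strata feeds the
    "unclassified" stratum.
    """
    if table.units not in ("cpm", "relab"):
        raise ValueError(f"expected cpm or relab units, got {table.units!r}")
    to_pct = 100.0 / 1e6 if table.units == "cpm" else 1.0

    totals = table.totals()
    strata = table.strata()
    samples = table.sample_ids
    vitamins = sorted(ann.vitamins_covered)

    un_rows, st_rows = [], []
    for vit in vitamins:
        for role in ("S", "D"):
            feats = set(ann.by_role(vit, role))
            if role == "D" and transport_as_downstream:
                feats |= set(ann.by_role(vit, "T"))
            present = [f for f in feats if f in totals.index]
            absent = feats - set(present)
            if absent:
                logger.info("annotation features absent from table (%s/%s): %s", vit, role, sorted(absent))
            tot = (
                totals.loc[present].sum(axis=0) * to_pct
                if present
                else pd.Series(0.0, index=samples)
            )
            for s in samples:
                un_rows.append((s, vit, role, float(tot[s])))
            # taxon attribution: named strata plus the remainder
            taxon_sums: dict[str, pd.Series] = {}
            if present:
                sub = strata[strata.index.get_level_values("feature_id").isin(present)]
                rem = totals.loc[present].sum(axis=0)
                if not sub.empty:
                    by_tax = sub.groupby(level="taxon").sum()
                    for tax, row in by_tax.iterrows():
                        if tax == UNCLASSIFIED:
                            continue
                        taxon_sums[tax] = row * to_pct
                    # explicit "unclassified" rows fold into the remainder
                    rem = rem - sub[sub.index.get_level_values("taxon") != UNCLASSIFIED].sum(axis=0)
                taxon_sums[UNCLASSIFIED] = rem.clip(lower=0.0) * to_pct
            for tax, vals in taxon_sums.items():
                for s in samples:
                    st_rows.append((s, vit, role, tax, float(vals[s])))
    un = pd.DataFrame(un_rows, columns=["sample", "vitamin", "role", "relab"])
    st = pd.DataFrame(st_rows, columns=["sample", "vitamin", "role", "taxon", "relab"])
    return VitaminRoleAbundance(un, st, sample_meta=table.sample_meta)


@dataclass
class SDRatioTable:
    """Per-sample, per-vitamin S, D and log2 S/D ratio.

    ``table`` columns: sample, vitamin, S, D, log2_ratio,
    pseudocount_applied (per vitamin, over the whole analysis set).
    """

    table: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    scale: str = "relab"


def log2_sd_ratio(vra: VitaminRoleAbundance, pseudocount_scale: str = "relab") -> SDRatioTable:
    """Per-sample log2(S/D) with the plus-one pseudocount rule.

    For each vitamin, if any sample's downstream value is zero, one is
    added to S and D of *all* samples for that vitamin before taking
    log2((S+1)/(D+1)); otherwise the plain log2(S/D) is used.  The
    pseudocount is applied on the percent relative-abundance scale by
    default; ``pseudocount_scale="cpm"`` rescales to CPM first (the ratio
    is scale-free, so only the pseudocount magnitude differs).
    """
    if pseudocount_scale not in ("relab", "cpm"):
        raise ValueError("pseudocount_scale must be 'relab' or 'cpm'")
    factor = 1.0 if pseudocount_scale == "relab" else 1e4  # % -> CPM

    wide = vra.unstratified.pivot_table(
        index=["sample", "vitamin"], columns="role", values="relab", fill_value=0.0
    ).reset_index()
    for col in ("S", "D"):
        if col not in wide.columns:
            wide[col] = 0.0
    rows = []
    for vit, sub in wide.groupby("vitamin"):
        s = sub["S"].to_numpy() * factor
        d = sub["D"].to_numpy() * factor
        pseudo = bool((d == 0).any())
        if pseudo:
            ratio = np.log2((s + 1.0) / (d + 1.0))
        else:
            with np.errstate(divide="ignore"):
                ratio = np.log2(s / d)
        # S=0,D=0 cannot escape the pseudocount path, so 0/0 never occurs;
        # S=0 with D>0 legitimately yields -inf
        assert not np.isnan(ratio).any()
        for samp, sv, dv, r in zip(sub["sample"], sub["S"], sub["D"], ratio):
            rows.append((samp, vit, float(sv), float(dv), float(r), pseudo))
    out = pd.DataFrame(
        rows, columns=["sample", "vitamin", "S", "D", "log2_ratio", "pseudocount_applied"]
    )
    return SDRatioTable(out, sample_meta=vra.sample_meta, scale=pseudocount_scale)


def _samples_in_group(meta: pd.DataFrame, label: str) -> list[str]:
    full = meta.apply(group_label, axis=1)
    hit = meta.index[full == label]
    if len(hit) == 0:
        hit = meta.index[meta["diet_group"] == label]
    return list(hit)


def compare_sd(
    sdr: SDRatioTable, group_a: str, group_b: str
) -> dict[str, GroupTestResult]:
    """Two-sided unpaired t test on per-sample log2 S/D ratios, per vitamin.

    Group labels may be full ``colonization:diet`` labels or bare diet
    labels.  Direction is the sign of mean(a) − mean(b); vitamins with
    fewer than 2 samples in either group are skipped with a warning.
    ``p_adj`` is left to the caller's family-wise adjustment.
    """
    if sdr.sample_meta is None:
        raise ValueError("compare_sd needs sample metadata on the ratio table")
    a_ids = _samples_in_group(sdr.sample_meta, group_a)
    b_ids = _samples_in_group(sdr.sample_meta, group_b)
    if not a_ids or not b_ids:
        raise ValueError(f"empty group selection: {group_a!r} -> {len(a_ids)}, {group_b!r} -> {len(b_ids)}")
    out: dict[str, GroupTestResult] = {}
    for vit, sub in sdr.table.groupby("vitamin"):
        sub = sub.set_index("sample")
        a = sub.loc[sub.index.intersection(a_ids), "log2_ratio"].to_numpy()
        b = sub.loc[sub.index.intersection(b_ids), "log2_ratio"].to_numpy()
        if a.size < 2 or b.size < 2:
            logger.warning("vitamin %s skipped: group n<2 (%d vs %d)", vit, a.size, b.size)
            continue
        if np.ptp(np.concatenate([a, b])) == 0.0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        diff = float(a.mean() - b.mean())
        out[vit] = GroupTestResult(
            test_used="t_unpaired",
            statistic=float(t),
            p_raw=float(p),
            direction=math.copysign(1.0, diff) if diff != 0 else 0.0,
        )
    return out


def taxon_contributions(
    vra: VitaminRoleAbundance, vitamin: str, role: str
) -> pd.DataFrame:
    """Ranked per-group taxon contributions for one vitamin/role.

    Returns a long frame (group, taxon, mean_relab, sd_relab, rank) with
    taxa ranked by mean stratified relative abundance within each group;
    "unclassified" is reported as its own row.  Empty when no strata exist.
    """
    sub = vra.stratified[
        (vra.stratified["vitamin"] == vitamin) & (vra.stratified["role"] == role)
    ]
    if sub.empty:
        logger.warning("no strata for %s/%s", vitamin, role)
        return pd.DataFrame(columns=["group", "taxon", "mean_relab", "sd_relab", "rank"])
    if vra.sample_meta is None:
        groups = pd.Series("all", index=sub["sample"].unique())
    else:
        groups = vra.sample_meta.apply(group_label, axis=1)
    sub = sub.assign(group=sub["sample"].map(groups))
    agg = (
        sub.groupby(["group", "taxon"])["relab"]
        .agg(mean_relab="mean", sd_relab=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
        .reset_index()
    )
    agg["rank"] = agg.groupby("group")["mean_relab"].rank(ascending=False, method="first").astype(int)
    return agg.sort_values(["group", "rank"]).reset_index(drop=True)
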