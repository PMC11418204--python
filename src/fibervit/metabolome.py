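"""Metabolome preprocessing and set-based microbiota-dependence analysis.

Concentration tables (CE-TOFMS-style: metabolites × samples, missing cells
where a compound fell below detection) flow through:

1. a prevalence filter — keep a metabolite iff it was detected in at least
   half the samples of at least one experimental group (diet ×
   colonization);
2. normalization to the per-sample size factor (cecal weight in g or serum
   volume in µL), imputation of surviving missing cells at one-fifth of the
   metabolite's minimum observed normalized value, log10 transform, and
   per-metabolite autoscaling (mean 0, SD 1, sample SD with n−1);
3. reference-coded differential ranking with an overall F test per
   metabolite and Benjamini–Hochberg adjustment across metabolites;
4. Ward-ordered row ordering for heatmap display;
5. presence/absence set algebra across colonization states, yielding the
   "microbiota-dependent" metabolites: detected in colonized hosts
   (SPF ∪ 14SM) but never in germ-free hosts on the same diet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .statcore import bh_adjust

logger = logging.getLogger(__name__)

META_COLUMNS = ["diet_group", "colonization", "compartment", "size_factor"]


@dataclass
class MetabolomeTable:
    """Metabolite × sample concentrations plus per-sample metadata.

    ``data``: DataFrame, rows = metabolites, columns = sample IDs, NaN for
    not-detected.  ``sample_meta``: indexed by sample ID with columns
    diet_group, colonization, compartment, size_factor.
    """

    data: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ValueError(f"sample_meta missing columns {missing}")
        unknown = set(self.data.columns) - set(self.sample_meta.index)
        if unknown:
            raise ValueError(f"samples without metadata: {sorted(unknown)}")
        vals = self.data.values
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("concentrations must be nonnegative")
        if (self.sample_meta.loc[self.data.columns, "size_factor"] <= 0).any():
            raise ValueError("size_factor must be positive")
        comps = self.sample_meta.loc[self.data.columns, "compartment"].unique()
        if len(comps) > 1:
            raise ValueError(f"mixed compartments in one table: {list(comps)}")

    def group_of(self) -> pd.Series:
        m = self.sample_meta.loc[self.data.columns]
        return m["colonization"].astype(str) + ":" + m["diet_group"].astype(str)

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask: reported and strictly positive."""
        return self.data.notna() & (self.data > 0)


@dataclass
class ScaledMatrix:
    """Autoscaled (z-valued) metabolite × sample matrix with provenance."""

    data: pd.DataFrame
    normalized: bool = True
    log_base: int = 10
    imputation_rule: str = "min/5"
    dropped_zero_variance: list[str] = field(default_factory=list)


def prevalence_filter(table: MetabolomeTable) -> MetabolomeTable:
    """Keep metabolites detected in at least half of one experimental group.

    The rule is the integer inequality ``2 × detected_count(m, g) ≥ n_g``
    for at least one group g.  Idempotent; dropped metabolites are logged.
    """
    groups = table.group_of()
    det = table.detected()
    keep = pd.Series(False, index=table.data.index)
    for g, cols in groups.groupby(groups).groups.items():
        n_g = len(cols)
        if n_g == 0:
            raise ValueError(f"empty group {g}")
        keep |= 2 * det[list(cols)].sum(axis=1) >= n_g
    dropped = list(table.data.index[~keep])
    if dropped:
        logger.info("prevalence filter dropped %d metabolites: %s", len(dropped), dropped[:10])
    return MetabolomeTable(table.data.loc[keep], table.sample_meta)


def normalize_log_scale(table: MetabolomeTable) -> ScaledMatrix:
    """Size-factor normalize, impute, log10, and autoscale per metabolite.

    Each concentration is divided by its sample's size factor; missing
    cells surviving the prevalence filter are imputed at one-fifth of the
    metabolite's minimum observed normalized value; values are log10
    transformed and each metabolite row is z-scaled (mean 0, SD 1, ddof=1).
    Zero-variance rows are dropped and recorded in the provenance.
    """
    sf = table.sample_meta.loc[table.data.columns, "size_factor"].astype(float)
    norm = table.data.div(sf, axis=1)
    row_min = norm.min(axis=1, skipna=True)
    assert row_min.notna().all(), "all-missing metabolite reached scaling (filter not applied?)"
    fill = row_min / 5.0
    imputed = norm.apply(lambda row: row.fillna(fill[row.name]), axis=1)
    logv = np.log10(imputed)
    mu = logv.mean(axis=1)
    sd = logv.std(axis=1, ddof=1)
    zero_var = sd[sd == 0].index.tolist()
    if zero_var:
        logger.info("dropping %d zero-variance metabolites: %s", len(zero_var), zero_var[:10])
    keep = sd != 0
    z = logv.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return ScaledMatrix(z, dropped_zero_variance=zero_var)


def _moderated_f(z: pd.DataFrame, labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """One-way F per row with limma-style empirical-Bayes variance moderation.

    The residual variances are shrunk toward a pooled prior (method-of-
    moments fit of a scaled inverse chi-square), then the F statistic is
    recomputed with the moderated denominator and augmented df.
    """
    cats = labels.unique()
    n = z.shape[1]
    k = len(cats)
    grand = z.mean(axis=1)
    ss_between = pd.Series(0.0, index=z.index)
    ss_within = pd.Series(0.0, index=z.index)
    for c in cats:
        cols = labels.index[labels == c]
        sub = z[cols]
        m = sub.mean(axis=1)
        ss_between += len(cols) * (m - grand) ** 2
        ss_within += ((sub.sub(m, axis=0)) ** 2).sum(axis=1)
    df1, df2 = k - 1, n - k
    s2 = (ss_within / df2).to_numpy()
    # method-of-moments prior on log s^2
    ls = np.log(np.clip(s2, 1e-300, None))
    e, v = ls.mean(), ls.var(ddof=1)
    from scipy.special import polygamma

    # solve trigamma(d0/2) = max(v - trigamma(df2/2), eps) by bisection
    target = max(v - float(polygamma(1, df2 / 2)), 1e-8)
    lo, hi = 1e-3, 1e6
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if float(polygamma(1, mid / 2)) > target:
            lo = mid
        else:
            hi = mid
    d0 = 0.5 * (lo + hi)
    from scipy.special import digamma

    s0_2 = float(np.exp(e - float(digamma(df2 / 2)) + np.log(df2 / 2) + float(digamma(d0 / 2)) - np.log(d0 / 2)))
    s2_post = (d0 * s0_2 + df2 * s2) / (d0 + df2)
    f = (ss_between.to_numpy() / df1) / s2_post
    p = stats.f.sf(f, df1, df2 + d0)
    return f, p


def differential_rank(
    z: ScaledMatrix,
    groups: pd.Series,
    reference_group: str,
    k: int = 50,
    moderate: bool = False,
) -> pd.DataFrame:
    """Rank metabolites by a reference-coded group linear model.

    For each metabolite, z is modeled on the group factor with
    ``reference_group`` as baseline; the overall F p-value (identical to
    one-way ANOVA F) ranks metabolites, with BH adjustment across them.
    ``moderate=True`` switches to empirical-Bayes variance moderation.
    Returns the top ``k`` rows (all, with a log message, if k exceeds the
    metabolite count), columns: metabolite, statistic, p_raw, p_adj.
    """
    labels = groups.loc[z.data.columns]
    if reference_group not in set(labels):
        raise ValueError(f"reference group {reference_group!r} not present")
    if labels.nunique() < 2:
        raise ValueError("need >=2 groups")
    if moderate:
        f, p = _moderated_f(z.data, labels)
    else:
        arrays = [z.data[labels.index[labels == c]].to_numpy() for c in labels.unique()]
        f, p = stats.f_oneway(*arrays, axis=1)
    p = np.nan_to_num(np.asarray(p, dtype=float), nan=1.0)
    out = pd.DataFrame(
        {
            "metabolite": z.data.index,
            "statistic": np.asarray(f, dtype=float),
            "p_raw": p,
            "p_adj": bh_adjust(p),
        }
    )
    out = out.sort_values(["p_raw", "metabolite"], kind="stable").reset_index(drop=True)
    if k > len(out):
        logger.info("k=%d exceeds %d metabolites; returning all", k, len(out))
        k = len(out)
    return out.head(k)


@dataclass
class DetectionSets:
    """Per-group detected-metabolite sets and exclusive intersection regions.

    ``sets`` maps group name (e.g. colonization state) to its detected set;
    ``regions`` maps a '+'-joined sorted membership string (e.g.
    ``"14SM+SPF"``) to the metabolites exclusive to exactly that set
    combination.
    """

    sets: dict[str, set[str]]
    regions: dict[str, set[str]]

    def region_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}


def detection_sets(tables: dict[str, MetabolomeTable], diet: str | None = None) -> DetectionSets:
    """Presence/absence set analysis across colonization states.

    ``tables`` maps group name (typically colonization: SPF / 14SM / GF) to
    its table; ``diet`` optionally restricts each table's samples to one
    diet group.  A metabolite is "present in a group" if detected
    (non-missing, > 0) in at least one of its samples.  All tables must
    share one metabolite universe.
    """
    universes = {name: set(t.data.index) for name, t in tables.items()}
    names = sorted(universes)
    base = universes[names[0]]
    for name in names[1:]:
        if universes[name] != base:
            only_a = sorted(base - universes[name])[:5]
            only_b = sorted(universes[name] - base)[:5]
            raise ValueError(
                f"inconsistent metabolite universes: only in {names[0]}: {only_a}; "
                f"only in {name}: {only_b}"
            )
    sets: dict[str, set[str]] = {}
    for name, t in tables.items():
        det = t.detected()
        if diet is not None:
            cols = [c for c in t.data.columns if t.sample_meta.loc[c, "diet_group"] == diet]
            if not cols:
                raise ValueError(f"no samples of diet {diet!r} in table {name!r}")
            det = det[cols]
        sets[name] = set(det.index[det.any(axis=1)])

    regions: dict[str, set[str]] = {}
    group_names = sorted(sets)
    for r in range(1, len(group_names) + 1):
        for combo in combinations(group_names, r):
            inside = set.intersection(*(sets[g] for g in combo))
            outside = set.union(set(), *(sets[g] for g in group_names if g not in combo))
            excl = inside - outside
            if excl or r > 0:
                regions["+".join(combo)] = excl
    return DetectionSets(sets=sets, regions=regions)


def colonized_only(sets: DetectionSets) -> tuple[set[str], int]:
    """Microbiota-dependent metabolites: (SPF ∪ 14SM) \\ GF, with count."""
    for g in ("SPF", "14SM", "GF"):
        if g not in sets.sets:
            raise ValueError(f"missing colonization group {g!r}")
    result = (sets.sets["SPF"] | sets.sets["14SM"]) - sets.sets["GF"]
    return result, len(result)


def ward_order(z: ScaledMatrix | pd.DataFrame) -> np.ndarray:
    """Row ordering from Ward-linkage clustering on Euclidean distances.

    Returns the dendrogram leaf order (a permutation of row indices) of
    agglomerative Ward.D2 clustering; a single row yields the identity.
    Deterministic for a given input row order.
    """
    data = z.data if isinstance(z, ScaledMatrix) else z
    n = data.shape[0]
    if n == 0:
        return np.array([], dtype=int)
    if n == 1:
        return np.array([0])
    link = linkage(data.to_numpy(), method="ward")
    return np.asarray(leaves_list(link), dtype=int)
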