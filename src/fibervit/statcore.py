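"""Shared statistical primitives.

Every downstream stage funnels its inference through the four operations
here: robust outlier exclusion (ROUT at FDR rate Q), the normality-gated
choice between heteroscedastic ANOVA and the Kruskal–Wallis test,
Benjamini–Hochberg adjustment, and Pearson correlation with a two-sided
p-value.  Keeping them in one module makes the gating rules auditable and
lets the rest of the package stay free of inference logic.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

SHAPIRO_ALPHA = 0.05


@dataclass
class GroupedValues:
    """Measurements for one experimental group (diet × colonization)."""

    group_label: str
    values: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_ids is None:
            self.sample_ids = [f"{self.group_label}_{i}" for i in range(self.values.size)]
        if len(self.sample_ids) != self.values.size:
            raise ValueError("sample_ids must align with values")


@dataclass
class OutlierReport:
    """Result of ROUT outlier detection on one vector.

    ``flagged`` is aligned with the input; ``q`` is the FDR rate the scan
    was run at; ``method_detail`` spells out the robust-fit variant so the
    exclusion is reproducible from the report alone.
    """

    flagged: np.ndarray
    q: float
    method_detail: str
    rsdr: float = float("nan")

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())


@dataclass
class GroupTestResult:
    """Outcome of a gated group comparison.

    ``p_adj`` stays NaN until :func:`bh_adjust` is applied across a family
    of tests; the caller owns the family definition.
    """

    test_used: str  # welch_anova | brown_forsythe | kruskal_wallis | t_unpaired
    statistic: float
    p_raw: float
    p_adj: float = float("nan")
    normality_p_per_group: np.ndarray = field(default_factory=lambda: np.array([]))
    brown_forsythe_statistic: float = float("nan")
    brown_forsythe_p: float = float("nan")
    direction: float = float("nan")
    n_outliers_removed: int = 0


_ROUT_DETAIL = (
    "univariate ROUT: robust location = median (constant model, K=1); "
    "RSDR = 68.27th percentile of |residuals| x n/(n-K); per-point two-sided "
    "t p-values with df=n-K; Benjamini-Hochberg step-up on those p-values at "
    "rate Q decides the flagged set"
)


def rout_outliers(values: Sequence[float], q: float = 0.01) -> OutlierReport:
    """Flag outliers in a single vector with the ROUT procedure.

    The method fits a robust constant model (the median), estimates a robust
    standard deviation of the residuals (RSDR) from the 68.27th percentile of
    the absolute residuals with the n/(n−K) small-sample correction, converts
    each residual to a two-sided t p-value (df = n−K), and flags the
    Benjamini–Hochberg rejection set at rate Q: with p-values sorted
    ascending, every point up to the largest rank i with p(i) ≤ Q·i/n.

    Parameters
    ----------
    values : sequence of float
        At least 3 finite observations.
    q : float
        FDR rate in (0, 1); the study convention is Q = 0.01 (1%).
    """
    x = np.asarray(values, dtype=float)
    if not (0.0 < q < 1.0):
        raise ValueError(f"q must lie in (0,1), got {q}")
    if x.size < 3 or not np.all(np.isfinite(x)):
        raise ValueError("insufficient-n: ROUT needs >=3 finite values")

    n = x.size
    resid = x - np.median(x)
    abs_resid = np.abs(resid)
    flagged = np.zeros(n, dtype=bool)

    # K = 1 parameter (the constant); small-sample correction n/(n-K)
    p6827 = float(np.percentile(abs_resid, 68.27))
    rsdr = p6827 * n / (n - 1)

    if rsdr == 0.0:
        # zero-spread (all identical, or >68% tied at the median): nothing
        # can be scored against a zero scale — flag nothing, explicitly.
        return OutlierReport(flagged=flagged, q=q, method_detail=_ROUT_DETAIL, rsdr=0.0)

    df = n - 1
    pvals = 2.0 * stats.t.sf(abs_resid / rsdr, df)
    order = np.argsort(pvals, kind="stable")
    thresholds = q * np.arange(1, n + 1) / n
    passed = pvals[order] <= thresholds
    if passed.any():
        cutoff = int(np.max(np.nonzero(passed)[0]))
        flagged[order[: cutoff + 1]] = True
    return OutlierReport(flagged=flagged, q=q, method_detail=_ROUT_DETAIL, rsdr=rsdr)


def _welch_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA (textbook formulas)."""
    k = len(groups)
    ns = np.array([g.size for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    vars_ = np.array([g.var(ddof=1) for g in groups])
    if np.any(vars_ == 0):
        # Degenerate within-group spread; handled by the caller's gate in
        # practice (zero-variance groups are routed to Kruskal–Wallis), but
        # the identical-groups case must still produce F=0, p=1.
        if np.allclose(means, means[0]):
            return 0.0, 1.0
        return float("inf"), 0.0
    w = ns / vars_
    sw = w.sum()
    grand = (w * means).sum() / sw
    num = ((w * (means - grand) ** 2).sum()) / (k - 1)
    lam = (3.0 * ((1 - w / sw) ** 2 / (ns - 1)).sum()) / (k**2 - 1)
    f = num / (1.0 + 2.0 * lam * (k - 2) / 3.0)
    df1 = k - 1
    df2 = 1.0 / lam if lam > 0 else np.inf
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return float(f), p


def _brown_forsythe_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Brown–Forsythe F* ANOVA (unequal variances, adjusted denominator)."""
    ns = np.array([g.size for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    vars_ = np.array([g.var(ddof=1) for g in groups])
    grand = np.concatenate(groups).mean()
    num = (ns * (means - grand) ** 2).sum()
    den = ((1.0 - ns / ns.sum()) * vars_).sum()
    if den == 0:
        if np.allclose(means, means[0]):
            return 0.0, 1.0
        return float("inf"), 0.0
    fstar = num / den
    c = (1.0 - ns / ns.sum()) * vars_ / den
    df2 = 1.0 / (c**2 / (ns - 1)).sum()
    df1 = len(groups) - 1
    return float(fstar), float(stats.f.sf(fstar, df1, df2))


def normality_gated_test(groups: list[GroupedValues]) -> GroupTestResult:
    """Compare ≥2 groups with the Shapiro–Wilk-gated test choice.

    Each group is tested for normality (Shapiro–Wilk, α = 0.05).  If every
    group passes, the heteroscedastic ANOVA branch is taken: Welch's ANOVA
    p-value is the decision p, and the Brown–Forsythe F* is reported
    alongside.  If any group fails — or has zero variance, where
    Shapiro–Wilk is undefined — the Kruskal–Wallis test is used instead.
    """
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    arrays = [np.asarray(g.values, dtype=float) for g in groups]
    for g, a in zip(groups, arrays):
        if a.size < 3:
            raise ValueError(f"group {g.group_label} has n<3")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"group {g.group_label} contains non-finite values")

    norm_p = np.empty(len(arrays))
    degenerate = False
    for i, a in enumerate(arrays):
        if np.ptp(a) == 0.0:
            norm_p[i] = np.nan
            degenerate = True
            logger.warning(
                "group %s has zero variance; Shapiro-Wilk undefined, "
                "routing to Kruskal-Wallis",
                groups[i].group_label,
            )
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                norm_p[i] = stats.shapiro(a).pvalue

    all_normal = (not degenerate) and bool(np.all(norm_p > SHAPIRO_ALPHA))
    if all_normal:
        f, p = _welch_anova(arrays)
        bf_f, bf_p = _brown_forsythe_anova(arrays)
        return GroupTestResult(
            test_used="welch_anova",
            statistic=f,
            p_raw=p,
            normality_p_per_group=norm_p,
            brown_forsythe_statistic=bf_f,
            brown_forsythe_p=bf_p,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            h, p = stats.kruskal(*arrays)
        except ValueError:  # all values identical across every group
            h, p = 0.0, 1.0
    return GroupTestResult(
        test_used="kruskal_wallis",
        statistic=float(h),
        p_raw=float(p),
        normality_p_per_group=norm_p,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Delegates to statsmodels' ``fdr_bh``; inputs outside [0, 1] are refused.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with its two-sided p-value (t transform).

    Zero-variance input yields the undefined-correlation sentinel
    ``(nan, nan)`` rather than an error, so correlation matrices with
    degenerate cells stay well-formed.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need equal-length vectors with n>=3")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValueError("non-finite values")
    if np.ptp(xa) == 0.0 or np.ptp(ya) == 0.0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(xa, ya)
    r = float(np.clip(r, -1.0, 1.0))
    # exact affine dependence should give exactly +/-1 (snap fp round-off)
    if 1.0 - abs(r) < 1e-12:
        r = math.copysign(1.0, r)
        p = 0.0
    return r, float(p)
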