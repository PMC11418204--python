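"""Correlation of cecal B-vitamin concentrations with immune-cell frequencies.

Vitamin concentrations are log10-transformed and correlated (Pearson)
against immune-population frequencies expressed as percent of CD45+ cells.
The pairing of observations honors the study design: groups with matched
per-mouse measurements are joined on sample ID; groups where matched values
are unavailable can be pooled, pairing samples by within-group rank after
sorting by sample ID.  A strict mode drops unmatched groups instead.
Significance is Benjamini–Hochberg-adjusted across every matrix cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metabolome import MetabolomeTable
from .statcore import bh_adjust, pearson_with_p

logger = logging.getLogger(__name__)


@dataclass
class ImmuneFrequencyTable:
    """Immune populations × samples, as percent of CD45+ cells."""

    data: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate population names")
        vals = self.data.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("frequencies must lie in [0, 100]")


@dataclass
class CorrelationMatrix:
    """Vitamin × population Pearson matrix with BH-gated significance."""

    r: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    significant: pd.DataFrame
    pairing_mode: dict[str, str] = field(default_factory=dict)
    n_pairs: int = 0

    def to_long(self) -> pd.DataFrame:
        rows = []
        for vit in self.r.index:
            for pop in self.r.columns:
                rows.append(
                    (
                        vit,
                        pop,
                        self.r.loc[vit, pop],
                        self.p_raw.loc[vit, pop],
                        self.p_adj.loc[vit, pop],
                        bool(self.significant.loc[vit, pop]),
                    )
                )
        return pd.DataFrame(
            rows, columns=["vitamin", "population", "r", "p_raw", "p_adj", "significant"]
        )


def _assemble_pairs(
    met: MetabolomeTable,
    imm: ImmuneFrequencyTable,
    pairing: dict[str, str],
    default_mode: str,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Column-align the two tables into one paired observation set."""
    if imm.sample_meta is None:
        raise ValueError("immune table needs sample metadata for group pairing")
    met_groups = met.group_of()
    imm_meta = imm.sample_meta.loc[imm.data.columns]
    imm_groups = imm_meta["colonization"].astype(str) + ":" + imm_meta["diet_group"].astype(str)

    met_cols: list[str] = []
    imm_cols: list[str] = []
    modes: dict[str, str] = {}
    for g in sorted(set(met_groups) & set(imm_groups)):
        mode = pairing.get(g, default_mode)
        m_ids = sorted(met_groups.index[met_groups == g])
        i_ids = sorted(imm_groups.index[imm_groups == g])
        if mode == "matched":
            shared = sorted(set(m_ids) & set(i_ids))
            if not shared:
                raise ValueError(f"matched group {g!r} has no overlapping sample IDs")
            met_cols += shared
            imm_cols += shared
            modes[g] = "matched"
        elif mode == "pooled":
            # rank pairing: i-th metabolome sample with i-th immune sample
            # (both sorted by sample ID); surplus samples dropped with a log.
            k = min(len(m_ids), len(i_ids))
            if len(m_ids) != len(i_ids):
                logger.warning(
                    "pooled group %s: unequal sizes (%d vs %d), pairing first %d",
                    g, len(m_ids), len(i_ids), k,
                )
            met_cols += m_ids[:k]
            imm_cols += i_ids[:k]
            modes[g] = "pooled"
        elif mode == "strict":
            logger.info("strict mode: dropping unmatched group %s", g)
            modes[g] = "dropped"
        else:
            raise ValueError(f"unknown pairing mode {mode!r} for group {g!r}")
    if not met_cols:
        raise ValueError("no paired observations assembled")
    return met.data[met_cols], imm.data[imm_cols], modes


def bvitamin_immune_correlation(
    met: MetabolomeTable,
    imm: ImmuneFrequencyTable,
    pairing: dict[str, str] | None = None,
    default_mode: str = "matched",
    alpha: float = 0.05,
) -> CorrelationMatrix:
    """Pearson correlation matrix between log10 vitamin levels and frequencies.

    ``met`` should already be restricted to the B-vitamin metabolites (its
    rows become the matrix rows).  ``pairing`` maps group labels
    (``colonization:diet``) to a mode in {"matched", "pooled", "strict"};
    unlisted groups use ``default_mode``.  Cells with zero variance get the
    NaN sentinel and are never flagged significant.
    """
    vit_block, imm_block, modes = _assemble_pairs(met, imm, pairing or {}, default_mode)
    if vit_block.shape[1] < 3:
        raise ValueError("need >=3 paired observations")
    with np.errstate(divide="ignore"):
        logv = np.log10(vit_block.where(vit_block > 0))

    vitamins = list(met.data.index)
    pops = list(imm.data.index)
    r = pd.DataFrame(np.nan, index=vitamins, columns=pops)
    p = pd.DataFrame(np.nan, index=vitamins, columns=pops)
    for vit in vitamins:
        x_all = logv.loc[vit].to_numpy(dtype=float)
        for pop in pops:
            y_all = imm_block.loc[pop].to_numpy(dtype=float)
            ok = np.isfinite(x_all) & np.isfinite(y_all)
            if ok.sum() < 3:
                continue
            r.loc[vit, pop], p.loc[vit, pop] = pearson_with_p(x_all[ok], y_all[ok])

    flat = p.to_numpy().ravel()
    defined = np.isfinite(flat)
    adj = np.full_like(flat, np.nan)
    if defined.any():
        adj[defined] = bh_adjust(flat[defined])
    p_adj = pd.DataFrame(adj.reshape(p.shape), index=vitamins, columns=pops)
    significant = (p_adj < alpha).fillna(False).astype(bool)
    return CorrelationMatrix(
        r=r, p_raw=p, p_adj=p_adj, significant=significant,
        pairing_mode=modes, n_pairs=vit_block.shape[1],
    )
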