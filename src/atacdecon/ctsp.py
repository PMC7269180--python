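"""Cell-type-specific peak (CTSP) detection.

A CTSP is an open-chromatin region significantly more accessible in one
cell type than in every other. Each feature's candidate type is the cell
type with the highest mean intensity; significance is an intersection-union
test (IUT) built from one-sided Welch two-sample t-tests of candidate >
other, combined by taking the maximum p-value — the feature is specific
only if it beats every other type. Candidates are ranked by the pi-value,
log2 fold change (candidate over runner-up, pseudocount 1) times
-log10(p), which balances effect size against significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import ReferenceProfile

__all__ = ["CTSPStat", "test_ctsp", "call_ctsps", "ctsp_table"]

_P_FLOOR = 1e-300  # keeps -log10(p) finite when a test saturates
_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class CTSPStat:
    feature_id: str
    cell_type: str
    log2_fc: float
    p_iut: float
    pi_value: float


def _group_stats(profile: ReferenceProfile):
    """Per-cell-type mean, variance and replicate count matrices."""
    types = profile.cell_types
    arr = profile.values
    means, variances, counts = {}, {}, {}
    for ct in types:
        cols = profile.samples_of(ct)
        if len(cols) < 2:
            raise ValueError(
                f"cell type {ct!r} has {len(cols)} replicate(s); >= 2 required "
                "(within-type variance is undefined otherwise)"
            )
        sub = arr[cols].to_numpy(dtype=float)
        means[ct] = sub.mean(axis=1)
        variances[ct] = sub.var(axis=1, ddof=1)
        counts[ct] = len(cols)
    m = np.column_stack([means[ct] for ct in types])
    v = np.column_stack([variances[ct] for ct in types])
    n = np.array([counts[ct] for ct in types])
    return types, m, v, n


def _welch_p_greater(m1, v1, n1, m2, v2, n2):
    """Vectorized one-sided Welch t-test p-values for mean1 > mean2."""
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = np.where(
        se2 > 0,
        stats.t.sf(np.where(se2 > 0, t, 0.0), np.where(se2 > 0, df, 1.0)),
        # both groups constant: p = 0 if strictly greater, else 1
        np.where(m1 > m2, 0.0, 1.0),
    )
    return np.clip(p, _P_FLOOR, 1.0)


def _all_stats(profile: ReferenceProfile) -> pd.DataFrame:
    types, m, v, n = _group_stats(profile)
    k = len(types)
    cand = np.argmax(m, axis=1)
    rows = np.arange(m.shape[0])
    p_iut = np.zeros(m.shape[0])
    for j in range(k):
        pj = _welch_p_greater(
            m[rows, cand], v[rows, cand], n[cand], m[:, j], v[:, j], n[j]
        )
        pj = np.where(cand == j, 0.0, pj)  # skip candidate-vs-itself
        p_iut = np.maximum(p_iut, pj)
    p_iut = np.clip(p_iut, _P_FLOOR, 1.0)
    # runner-up mean: second-highest per feature
    m_masked = m.copy()
    m_masked[rows, cand] = -np.inf
    runner_up = m_masked.max(axis=1)
    log2_fc = np.log2((m[rows, cand] + _PSEUDOCOUNT) / (runner_up + _PSEUDOCOUNT))
    pi = np.where(log2_fc > 0, log2_fc * (-np.log10(p_iut)), 0.0)
    return pd.DataFrame(
        {
            "feature_id": profile.feature_ids,
            "cell_type": [types[c] for c in cand],
            "log2_fc": log2_fc,
            "p_iut": p_iut,
            "pi_value": pi,
        }
    )


def test_ctsp(profile: ReferenceProfile, feature_id: str) -> CTSPStat:
    """IUT statistics for a single feature (see module docstring)."""
    if feature_id not in profile.values.index:
        raise KeyError(f"unknown feature: {feature_id}")
    sub = profile.replace_values(profile.values.loc[[feature_id]])
    row = _all_stats(sub).iloc[0]
    return CTSPStat(
        feature_id=feature_id,
        cell_type=row["cell_type"],
        log2_fc=float(row["log2_fc"]),
        p_iut=float(row["p_iut"]),
        pi_value=float(row["pi_value"]),
    )


def call_ctsps(
    profile: ReferenceProfile,
    max_p: float = 0.05,
    bh_adjust: bool = False,
) -> dict[str, list[CTSPStat]]:
    """Call CTSPs for every cell type, ranked by pi-value.

    Each feature is assigned to at most one cell type (its intensity
    argmax) and reported there only if its IUT p-value is below ``max_p``
    and the fold change over the runner-up type is positive. Setting
    ``bh_adjust`` applies Benjamini-Hochberg to the p-values within each
    cell type before thresholding (ranking is the default goal, so the
    adjustment is off by default).
    """
    if not 0 < max_p <= 1:
        raise ValueError("max_p must be in (0, 1]")
    table = _all_stats(profile)
    out: dict[str, list[CTSPStat]] = {ct: [] for ct in profile.cell_types}
    for ct, grp in table.groupby("cell_type", sort=False):
        p = grp["p_iut"].to_numpy()
        if bh_adjust and len(p):
            p = stats.false_discovery_control(p, method="bh")
        keep = (p < max_p) & (grp["log2_fc"].to_numpy() > 0)
        sel = grp.loc[keep].assign(p_adj=p[keep]).sort_values(
            ["pi_value", "feature_id"], ascending=[False, True]
        )
        out[ct] = [
            CTSPStat(r.feature_id, r.cell_type, r.log2_fc, r.p_iut, r.pi_value)
            for r in sel.itertuples(index=False)
        ]
    for ct, lst in out.items():
        if not lst:
            warnings.warn(f"no CTSPs pass max_p={max_p} for cell type {ct!r}", stacklevel=2)
    return out


def ctsp_table(ctsps: dict[str, list[CTSPStat]]) -> pd.DataFrame:
    """Flatten grouped CTSPs into a writable table."""
    rows = [
        (s.feature_id, s.cell_type, s.log2_fc, s.p_iut, s.pi_value)
        for lst in ctsps.values()
        for s in lst
    ]
    return pd.DataFrame(
        rows, columns=["feature_id", "cell_type", "log2_fc", "p_iut", "pi_value"]
    )
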