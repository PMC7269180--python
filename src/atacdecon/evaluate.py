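"""Deconvolution scoring: RMSE, Pearson correlation, Wasserstein p-value.

When the true composition is known, root-mean-square error and Pearson
correlation between predicted and true fractions quantify accuracy. With
or without truth, a Monte-Carlo goodness-of-fit p-value asks whether the
reconstruction B f-hat matches the observed mixture better than chance:
the observed Wasserstein-1 distance between the value distributions of m
and B f-hat is compared against a null of random compositions drawn
uniformly from the simplex (Dirichlet(1)) and pushed through the same
signature. Smaller distances than the null yield smaller p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rmse", "pcc", "wasserstein_pvalue", "DeconvolutionReport", "evaluate_deconvolution"]


def rmse(f_p: np.ndarray, f_t: np.ndarray) -> float:
    """Root-mean-square error between prediction and truth."""
    f_p = np.asarray(f_p, dtype=float)
    f_t = np.asarray(f_t, dtype=float)
    if f_p.shape != f_t.shape:
        raise ValueError(f"length mismatch: {f_p.shape} vs {f_t.shape}")
    return float(np.sqrt(np.mean((f_p - f_t) ** 2)))


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation; NaN when either side is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 points for a correlation")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def wasserstein_pvalue(
    m: np.ndarray,
    m_hat: np.ndarray,
    signature_values: np.ndarray,
    n_draws: int = 1000,
    seed: int = 42,
    asymptotic: bool = False,
) -> dict[str, float]:
    """Monte-Carlo goodness-of-fit p-value from the Wasserstein-1 distance.

    ``signature_values`` is the (transformed) features x cell-types matrix
    used in the fit; the null draws f ~ Dirichlet(1, ..., 1) over the cell
    types and scores B f against the observed m. The p-value uses the
    add-one estimator p = (1 + #{d_null <= d_obs}) / (n_draws + 1), so it
    lies in [1/(n_draws+1), 1] and is never zero. With ``asymptotic=True``
    a normal approximation to the null distances replaces the empirical
    count (p = Phi((d_obs - mean)/sd), clipped to the same bounds).
    """
    m = np.asarray(m, dtype=float)
    m_hat = np.asarray(m_hat, dtype=float)
    if m.shape != m_hat.shape:
        raise ValueError("m and m_hat must have the same length")
    if n_draws < 99:
        raise ValueError("n_draws must be >= 99")
    B = np.asarray(signature_values, dtype=float)
    d_obs = float(stats.wasserstein_distance(m, m_hat))
    rng = np.random.default_rng(seed)
    F = rng.dirichlet(np.ones(B.shape[1]), size=n_draws)  # n_draws x k
    null_mixes = B @ F.T  # features x n_draws
    m_sorted = np.sort(m)
    null_sorted = np.sort(null_mixes, axis=0)
    # equal-length empirical Wasserstein-1 = mean |sorted difference|
    d_null = np.mean(np.abs(null_sorted - m_sorted[:, None]), axis=0)
    if asymptotic:
        sd = d_null.std(ddof=1)
        z = (d_obs - d_null.mean()) / sd if sd > 0 else np.inf * np.sign(d_obs - d_null.mean())
        pvalue = float(np.clip(stats.norm.cdf(z), 1 / (n_draws + 1), 1.0))
    else:
        pvalue = (1 + int(np.sum(d_null <= d_obs))) / (n_draws + 1)
    return {"wasserstein_d": d_obs, "pvalue": float(pvalue)}


@dataclass
class DeconvolutionReport:
    per_mixture: pd.DataFrame  # mixture_id, rmse, pcc, wasserstein_d, pvalue
    mean_rmse: float | None
    pooled_pcc: float | None


def evaluate_deconvolution(
    estimates,
    truth: pd.DataFrame | None = None,
    mixtures=None,
    signature=None,
    n_draws: int = 1000,
    seed: int = 42,
) -> DeconvolutionReport:
    """Score a list of :class:`~atacdecon.deconv.ProportionEstimate`.

    ``truth`` (mixtures x cell types, aligned by labels) enables per-mixture
    RMSE/PCC and the pooled statistics; supplying the original ``mixtures``
    and ``signature`` enables the Wasserstein p-value (computed in the same
    transform space the fit used). Either part may be omitted.
    """
    from .transform import snap_and_apply

    rows = []
    truths, preds = [], []
    for est in estimates:
        row: dict[str, object] = {"mixture_id": est.mixture_id}
        if truth is not None:
            f_t = truth.loc[est.mixture_id, est.cell_types].to_numpy(dtype=float)
            row["rmse"] = rmse(est.fractions, f_t)
            row["pcc"] = pcc(est.fractions, f_t) if len(f_t) >= 3 else float("nan")
            truths.append(f_t)
            preds.append(est.fractions)
        if mixtures is not None and signature is not None and not est.degenerate:
            shared = [f for f in signature.feature_ids if f in set(mixtures.feature_ids)]
            B = signature.values.loc[shared]
            m = mixtures.values.loc[shared, est.mixture_id]
            spec = getattr(est, "transform", None)
            if spec is not None:
                (m_df, B), _ = snap_and_apply(spec, m.to_frame(), B)
                m = m_df.iloc[:, 0]
            m_hat = B.to_numpy() @ est.fractions
            row.update(
                wasserstein_pvalue(m.to_numpy(), m_hat, B.to_numpy(), n_draws, seed)
            )
        rows.append(row)
    per_mixture = pd.DataFrame(rows)
    if truth is not None and truths:
        all_t = np.concatenate(truths)
        all_p = np.concatenate(preds)
        return DeconvolutionReport(
            per_mixture=per_mixture,
            mean_rmse=float(per_mixture["rmse"].mean()),
            pooled_pcc=pcc(all_p, all_t),
        )
    return DeconvolutionReport(per_mixture=per_mixture, mean_rmse=None, pooled_pcc=None)
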