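"""Mixture deconvolution: solve m = B f with SIMPLS regression.

Per mixture sample the signature matrix B (rows: shared features, columns:
cell types) is the predictor block and the mixture column m the response.
SIMPLS — de Jong's statistically inspired modification of PLS — extracts
components directly from the predictor-response cross-product matrix
S = X'Y, deflating S itself (not X) by projecting out the orthonormalized
X-loadings. With as many components as cell types on a well-conditioned B
the fit coincides with least squares, while remaining stable when lineage-
adjacent cell types make B near-collinear. Negative coefficients are
clipped to zero and the remainder renormalized to sum to one, giving the
proportion vector f.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import MixtureMatrix
from .signature import SignatureMatrix
from .transform import TransformSpec, snap_and_apply

__all__ = [
    "ProportionEstimate",
    "simpls_fit",
    "clip_to_proportions",
    "estimate_proportions",
    "proportions_frame",
]


def clip_to_proportions(coefficients: np.ndarray) -> tuple[np.ndarray, bool]:
    """Clip negative coefficients to zero and renormalize to sum to one.

    Returns ``(fractions, degenerate)``; when every coefficient is
    non-positive the fractions are all zero and the degenerate flag is set.
    """
    clipped = np.clip(np.asarray(coefficients, dtype=float), 0.0, None)
    total = clipped.sum()
    if total <= 0:
        return np.zeros_like(clipped), True
    return clipped / total, False


@dataclass
class ProportionEstimate:
    """Estimated cell-type fractions for one mixture sample."""

    mixture_id: str
    cell_types: list[str]
    fractions: np.ndarray
    n_components: int
    raw_coefficients: np.ndarray
    degenerate: bool = False

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions, index=self.cell_types, name=self.mixture_id)


def simpls_fit(X: np.ndarray, Y: np.ndarray, n_components: int) -> np.ndarray:
    """SIMPLS regression coefficients (p x q) for centered X and Y.

    Columns of ``X`` and ``Y`` are mean-centered internally (center only,
    no unit scaling — intensity magnitudes carry signal). Components are
    extracted from S = X'Y: at each step the dominant right singular
    direction of S yields the X-weight vector, scores and loadings are
    accumulated, and S is deflated by the orthonormal basis of X-loadings.
    Deterministic for fixed input.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    q = Y.shape[1]
    if X.std(axis=0).min() == 0:
        raise ValueError("zero-variance predictor column")
    max_comp = min(n - 1, p)
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}]")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)

    S = Xc.T @ Yc
    R = np.zeros((p, n_components))  # X weights
    T = np.zeros((n, n_components))  # X scores
    Q = np.zeros((q, n_components))  # Y loadings
    V = np.zeros((p, n_components))  # orthonormalized X loadings
    a_used = 0
    for a in range(n_components):
        # dominant right singular direction of the deflated cross-product
        _, sv, vt = np.linalg.svd(S, full_matrices=False)
        if sv[0] <= 1e-14:
            warnings.warn(
                f"cross-product exhausted after {a} components; reducing", stacklevel=2
            )
            break
        r = S @ vt[0]
        t = Xc @ r
        tnorm = np.linalg.norm(t)
        if tnorm <= 1e-14:
            break
        t /= tnorm
        r /= tnorm
        pload = Xc.T @ t
        qload = Yc.T @ t
        v = pload.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pload)
        vnorm = np.linalg.norm(v)
        if vnorm <= 1e-14:
            break
        v /= vnorm
        S = S - np.outer(v, v @ S)
        R[:, a], T[:, a], Q[:, a], V[:, a] = r, t, qload, v
        a_used = a + 1
    if a_used == 0:
        raise ValueError("no SIMPLS component could be extracted (degenerate input)")
    return R[:, :a_used] @ Q[:, :a_used].T


def estimate_proportions(
    signature: SignatureMatrix,
    mixtures: MixtureMatrix,
    transform: TransformSpec | None = None,
    n_components: int | None = None,
) -> list[ProportionEstimate]:
    """Estimate cell-type fractions for every mixture column.

    Features are matched between signature and mixture by exact id; the
    intersection defines the regression rows. The chosen transform (auto by
    default, estimated from the pooled mixture values) is applied
    identically to both sides. ``n_components`` defaults to the number of
    cell types, capped at the rank of the centered predictor block.
    Negative coefficients are clipped to zero before renormalization; if
    every coefficient is non-positive the estimate is flagged degenerate
    and the fractions are all zero.
    """
    transform = transform or TransformSpec(mode="auto")
    shared = [f for f in signature.feature_ids if f in set(mixtures.feature_ids)]
    k = len(signature.cell_types)
    if len(shared) < k:
        raise ValueError(
            f"only {len(shared)} features shared between signature and mixture; "
            f"need >= {k}. Check that feature ids use the same convention "
            "(e.g. chrom_start_end peak ids or gene symbols) on both sides."
        )
    B = signature.values.loc[shared]
    M = mixtures.values.loc[shared]
    (M_t, B_t), spec = snap_and_apply(transform, M, B)

    X = B_t.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    rank = int(np.linalg.matrix_rank(Xc))
    want = k if n_components is None else n_components
    ncomp = max(1, min(want, rank, X.shape[0] - 1))
    if ncomp < want:
        warnings.warn(
            f"n_components reduced from {want} to {ncomp} (rank limit)", stacklevel=2
        )

    results = []
    for mid in M_t.columns:
        y = M_t[mid].to_numpy(dtype=float)
        coef = simpls_fit(X, y, ncomp)[:, 0]
        fractions, degenerate = clip_to_proportions(coef)
        results.append(
            ProportionEstimate(
                mixture_id=str(mid),
                cell_types=list(signature.cell_types),
                fractions=fractions,
                n_components=ncomp,
                raw_coefficients=coef,
                degenerate=degenerate,
            )
        )
    # record the finalized transform on each estimate for reporting
    for r in results:
        r.transform = spec  # type: ignore[attr-defined]
    return results


def proportions_frame(estimates: list[ProportionEstimate]) -> pd.DataFrame:
    """Stack per-mixture estimates into a mixtures x cell-types table."""
    return pd.DataFrame([e.as_series() for e in estimates])
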