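"""Automatic data transformation via Box-Cox lambda estimation.

Peak intensities and expression values are often heavily right-skewed;
regression behaves better when the inputs are roughly normal. Rather than
apply an arbitrary power transform, the Box-Cox profile log-likelihood is
maximized over lambda in [-2, 2] on the pooled mixture values and the
estimate is snapped to the nearest of three interpretable transforms:
log2 (lambda = 0), square root (lambda = 0.5), or none (lambda = 1).
Signature and mixture matrices always receive the same transform so the
linear mixing model stays internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

__all__ = ["TransformSpec", "estimate_lambda", "snap_lambda", "snap_and_apply"]

_MODES = ("auto", "none", "sqrt", "log2")


@dataclass(frozen=True)
class TransformSpec:
    """Which monotone transform to apply, and how it was chosen.

    ``mode`` is the user request; ``chosen`` is the transform actually
    applied (equal to ``mode`` unless mode is ``auto``). ``offset`` is the
    pseudocount added before lambda estimation and before log2.
    """

    mode: str = "auto"
    lambda_hat: float | None = None
    chosen: str | None = None
    offset: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.chosen is not None and self.chosen not in _MODES[1:]:
            raise ValueError("chosen must be none, sqrt or log2")
        if self.offset <= 0:
            raise ValueError("offset must be > 0")


def estimate_lambda(values: np.ndarray) -> float:
    """Box-Cox lambda maximizing the profile log-likelihood on [-2, 2]."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 10:
        raise ValueError("need >= 10 values to estimate lambda")
    if (x <= 0).any():
        raise ValueError("values must be strictly positive; add an offset first")
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, x), bounds=(-2.0, 2.0), method="bounded"
    )
    return float(res.x)


def snap_lambda(lambda_hat: float) -> str:
    """Nearest of log2 (0), sqrt (0.5), none (1); midpoint ties snap up."""
    if lambda_hat < 0.25:
        return "log2"
    if lambda_hat < 0.75:
        return "sqrt"
    return "none"


def _apply_one(chosen: str, offset: float, arr: np.ndarray) -> np.ndarray:
    if chosen == "none":
        return arr
    if chosen == "sqrt":
        return np.sqrt(arr)
    if chosen == "log2":
        return np.log2(arr + offset)
    raise ValueError(f"unknown transform: {chosen}")


def snap_and_apply(spec: TransformSpec, *matrices):
    """Finalize the transform choice and apply it to every matrix.

    In ``auto`` mode the lambda is estimated from the pooled values of the
    FIRST matrix (offset added) unless ``spec.lambda_hat`` is already set,
    then snapped; otherwise ``mode`` is used directly. Every supplied
    matrix — numpy array or pandas DataFrame — receives the identical
    transform. Returns ``(transformed_matrices, finalized_spec)``.
    """
    if spec.mode == "auto":
        lam = spec.lambda_hat
        if lam is None:
            first = np.asarray(
                matrices[0].to_numpy() if hasattr(matrices[0], "to_numpy") else matrices[0],
                dtype=float,
            )
            lam = estimate_lambda(first.ravel() + spec.offset)
        chosen = snap_lambda(lam)
        spec = replace(spec, lambda_hat=lam, chosen=chosen)
    else:
        spec = replace(spec, chosen=spec.mode)
    out = []
    for m in matrices:
        if hasattr(m, "to_numpy"):  # DataFrame: preserve labels
            out.append(m.__class__(
                _apply_one(spec.chosen, spec.offset, m.to_numpy(dtype=float)),
                index=m.index,
                columns=m.columns,
            ))
        else:
            out.append(_apply_one(spec.chosen, spec.offset, np.asarray(m, dtype=float)))
    return out, spec
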