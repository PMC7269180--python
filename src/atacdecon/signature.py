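"""Signature-matrix construction by condition-number minimization.

The signature matrix B (features x cell types) holds, for each selected
cell-type-specific peak, its mean intensity in each cell type. Too few
markers lose information; too many inject noise and collinearity. The
sweep takes, for each candidate count n between g and G, the top-n CTSPs
per cell type by pi-value, forms the union of those features, and scores
the resulting means matrix by its 2-norm condition number (sigma_max /
sigma_min) after column-wise z-scoring; the candidate with the smallest
condition number wins (ties go to the smaller n). The returned matrix is
the raw (un-z-scored) means matrix — z-scoring is a scoring normalization
only, since regression on m = B f needs B on the intensity scale.

Z-scoring is per column (each cell type standardized across features):
standardizing per row would center every row at zero, putting the all-ones
vector in the null space and making every candidate exactly singular.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ctsp import CTSPStat
from .profiles import ReferenceProfile

__all__ = [
    "SignatureMatrix",
    "celltype_means",
    "condition_number",
    "zscore_columns",
    "build_signature",
    "write_signature",
]

_SV_RTOL = 1e-12  # sigma_min below rtol * sigma_max counts as singular


@dataclass
class SignatureMatrix:
    """Features x cell-types matrix B with its selection metadata."""

    values: pd.DataFrame  # rows: feature ids, columns: cell types
    condition_number: float
    n_per_type: int
    g: int | None = None
    G: int | None = None

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("signature features must be unique")
        if len(self.values) < len(self.values.columns):
            raise ValueError("need at least as many features as cell types")
        if self.condition_number < 1:
            raise ValueError("condition number must be >= 1")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)


def celltype_means(profile: ReferenceProfile, features: Sequence[str]) -> pd.DataFrame:
    """Mean intensity of each feature within each cell type's samples."""
    missing = [f for f in features if f not in profile.values.index]
    if missing:
        raise KeyError(f"features not in profile: {missing[:5]}")
    sub = profile.values.loc[list(features)]
    cols = {
        ct: sub[profile.samples_of(ct)].mean(axis=1) for ct in profile.cell_types
    }
    return pd.DataFrame(cols, index=list(features))


def condition_number(matrix: np.ndarray | pd.DataFrame) -> float:
    """2-norm condition number sigma_max / sigma_min.

    Returns +inf when the smallest singular value vanishes (relative to the
    largest, tolerance 1e-12); raises on an all-zero matrix.
    """
    arr = np.asarray(matrix, dtype=float)
    sv = np.linalg.svd(arr, compute_uv=False)
    if sv.size == 0 or sv[0] == 0:
        raise ValueError("condition number undefined for an all-zero matrix")
    if sv[-1] <= _SV_RTOL * sv[0]:
        return float("inf")
    return float(sv[0] / sv[-1])


def zscore_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-score (per cell type across features).

    A constant column (degenerate cell type) is left centered at zero
    rather than divided by its zero standard deviation; the candidate then
    scores as singular and is skipped by the sweep.
    """
    arr = matrix.to_numpy(dtype=float)
    mu = arr.mean(axis=0, keepdims=True)
    sd = arr.std(axis=0, ddof=0, keepdims=True)
    z = (arr - mu) / np.where(sd > 0, sd, 1.0)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def build_signature(
    ctsps: dict[str, list[CTSPStat]],
    profile: ReferenceProfile,
    g: int = 50,
    G: int = 150,
) -> SignatureMatrix:
    """Sweep per-type marker counts n = g..G; keep the best-conditioned B.

    For each n, the candidate feature set is the union over cell types of
    each type's top-n CTSPs (pi-value order). The candidate is scored by
    the condition number of the column-z-scored cell-type-means matrix;
    singular candidates are skipped. Ties in condition number resolve to
    the smallest n. A cell type with fewer than n CTSPs contributes all it
    has (warning at sweep start); a cell type with none is an error.
    """
    if not (2 <= g <= G):
        raise ValueError("need 2 <= g <= G")
    empty = [ct for ct in profile.cell_types if not ctsps.get(ct)]
    if empty:
        raise ValueError(f"cell types with zero CTSPs cannot be represented: {empty}")
    short = [ct for ct in profile.cell_types if len(ctsps[ct]) < g]
    if short:
        warnings.warn(
            f"cell types with fewer than g={g} CTSPs contribute all they have: {short}",
            stacklevel=2,
        )
    best: tuple[float, int, list[str]] | None = None
    for n in range(g, G + 1):
        features: list[str] = []
        seen: set[str] = set()
        for ct in profile.cell_types:
            for stat in ctsps[ct][:n]:
                if stat.feature_id not in seen:
                    seen.add(stat.feature_id)
                    features.append(stat.feature_id)
        if len(features) < len(profile.cell_types):
            continue
        means = celltype_means(profile, features)
        z = zscore_columns(means)
        if len(z) < len(profile.cell_types):
            continue
        kappa = condition_number(z)
        if np.isinf(kappa):
            continue
        if best is None or kappa < best[0]:
            best = (kappa, n, features)
    if best is None:
        raise ValueError("every candidate signature in the sweep was singular")
    kappa, n_win, features = best
    return SignatureMatrix(
        values=celltype_means(profile, features),
        condition_number=kappa,
        n_per_type=n_win,
        g=g,
        G=G,
    )


def write_signature(sig: SignatureMatrix, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Write the signature TSV and a sidecar JSON of selection metadata."""
    sig.values.rename_axis("feature_id").to_csv(tsv_path, sep="\t")
    if json_path is not None:
        meta = {
            "n_per_type": sig.n_per_type,
            "condition_number": sig.condition_number,
            "g": sig.g,
            "G": sig.G,
            "n_features": len(sig.values),
        }
        Path(json_path).write_text(json.dumps(meta, indent=2) + "\n")
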