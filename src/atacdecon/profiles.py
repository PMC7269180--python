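"""Labeled intensity tables and their normalization.

A :class:`ReferenceProfile` holds the peaks-by-samples intensity matrix for
the purified reference samples together with a sample -> cell-type map; a
:class:`MixtureMatrix` holds the features-by-mixtures matrix to be
deconvolved. Reference samples are quantile-normalized across columns to
suppress batch effects, and features whose intensity never reaches the
global median of the normalized matrix are discarded as uninformative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceProfile",
    "MixtureMatrix",
    "quantile_normalize",
    "median_intensity_filter",
    "read_intensity_tsv",
    "read_phenotype_tsv",
]


@dataclass
class ReferenceProfile:
    """Features x reference-samples intensity table with cell-type labels.

    ``values`` is a DataFrame indexed by feature id with one column per
    sample; ``labels`` maps each sample id to its cell-type name. At least
    two distinct cell types must be present.
    """

    values: pd.DataFrame
    labels: dict[str, str]

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("feature ids must be unique")
        missing = [s for s in self.values.columns if s not in self.labels]
        if missing:
            raise ValueError(f"samples without a cell-type label: {missing}")
        self.labels = {s: self.labels[s] for s in self.values.columns}
        if len(set(self.labels.values())) < 2:
            raise ValueError("reference must contain >= 2 cell types")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)) or (arr < 0).any():
            raise ValueError("intensities must be finite and >= 0")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def cell_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.labels[s], None)
        return list(seen)

    def samples_of(self, cell_type: str) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == cell_type]

    def replace_values(self, values: pd.DataFrame) -> "ReferenceProfile":
        return ReferenceProfile(values=values, labels=dict(self.labels))


@dataclass
class MixtureMatrix:
    """Features x mixture-samples intensity table (the measurement m)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("feature ids must be unique")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)) or (arr < 0).any():
            raise ValueError("intensities must be finite and >= 0")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def mixture_ids(self) -> list[str]:
        return list(self.values.columns)


def _quantile_normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns; ties take the mean of spanned quantiles."""
    arr = df.to_numpy(dtype=float)
    n = arr.shape[0]
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    # average ranks (1-based); ties receive the mean of the reference
    # values their rank span covers, via linear interpolation on ranks
    ranks = pd.DataFrame(arr).rank(axis=0, method="average").to_numpy()
    out = np.interp(ranks, np.arange(1, n + 1), reference)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def quantile_normalize(profile: ReferenceProfile) -> ReferenceProfile:
    """Force every reference sample onto a common intensity distribution.

    Each column's values are replaced by the mean of the column-sorted
    matrix at the same rank, so after normalization all columns share one
    multiset of values. Tied values within a column receive the mean of the
    reference quantiles they span.
    """
    if len(profile.sample_ids) < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    return profile.replace_values(_quantile_normalize_frame(profile.values))


def median_intensity_filter(profile: ReferenceProfile) -> ReferenceProfile:
    """Drop features that never reach the global median intensity.

    The median is computed over every entry of the (already normalized)
    matrix; a feature is retained iff its maximum across samples is >= that
    median. Keying on the row maximum protects markers of rare cell types:
    a peak open in only one cell type still clears the bar.
    """
    arr = profile.values.to_numpy()
    global_median = float(np.median(arr))
    keep = profile.values.max(axis=1) >= global_median
    filtered = profile.values.loc[keep]
    if len(filtered) < 100:
        warnings.warn(
            f"only {len(filtered)} features survive the median filter",
            stacklevel=2,
        )
    return profile.replace_values(filtered)


def read_intensity_tsv(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV (first column feature id, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_phenotype_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column sample_id/cell_type TSV (with header) into a map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("phenotype table needs sample_id and cell_type columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
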