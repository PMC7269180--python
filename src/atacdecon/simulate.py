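"""Synthetic reference profiles and composition-known mixtures.

The generator emulates, at the intensity level, the statistical structure
partial deconvolution assumes: every cell type has a set of marker peaks
elevated ``marker_fold``-fold over a shared lognormal background, replicate
samples scatter around each type's mean profile with multiplicative
lognormal noise, and mixtures are linear combinations of the type means
with weights drawn from a Dirichlet distribution over the simplex.
Optional collinearity blending pulls designated type pairs' mean profiles
toward each other to emulate lineage-adjacent similarity (e.g. stem cells
versus their immediate progenitors). Everything is deterministic given the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import MixtureMatrix, ReferenceProfile

__all__ = ["SimulationConfig", "SimulatedTruth", "simulate_reference", "simulate_mixtures", "simulate_dataset"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study design.

    ``marker_fold`` is the accessibility elevation of a marker peak in its
    own cell type; ``noise_cv`` the coefficient of variation of the
    multiplicative lognormal replicate/measurement noise; ``collinearity``
    a list of (type_i, type_j, weight) triples blending type j's mean
    profile into type i's at the given weight in [0, 1).
    """

    n_cell_types: int = 5
    n_features: int = 2000
    n_markers_per_type: int = 100
    n_replicates_per_type: int = 3
    marker_fold: float = 10.0
    noise_cv: float = 0.1
    dirichlet_alpha: float | np.ndarray = 1.0
    n_mixtures: int = 100
    collinearity: list[tuple[int, int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 2:
            raise ValueError("need >= 2 cell types")
        if self.n_replicates_per_type < 2:
            raise ValueError("need >= 2 replicates per type")
        if self.n_markers_per_type * self.n_cell_types > self.n_features:
            raise ValueError("markers exceed feature budget")
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must be > 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for i, j, w in self.collinearity:
            if not 0 <= w < 1:
                raise ValueError("collinearity weights must be in [0, 1)")
            if not (0 <= i < self.n_cell_types and 0 <= j < self.n_cell_types):
                raise ValueError("collinearity indices out of range")

    @property
    def cell_type_names(self) -> list[str]:
        return [f"type{i + 1}" for i in range(self.n_cell_types)]

    def alpha_vector(self) -> np.ndarray:
        a = np.asarray(self.dirichlet_alpha, dtype=float)
        if a.ndim == 0:
            a = np.full(self.n_cell_types, float(a))
        if a.shape != (self.n_cell_types,) or (a <= 0).any():
            raise ValueError("dirichlet_alpha must be positive, one per cell type")
        return a


@dataclass
class SimulatedTruth:
    """Everything the generator knows: profiles, mixtures, and ground truth."""

    reference: ReferenceProfile
    mixtures: MixtureMatrix
    fractions: pd.DataFrame  # mixtures x cell types, rows sum to 1
    marker_map: dict[str, str]  # feature id -> planted cell type
    type_means: pd.DataFrame  # features x cell types, noise-free means


def _lognormal_factor(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=shape)


def _type_means(config: SimulationConfig, rng: np.random.Generator):
    nf, k = config.n_features, config.n_cell_types
    base = rng.lognormal(mean=np.log(20.0), sigma=1.0, size=nf)
    means = np.tile(base[:, None], (1, k))
    feature_ids = [f"peak{i + 1}" for i in range(nf)]
    marker_map: dict[str, str] = {}
    names = config.cell_type_names
    for t in range(k):
        lo = t * config.n_markers_per_type
        hi = lo + config.n_markers_per_type
        means[lo:hi, t] *= config.marker_fold
        for i in range(lo, hi):
            marker_map[feature_ids[i]] = names[t]
    for i, j, w in config.collinearity:
        means[:, i] = (1 - w) * means[:, i] + w * means[:, j]
    return pd.DataFrame(means, index=feature_ids, columns=names), marker_map


def simulate_reference(config: SimulationConfig):
    """Generate replicate reference samples around planted type means.

    Returns ``(ReferenceProfile, marker_map, type_means)``; replicates are
    the type mean scaled by independent lognormal noise at ``noise_cv``.
    """
    rng = np.random.default_rng(config.seed)
    means, marker_map = _type_means(config, rng)
    cols, labels = {}, {}
    for ct in config.cell_type_names:
        mu = means[ct].to_numpy()
        for r in range(config.n_replicates_per_type):
            sid = f"{ct}_rep{r + 1}"
            cols[sid] = mu * _lognormal_factor(rng, config.noise_cv, mu.shape)
            labels[sid] = ct
    values = pd.DataFrame(cols, index=means.index)
    return ReferenceProfile(values=values, labels=labels), marker_map, means


def simulate_mixtures(
    type_means: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_present: int | None = None,
):
    """Draw Dirichlet compositions and mix the noise-free type means.

    ``n_present`` restricts each mixture to a random subset of that many
    cell types (the others' fractions zeroed and the rest renormalized),
    emulating samples where only some types occur. Returns
    ``(MixtureMatrix, fractions)`` with fraction rows summing to 1.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    k = config.n_cell_types
    alpha = config.alpha_vector()
    F = rng.dirichlet(alpha, size=config.n_mixtures)
    if n_present is not None:
        if not 1 <= n_present <= k:
            raise ValueError("n_present must be in [1, n_cell_types]")
        for row in F:
            absent = rng.choice(k, size=k - n_present, replace=False)
            row[absent] = 0.0
            row /= row.sum()
    M = type_means.to_numpy() @ F.T
    M *= _lognormal_factor(rng, config.noise_cv, M.shape)
    mix_ids = [f"mix{i + 1}" for i in range(config.n_mixtures)]
    mixtures = MixtureMatrix(
        values=pd.DataFrame(M, index=type_means.index, columns=mix_ids)
    )
    fractions = pd.DataFrame(F, index=mix_ids, columns=type_means.columns)
    return mixtures, fractions


def simulate_dataset(config: SimulationConfig, n_present: int | None = None) -> SimulatedTruth:
    """One-call generator: reference, mixtures and ground truth together."""
    reference, marker_map, means = simulate_reference(config)
    rng = np.random.default_rng(config.seed + 1)
    mixtures, fractions = simulate_mixtures(means, config, rng=rng, n_present=n_present)
    return SimulatedTruth(
        reference=reference,
        mixtures=mixtures,
        fractions=fractions,
        marker_map=marker_map,
        type_means=means,
    )
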