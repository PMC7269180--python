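import numpy as np
import pandas as pd
import pytest

from atacdecon.profiles import ReferenceProfile
from atacdecon.simulate import SimulationConfig, simulate_dataset


def make_profile(values: np.ndarray, n_types: int, n_reps: int, feature_prefix: str = "f") -> ReferenceProfile:
    """Wrap a (features x n_types*n_reps) array into a labeled profile."""
    cols = [f"type{t + 1}_rep{r + 1}" for t in range(n_types) for r in range(n_reps)]
    labels = {c: c.split("_")[0] for c in cols}
    idx = [f"{feature_prefix}{i + 1}" for i in range(values.shape[0])]
    return ReferenceProfile(values=pd.DataFrame(values, index=idx, columns=cols), labels=labels)


@pytest.fixture(scope="session")
def planted_dataset():
    """Default-condition synthetic study: 5 types, 10x markers, 10% noise."""
    config = SimulationConfig(
        n_cell_types=5,
        n_features=2000,
        n_markers_per_type=100,
        n_replicates_per_type=3,
        marker_fold=10.0,
        noise_cv=0.1,
        n_mixtures=100,
        seed=7,
    )
    return simulate_dataset(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
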