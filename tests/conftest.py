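"""Shared fixtures: small grids and reduced synthetic designs.

Simulation-based tests use fixed seeds throughout so the suite is
deterministic.
"""

import numpy as np
import pandas as pd
import pytest

from aquaphot.dataset import SpectralDataset
from aquaphot.synthetic import SyntheticConfig


@pytest.fixture
def grid50():
    """50-channel grid over the first overtone of water."""
    return np.linspace(1300.0, 1600.0, 50)


@pytest.fixture
def bare_dataset(grid50):
    """Factory: SpectralDataset from a matrix with index-only metadata."""

    def make(X, meta=None):
        X = np.atleast_2d(X)
        if meta is None:
            meta = pd.DataFrame(index=range(X.shape[0]))
        return SpectralDataset(grid50[: X.shape[1]] if X.shape[1] != 50 else grid50,
                               X, meta)

    return make


@pytest.fixture
def small_config():
    """Reduced study design: fast to simulate, same spectral structure."""
    return SyntheticConfig(seed=0, n_fruits=4, n_positions=1, n_replicates=1)


@pytest.fixture
def labelled_dataset(grid50):
    """Factory: dataset with day labels from per-class matrices."""

    def make(blocks):
        X = np.vstack([b for _, b in blocks])
        days = np.concatenate(
            [np.full(len(b), day, dtype=int) for day, b in blocks]
        )
        return SpectralDataset(grid50, X, pd.DataFrame({"day": days}))

    return make
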