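"""Shared fixtures: all test data are generated programmatically."""

import numpy as np
import pandas as pd
import pytest

from rlqspace.synthetic import SimConfig, generate


def small_config(**overrides) -> SimConfig:
    """Small but realistic plot: 200 quadrats at 10 m, 40 species."""
    base = dict(
        plot_width=200.0,
        plot_height=100.0,
        n_species=40,
        n_individuals=4000,
        env_range_param=60.0,
        n_env_vars=5,
        n_traits=6,
        signal_lambda=0.7,
        filtering_strength=5.0,
        seed=7,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def filtering_dataset():
    """Strong trait-environment filtering with full phylogenetic signal."""
    return generate(small_config(filtering_strength=10.0, signal_lambda=1.0))


@pytest.fixture(scope="session")
def neutral_dataset():
    return generate(small_config(filtering_strength=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_abundance_table(rng, n_sites=6, n_species=5) -> pd.DataFrame:
    """Random strictly-positive-margin count table."""
    L = rng.poisson(3.0, size=(n_sites, n_species)).astype(float)
    L[rng.random(L.shape) < 0.2] = 0.0
    # guarantee non-zero margins
    for i in range(n_sites):
        if L[i].sum() == 0:
            L[i, rng.integers(n_species)] = 1.0
    for j in range(n_species):
        if L[:, j].sum() == 0:
            L[rng.integers(n_sites), j] = 1.0
    return pd.DataFrame(
        L,
        index=[f"s{i}" for i in range(n_sites)],
        columns=[f"sp{j}" for j in range(n_species)],
    )
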