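import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from clonostate.datasets import normalize_log1p
from clonostate.simulate import (
    ClonotypeClassConfig,
    SimConfig,
    default_config,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small (~500-cell) simulated dataset with ground truth."""
    cfg = default_config(seed=42, scale=0.2)
    dataset, truth, clones = simulate_dataset(cfg)
    return cfg, dataset, truth, clones


@pytest.fixture(scope="session")
def medium_sim():
    """A ~2,500-cell simulated dataset for recovery-style checks."""
    cfg = default_config(seed=7, scale=1.0)
    dataset, truth, clones = simulate_dataset(cfg)
    return cfg, dataset, truth, clones


@pytest.fixture(scope="session")
def medium_log_expr(medium_sim):
    _, dataset, _, _ = medium_sim
    return pd.DataFrame(
        normalize_log1p(dataset), index=dataset.cell_ids, columns=dataset.gene_names
    )


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def tiny_config(seed=0, **kwargs) -> SimConfig:
    """One-class config used by parameter-focused simulator tests."""
    defaults = dict(
        seed=seed,
        clonotype_classes=[
            ClonotypeClassConfig(name="Vd1", n_clones=5, size_mean=4.0, size_dispersion=1.0)
        ],
        n_genes=60,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)
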