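"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

from dysreg import SelectionParams, SyntheticConfig, default_panel, generate_cohort
from dysreg.lasso import PathParams


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_tumour=150,
        n_normal=50,
        n_panel_genes=12,
        n_tfs=40,
        true_tfs_per_gene=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    bundle, truth = generate_cohort(small_config)
    return bundle, truth


@pytest.fixture(scope="session")
def small_panel(small_config):
    return default_panel(small_config)


@pytest.fixture(scope="session")
def quick_selection_params() -> SelectionParams:
    """Desk-scale stability selection: few runs/splits, short lambda path."""
    return SelectionParams(
        runs=10,
        splits=10,
        seed=5,
        path=PathParams(n_points=60, folds=5),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
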