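"""Shared fixtures: small planted-motif datasets, reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from kinasepred.family_model import ModelSpec, fit
from kinasepred.featurize import featurize_dataset
from kinasepred.fixtures import FixtureSpec, generate_family_fixture


@pytest.fixture(scope="session")
def family_ds():
    """100 actives / 100 inactives, planted motif, no noise."""
    return generate_family_fixture(FixtureSpec(n_active=100, n_inactive=100, seed=7))


@pytest.fixture(scope="session")
def morgan_features(family_ds):
    return featurize_dataset(family_ds, "morgan")


@pytest.fixture(scope="session")
def small_ds():
    """40/40 dataset for cheap model tests."""
    return generate_family_fixture(FixtureSpec(n_active=40, n_inactive=40, seed=11))


@pytest.fixture(scope="session")
def small_features(small_ds):
    return featurize_dataset(small_ds, "morgan")


@pytest.fixture(scope="session")
def small_rf_model(small_ds, small_features):
    spec = ModelSpec.make(
        "random_forest", "morgan", {"n_estimators": 100, "max_features": "sqrt"},
        seed=3,
    )
    return fit(
        spec,
        small_features,
        small_ds.labels,
        training_smiles=[rec.smiles_std for rec, _ in small_ds.records],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
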