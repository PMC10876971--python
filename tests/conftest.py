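import numpy as np
import pytest
from hypothesis import settings

from focalamp.classifier import ModelConfig, train
from focalamp.feature_engineering import build_feature_matrix
from focalamp.simulate import SimulationConfig, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def label_features(cohort, matrix):
    """Merge truth cargo labels onto a feature matrix (adds ``label``)."""
    truth = cohort.truth[["sample_id", "gene_id", "is_cargo"]]
    merged = matrix.merge(truth, on=["sample_id", "gene_id"], how="left")
    merged["label"] = merged["is_cargo"].astype(int)
    return merged.drop(columns="is_cargo")


@pytest.fixture(scope="session")
def small_cohort():
    """Compact simulated cohort for fast unit tests."""
    return simulate_cohort(SimulationConfig(n_samples=40, n_genes=150, seed=11))


@pytest.fixture(scope="session")
def small_features(small_cohort):
    matrix = build_feature_matrix(
        small_cohort.profiles, small_cohort.genes, small_cohort.priors
    )
    return label_features(small_cohort, matrix)


@pytest.fixture(scope="session")
def small_model(small_features):
    config = ModelConfig(k_folds=4, n_search=3, max_rounds=150, seed=7)
    return train(small_features, config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
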