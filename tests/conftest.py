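import numpy as np
import pytest

from neuronorm import compute_relative_volumes, default_schema, simulate_cohort
from neuronorm.prep import prepare_training_cohort
from neuronorm.simulate import SimConfig


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def two_scanner():
    """A two-scanner healthy cohort plus its ground truth (n=150/scanner)."""
    return simulate_cohort(SimConfig(n_per_scanner=(150, 150), seed=11))


@pytest.fixture(scope="session")
def clean_relative(two_scanner):
    """The two-scanner cohort in relative volumes after the cleaning rules."""
    cohort, _ = two_scanner
    rel = compute_relative_volumes(cohort)
    clean, _ = prepare_training_cohort(rel, seed=11)
    return clean


@pytest.fixture(scope="session")
def gaussian_features():
    """Correlated Gaussian 'healthy' features for network-level tests."""
    rng = np.random.default_rng(5)
    n, k, r = 600, 101, 6
    latent = rng.normal(size=(n, r))
    loadings = rng.normal(size=(r, k))
    return latent @ loadings + 0.5 * rng.normal(size=(n, k))


@pytest.fixture(scope="session")
def trained_aae(gaussian_features):
    from neuronorm.outliers import AAEConfig, train_aae

    return train_aae(gaussian_features[:500], AAEConfig(seed=3))
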