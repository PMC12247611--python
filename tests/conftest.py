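import numpy as np
import pytest

from nmqc import CohortSpec, FitConfig, fit_normative_model, generate_cohort
from nmqc.warp import WarpParams, warp_inverse


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fitted_model():
    """A model fit once on clean model-matched data, shared across tests.

    Returns (model, ages, y, true_warp, true_noise_sd).
    """
    rng = np.random.default_rng(7)
    n = 3000
    ages = rng.uniform(45.0, 85.0, n)
    true_warp = WarpParams(a0=0.8, b0=0.05, epsilon=0.4, delta=1.2)
    latent = 0.04 * (ages - 65.0) / 10.0 + rng.normal(0.0, 1.0, n)
    y = warp_inverse(latent, true_warp)
    model = fit_normative_model(ages, y, FitConfig(seed=0))
    return model, ages, y, true_warp, 1.0


@pytest.fixture(scope="session")
def small_cohort():
    """200 clean subjects with the default 24 IDPs."""
    return generate_cohort(CohortSpec(n_subjects=200, seed=42))
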