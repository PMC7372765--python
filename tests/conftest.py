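import numpy as np
import pytest

from semigwas import FitConfig, SynthConfig, generate_dataset, fit_logistic_gd

CONVERGED = FitConfig(iters=200_000, tol=1e-10)


@pytest.fixture(scope="session")
def small_data():
    """Well-conditioned null panel: 300 patients, 50 SNPs, 3 covariates."""
    return generate_dataset(SynthConfig(n=300, m=50, k=3, seed=11))


@pytest.fixture(scope="session")
def small_state(small_data):
    """Gradient-descent fit of the small panel, run to convergence."""
    return fit_logistic_gd(small_data, CONVERGED)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
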