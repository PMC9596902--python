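import warnings

import numpy as np
import pytest
from statsmodels.tools.sm_exceptions import ConvergenceWarning

import cartigrade as cg


@pytest.fixture(autouse=True)
def _quiet_mixed_model_chatter():
    """Silence optimizer/singularity chatter from nested MixedLM fits."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        warnings.filterwarnings("ignore", message=".*covariance.*singular.*")
        warnings.filterwarnings("ignore", message=".*random effects covariance.*")
        warnings.filterwarnings("ignore", message=".*Maximum Likelihood optimization.*")
        yield


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 cadavers, 7 sites per knee: the smallest nested cohort."""
    return cg.simulate_cohort(cg.SynthParams(n_cadavers=3, sites_per_surface=(3, 2, 2), seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """4 cadavers, 9 sites per knee, 30% planted poor-contact spectra."""
    return cg.simulate_cohort(cg.SynthParams(n_cadavers=4, sites_per_surface=(4, 3, 2), seed=7))


@pytest.fixture(scope="session")
def snv_config():
    """A cheap, signal-preserving preprocessing config used across tests."""
    return cg.PreprocessConfig(scatter="snv", sg_deriv=0, sg_window=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
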