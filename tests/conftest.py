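import numpy as np
import pytest

from tkrcea.config import GeneratorConfig, RunConfig
from tkrcea.pipeline import fit_all, simulate


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Reduced-scale generator: enough signal for structural checks, fast."""
    return GeneratorConfig(n_patients=20_000, n_revision_cohort=40_000,
                           n_rerevision_cohort=20_000, seed=7)


@pytest.fixture(scope="session")
def small_data(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def small_run() -> RunConfig:
    run = RunConfig(seed=7, m_imputations=3, mice_iterations=3, n_psa=200)
    run.generator = GeneratorConfig(n_patients=20_000,
                                    n_revision_cohort=40_000,
                                    n_rerevision_cohort=20_000, seed=7)
    return run


@pytest.fixture(scope="session")
def small_models(small_data, small_run):
    return fit_all(small_data, small_run)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
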