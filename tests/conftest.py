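import numpy as np
import pytest

from ps5 import MediationDataset, PS5Config, ScenarioConfig, generate


@pytest.fixture(scope="session")
def small_alternative():
    """A modest alternative-scenario dataset with 3 active of 40 mediators."""
    cfg = ScenarioConfig(kind="alternative", n=240, p=40, s=3,
                         alpha_strength=0.5, seed=424)
    return generate(cfg)


@pytest.fixture(scope="session")
def fast_config():
    """Light pipeline configuration for unit-level end-to-end runs."""
    return PS5Config.simulation(mc_draws=400, cv_folds=4, n_lambda=30)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)


def make_dataset(n=60, p=4, seed=0, covariates=0):
    """Small generic dataset with independent mediators."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    m = 0.5 * x[:, None] + rng.standard_normal((n, p))
    c = rng.standard_normal((n, covariates)) if covariates else None
    y = 0.3 * x + m @ rng.uniform(-1, 1, p) + rng.standard_normal(n)
    return MediationDataset(
        exposure=x, outcome=y, mediators=m, covariates=c,
        covariate_names=tuple(f"C{i+1}" for i in range(covariates)))
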