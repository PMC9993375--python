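from dataclasses import replace

import pytest
from hypothesis import HealthCheck, settings

from asuc_cua import generate_cohort
from asuc_cua.config import default_config_path, load_config
from asuc_cua.pipeline import build_inputs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return load_config(default_config_path())


@pytest.fixture(scope="session")
def records(config):
    return generate_cohort(config.synthetic)


@pytest.fixture(scope="session")
def generating_weibull(config):
    """The configured generating (shape, scale) per arm — lets pipeline tests
    skip the fitting stage."""
    return {
        arm: (spec.event_model.shape, spec.event_model.scale)
        for arm, spec in config.synthetic.arms.items()
    }


@pytest.fixture(scope="session")
def base_inputs(config, generating_weibull):
    return build_inputs(config, generating_weibull)


@pytest.fixture()
def small_config(config):
    """Config shrunk for fast end-to-end runs."""
    arms = {arm: replace(s, n=60) for arm, s in config.synthetic.arms.items()}
    return replace(
        config,
        synthetic=replace(config.synthetic, arms=arms, seed=11),
        psa=replace(config.psa, n_draws=40, seed=5),
    )
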