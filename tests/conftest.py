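import pytest
from hypothesis import HealthCheck, settings

import ownsync as osy

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Group-level parameter estimates typical of the two detection tasks.
TYPICAL_SIGMAS = {0: 116.0, 30: 141.0, 50: 178.0}


@pytest.fixture(scope="session")
def ownership_design():
    return osy.default_design("ownership")


@pytest.fixture(scope="session")
def synchrony_design():
    return osy.default_design("synchrony")


@pytest.fixture(scope="session")
def typical_bci_params():
    return osy.ObserverParams(
        model="BCI", p_same=0.8, sigma_by_noise=TYPICAL_SIGMAS, lapse=0.08
    )


@pytest.fixture(scope="session")
def typical_counts(ownership_design, typical_bci_params):
    return osy.simulate_responses(
        ownership_design, typical_bci_params, participant="P01", seed=11
    )
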