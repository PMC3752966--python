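import pytest
from hypothesis import HealthCheck, settings

from screensojourn import QuadraticIncidenceModel

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

#: quadratic-incidence coefficients published for the Rotterdam prostate
#: screening trial (hazard beta1 + beta2*x per person-year)
BETA1 = 0.0034342704
BETA2 = 2 * 0.0001796227

#: first-round detection rate treated as preclinical prevalence
PREVALENCE = 0.04


@pytest.fixture(scope="session")
def prostate_model() -> QuadraticIncidenceModel:
    return QuadraticIncidenceModel(beta1=BETA1, beta2=BETA2)
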