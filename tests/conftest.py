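import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from rndflux.constants import KT_323
from rndflux.synthetic import AnalyticPmf, BiasSchedule, sample_umbrella_windows

DOUBLE_WELL = dict(well_a=1.0, well_b=3.0, barrier=20.0, domain=(0.8, 3.2))


@pytest.fixture(scope="session")
def double_well_pmf():
    return AnalyticPmf.double_well(**DOUBLE_WELL)


@pytest.fixture(scope="session")
def double_well_windows(double_well_pmf):
    """Umbrella windows over the double well at the standard bias protocol."""
    schedule = BiasSchedule.spanning(0.8, 3.2, spacing=0.05, force_constant=1000.0)
    return sample_umbrella_windows(
        double_well_pmf, schedule, n_samples=5000, kT=KT_323, seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
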