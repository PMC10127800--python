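import pytest
from hypothesis import HealthCheck, settings

from dakinetics import observable, simulate
from dakinetics.presets import ko_parameters, standard_protocol, wt_parameters
from dakinetics.synthetic import generate_recording

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def protocol():
    """Single burst, 30 pulses at 50 Hz, 0.4 mA, onset 1 s."""
    return standard_protocol()


@pytest.fixture(scope="session")
def wt_params():
    return wt_parameters()


@pytest.fixture(scope="session")
def ko_params():
    return ko_parameters()


@pytest.fixture(scope="session")
def wt_trace(protocol, wt_params):
    """Noise-free wild-type simulation, 12 s at 1 ms steps."""
    return simulate(wt_params, protocol, duration=12.0)


@pytest.fixture(scope="session")
def wt_recording(wt_trace):
    """Noise-free wild-type observable sampled at 10 Hz."""
    return observable(wt_trace, sample_rate=10.0)


@pytest.fixture(scope="session")
def ko_recording(protocol, ko_params):
    return generate_recording(
        ko_params, protocol, noise_sd=0.0, sample_rate=10.0, seed=0
    )
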