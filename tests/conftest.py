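import pytest

from rebreathe.estimator import DeadSpaceConfig, EstimatorConfig
from rebreathe.simulator import SimulatorParams, simulate_trace


@pytest.fixture
def ideal_params() -> SimulatorParams:
    """Zero-distortion simulator settings: no noise, no lag, no delay."""
    return SimulatorParams(
        elv_true=3.0,
        rr=12.0,
        noise_sd=0.0,
        analyzer_tau=0.0,
        transport_delay=0.0,
    )


@pytest.fixture
def ideal_trace(ideal_params):
    """Six-breath zero-distortion trace with its ground truth."""
    return simulate_trace(ideal_params, n_breaths=6)


@pytest.fixture
def dead_space() -> DeadSpaceConfig:
    return DeadSpaceConfig()


@pytest.fixture
def auto_config() -> EstimatorConfig:
    return EstimatorConfig(weight="auto")
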