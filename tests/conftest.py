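import pytest
from dataclasses import replace

from chipause.config import load_model_config
from chipause.simulator import calibrate_resting_potential


@pytest.fixture(scope="session")
def default_model():
    """Shipped model config, calibrated to its -40 mV target RMP."""
    cfg = load_model_config()
    return replace(cfg, leak_e=calibrate_resting_potential(cfg, verify=False))


@pytest.fixture(scope="session")
def fast_model(default_model):
    """Calibrated model at a coarser (but converged) integration step."""
    return replace(default_model, dt=0.05)


@pytest.fixture(scope="session")
def kr_spec(default_model):
    return default_model.channel("kr")


@pytest.fixture(scope="session")
def a_spec(default_model):
    return default_model.channel("a")
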