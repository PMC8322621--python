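import numpy as np
import pytest

from flytread.engine import TransportModel, run_experiment
from flytread.geometry import DisplayGeometry
from flytread.simfly import FlyModel
from flytread.stimuli import build_protocol, randomize_blocks


@pytest.fixture(scope="session")
def geom():
    return DisplayGeometry()


@pytest.fixture(scope="session")
def temporal_protocol():
    return build_protocol("temporal")


@pytest.fixture(scope="session")
def small_run(geom):
    """One synthetic fly through a 1-block temporal protocol (with closed loop)."""
    proto = build_protocol("temporal", n_blocks=1, startup_delay_ms=1000.0, rng_seed=7)
    trials = randomize_blocks(proto)
    fly = FlyModel(seed=11, motor_noise_sd_dps=10.0)
    return run_experiment(trials, geom, TransportModel(seed=5), fly,
                          startup_delay_ms=1000.0)
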