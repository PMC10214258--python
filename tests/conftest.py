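import numpy as np
import pytest

from egtrc.device import default_params
from egtrc.gait import GaitGenParams, generate_dataset
from egtrc.pipeline import batch_states


@pytest.fixture(scope="session")
def device():
    return default_params()


@pytest.fixture(scope="session")
def gait_params():
    return GaitGenParams()


@pytest.fixture(scope="session")
def small_dataset(gait_params):
    """100-sample pilot dataset (25 per class), fixed seed."""
    return generate_dataset(25, gait_params, master_seed=42)


@pytest.fixture(scope="session")
def small_states(small_dataset, device):
    return batch_states(small_dataset, device)


def random_pulse_programs(n_programs, rng, t_span=2000.0, n_channels=2):
    """Random two-channel pulse programs for integrator cross-checks."""
    from egtrc.device import Pulse, PulseTrain

    programs = []
    for _ in range(n_programs):
        trains = []
        for ch in range(n_channels):
            t, pulses = 0.0, []
            while True:
                dur = rng.uniform(20.0, 80.0)
                if t + dur > t_span:
                    break
                pulses.append(Pulse(t, dur, -rng.uniform(0.5, 1.6)))
                t += dur + rng.uniform(30.0, 400.0)
            trains.append(PulseTrain(f"g{ch + 1}", tuple(pulses)))
        programs.append(trains)
    return programs
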