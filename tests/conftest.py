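import numpy as np
import pandas as pd
import pytest

from memtd import (
    DeviceCurve,
    MemristorSynapse,
    TMazeEnv,
    WaterMazeEnv,
    generate_synthetic_curve,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def linear_curve():
    return generate_synthetic_curve(nu_pot=0.0, nu_dep=0.0, n_pulses=200)


@pytest.fixture
def nonlinear_curve():
    return generate_synthetic_curve(nu_pot=3.0, nu_dep=3.0, n_pulses=200)


@pytest.fixture
def tmaze():
    return TMazeEnv()


@pytest.fixture
def watermaze():
    return WaterMazeEnv()


def make_synapse(curve: DeviceCurve, weight: float = 0.0, seed: int = 0):
    return MemristorSynapse(curve, weight, np.random.default_rng(seed))


def cycles_frame(device_id, direction, cycles):
    """Rows of a measured-cycle CSV from a list of per-cycle weight arrays."""
    rows = []
    for cid, weights in enumerate(cycles):
        for p, w in enumerate(weights):
            rows.append({"device_id": device_id, "cycle_id": cid,
                         "direction": direction, "pulse_index": p, "weight": w})
    return pd.DataFrame(rows)
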