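import numpy as np
import pytest

import optoentrain as oe


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def stim40():
    """Continuous 40 Hz, 50% duty pulse train over 100 s."""
    return oe.make_pulse_train(40.0, 0.5, 100.0)


@pytest.fixture(scope="session")
def train_stim40():
    """Twenty 1 s trains of 40 Hz pulses separated by 3 s pauses."""
    return oe.make_train_sequence(40.0, 0.5, train_dur=1.0, n_trains=20, gap=3.0, t0=2.0)


@pytest.fixture(scope="session")
def entrain_session():
    """One 40 Hz-entrained synthetic session shared by spike-field tests."""
    return oe.preset_entrain40(seed=7)


def small_session(seed=0):
    """A compact but fully populated session for I/O tests."""
    rng = np.random.default_rng(seed)
    stim = oe.make_pulse_train(40.0, 0.5, 2.0, t0=1.0)
    sig = oe.ContinuousSignal(rng.standard_normal(2000), 500.0, 0.0, "VP", "vp")
    spikes = [
        oe.SpikeTrain(np.sort(rng.uniform(0, 4, 50)), "u1", "LHb"),
        oe.SpikeTrain(np.sort(rng.uniform(0, 4, 30)), "u2", "VP"),
    ]
    blocks = [oe.TrialBlock("S+A", 0.0, 1.5, True), oe.TrialBlock("S-B", 2.0, 3.5, False)]
    presses = np.sort(rng.uniform(0, 4, 12))
    events = oe.EventSeries(presses, presses[::3])
    return oe.Session([sig], spikes, [stim], blocks, events, {"subject": "r1", "day": 3})
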