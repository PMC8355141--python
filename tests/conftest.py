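import numpy as np
import pytest

from thetaseq.session import LFPChannel, SequenceEvent, Session, SpikeTrain
from thetaseq.spectral import bandpass_phase, preprocess_lfp
from thetaseq.synth import default_config, generate_session


def make_toy_session(n_stimuli=3, n_iterations=4, fs=1000.0, probe_events=()):
    """Small hand-built session: trials of 2 s, one unit, one channel."""
    events = []
    k = 0
    for it in range(n_iterations):
        for pos in range(n_stimuli):
            onset = 2.0 * k
            events.append(
                SequenceEvent(
                    iteration_index=it,
                    position=pos,
                    stimulus_id=pos,
                    onset_s=onset,
                    offset_s=onset + 1.5,
                    is_probe=(it, pos) in probe_events,
                )
            )
            k += 1
    duration = 2.0 * k + 1.0
    t = np.arange(int(duration * fs)) / fs
    lfp = LFPChannel("ch0", fs, 10.0 * np.cos(2 * np.pi * 6.0 * t))
    spikes = SpikeTrain("u0", "ch0", np.arange(0.5, duration - 0.9, 1.0), "single")
    return Session(
        session_id="toy",
        n_stimuli=n_stimuli,
        events=events,
        spikes=[spikes],
        lfp=[lfp],
        unit_to_lfp={"u0": "ch0"},
    )


@pytest.fixture
def toy_session():
    return make_toy_session()


@pytest.fixture(scope="session")
def synthetic_session():
    """Moderate default-condition session shared by read-only tests."""
    return generate_session(default_config(12, seed=3))


@pytest.fixture(scope="session")
def synthetic_theta(synthetic_session):
    return {
        ch.channel_id: bandpass_phase(preprocess_lfp(ch), (4.0, 8.0), "theta")
        for ch in synthetic_session.lfp
    }
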