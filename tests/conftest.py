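import numpy as np
import pytest

from eegsync.io import Recording
from eegsync.synth import (
    ArtifactSpec,
    OscillatorSpec,
    SeizureSpec,
    SynthConfig,
    gen_recording,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_recording(rng) -> Recording:
    """4-channel, 8-second noise recording at 256 Hz."""
    return Recording(data=rng.standard_normal((4, 8 * 256)), fs=256.0)


@pytest.fixture(scope="session")
def event_recording():
    """2-minute, 23-channel recording with one seizure and one artifact."""
    cfg = SynthConfig(
        duration=120.0,
        seed=7,
        seizures=(SeizureSpec(onset=80.0, offset=100.0),),
        artifacts=(ArtifactSpec(onset=40.0, offset=42.0, channels=(3, 17)),),
    )
    rec, gt = gen_recording(cfg)
    return rec, gt


@pytest.fixture(scope="session")
def oscillator_pair():
    """Two coupled phase oscillators plus one uncoupled bystander, in
    the drift (non-phase-locked) regime where coupling is identifiable."""
    K = np.zeros((3, 3))
    K[0, 1] = K[1, 0] = 0.6
    spec = OscillatorSpec(
        omegas=(2.0, 3.5, 5.5),
        coupling=tuple(map(tuple, K)),
        step=0.005,
        noise_std=0.005,
        seed=11,
    )
    from eegsync.synth import simulate_oscillators

    rec, gt = simulate_oscillators(spec, duration=40.0)
    return rec, gt
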