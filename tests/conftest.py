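import numpy as np
import pytest

from ernakit import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_recording():
    """Noiseless, artifact-free recording: analysis must recover the
    template exactly (up to one sample)."""
    return synth.generate_recording(
        seed=7, duration=1.0, prestim=2.0, noise_rms=0.0, artifact_amp=0.0,
        spiking=synth.SpikingParams(baseline_rate=0.0),
    )


@pytest.fixture(scope="session")
def noisy_recording():
    """Default synthetic recording (noise + artifact + spiking), 3 s train."""
    return synth.generate_recording(seed=11, duration=3.0)
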