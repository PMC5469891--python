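import logging

import numpy as np
import pytest

import hrv2d as h

logging.getLogger("hrv2d").setLevel(logging.WARNING)


def make_tone(amp, freq, duration=300.0, fs=4.0, phase=0.0):
    """Uniform tachogram carrying a single pure tone (oracle: amp**2/2)."""
    t = np.arange(0.0, duration, 1.0 / fs)
    return h.UniformTachogram(fs=fs, t0=0.0, values=amp * np.sin(2 * np.pi * freq * t + phase))


@pytest.fixture(scope="session")
def part1_run():
    """One full simulated rest/math/rest/exercise/rest recording (seed 0)
    with its per-window feature table under the default configuration."""
    config = h.RunConfig()
    beats, segments = h.generate_protocol(h.part1_protocol(seed=0))
    features = h.extract_features(beats, segments, config)
    return beats, segments, features, config
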