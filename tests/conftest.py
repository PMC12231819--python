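import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles

from resteeg.io import Recording
from resteeg.synth import GroupSpec, gen_resting_eeg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """Two tiny groups differing only in delta amplitude (x2)."""
    groups = [
        GroupSpec("N", n_subjects=4, delta_gain=1.0, seed=101),
        GroupSpec("A+P+", n_subjects=4, delta_gain=2.0, seed=102),
    ]
    recs, participants = gen_resting_eeg(groups, n_channels=4, fs=250,
                                         duration_s=60)
    return recs, participants


@pytest.fixture
def sine_recording():
    """Unit-amplitude 10 Hz sine, 250 Hz, 120 s, two channels."""
    fs, dur = 250.0, 120.0
    t = np.arange(int(fs * dur)) / fs
    x = np.sin(2 * np.pi * 10.0 * t)
    return Recording("sine", fs, ["a", "b"], np.vstack([x, x.copy()]))


@pytest.fixture
def noise_recording(rng):
    """Two independent white-noise channels, 90 x 4-s segments."""
    n = 90 * 1000
    data = rng.standard_normal((2, n))
    return Recording("noise", 250.0, ["a", "b"], data)
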