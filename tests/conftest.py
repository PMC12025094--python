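import numpy as np
import pytest

from gaitbbs.data_io import CHANNELS, ImuRecording
from gaitbbs.preprocessing import GaitDataset
from gaitbbs.simulate import SimConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_recording(rng):
    """A 10-s walking recording with a 2-s static baseline (validation-grade)."""
    walking = rng.normal(0.0, 1.0, size=(1000, len(CHANNELS)))
    static = rng.normal(0.0, 0.05, size=(1000, len(CHANNELS)))
    return ImuRecording(subject_id="s00", walking=walking, static=static,
                        group="young_hc", sample_rate=100.0)


@pytest.fixture(scope="session")
def short_sim_config():
    """Simulator settings for quick tests: 20-s walks, 2-s static baseline."""
    return SimConfig(duration_seconds=20.0, static_seconds=2.0)


@pytest.fixture(scope="session")
def toy_dataset(rng):
    """64 random standardized windows with labels tied to channel variance.

    Window i's label increases with the amplitude of channel 0, so even a
    brief fit has signal to latch onto; used for smoke/one-epoch tests.
    """
    n = 64
    amp = rng.uniform(0.5, 3.0, size=n)
    t = np.arange(200) / 100.0
    X = rng.normal(0.0, 0.3, size=(n, 200, 12))
    X[:, :, 0] += amp[:, None] * np.sin(2 * np.pi * 1.25 * t)
    y = (amp - amp.min()) / (amp.max() - amp.min())
    sids = np.array([f"t{i % 8}" for i in range(n)])
    groups = np.array(["unknown"] * n)
    return GaitDataset(X, y, sids, groups)
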