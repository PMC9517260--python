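import numpy as np
import pytest

from hear.data import SensorStream
from hear.generate import generate_dataset, make_profiles, scenario
from hear.nn import NetworkSpec


def make_stream(sensor_id=1, t0=0, n=100, label="cooking", seed=0):
    """A small single-label stream with unit-step timestamps."""
    rng = np.random.default_rng(seed)
    return SensorStream(
        sensor_id=sensor_id,
        timestamps=np.arange(t0, t0 + n),
        values=rng.normal(size=(n, 9)),
        labels=np.full(n, label),
    )


@pytest.fixture(scope="session")
def tiny_spec():
    """A scaled-down architecture for fast training tests."""
    return NetworkSpec(
        t_in=12, n_sensors=2, n_channels=2, lstm_units=4,
        conv1d_filters=2, conv1d_kernel=3, conv2d_sensor_filters=2,
        conv2d_fused_filters=4, head=(8, 6), n_classes=3, dropout=0.0,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A 3-class dataset matching ``tiny_spec`` geometry (no wavelet step)."""
    profiles = make_profiles(3, seed=0, n_channels=2, noise_std=0.3,
                             phase_jitter=0.2)
    scen = scenario("S1", majority=30, class_names=("a", "b", "c"))
    return generate_dataset(profiles, scen, T=12, S=2, seed=0)
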