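import numpy as np
import pytest

from fishbeat.synthgen import SyntheticEmbryoConfig

FPS = 67.0
DT = 1.0 / FPS


@pytest.fixture
def small_config() -> SyntheticEmbryoConfig:
    """A quick-to-render single-chamber embryo at the wild-type rate."""
    return SyntheticEmbryoConfig(
        true_bpm=150.0,
        duration_s=10.0,
        fps=FPS,
        frame_shape=(64, 64),
        base_radius=15.0,
        radius_amplitude=4.0,
        rng_seed=42,
    )


@pytest.fixture
def noiseless_config(small_config) -> SyntheticEmbryoConfig:
    from dataclasses import replace

    return replace(small_config, noise_sigma=0.0)


def sine_chronology(freq_hz, n=304, dt=0.015, amp=1.0, phase=0.0, offset=0.0):
    from fishbeat.spectral import Chronology

    t = np.arange(n) * dt
    return Chronology(
        values=offset + amp * np.sin(2 * np.pi * freq_hz * t + phase), times=t
    )
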