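import numpy as np
import pytest

from barovar import BeatSeries, SimConfig


def clean_sim(**overrides) -> SimConfig:
    """Noise-free, fully coupled simulation with slow SBP oscillations.

    The 0.4 Hz (Mayer-wave) and 0.1 Hz components produce multi-beat
    monotonic SBP ramps so the sequence method has material to work on.
    """
    kwargs = dict(
        duration=410.0,
        mean_sbp=120.0,
        pulse_pressure=30.0,
        mean_hr=350.0,
        components=((0.4, 3.0, 0.0), (0.1, 2.0, 0.0)),
        gain=1.5,
        lag=3,
        coupling_prob=1.0,
        sbp_noise_sd=0.0,
        pi_noise_sd=0.0,
        seed=0,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def beats_from_arrays(t, sbp, pi, dbp_offset=30.0) -> BeatSeries:
    """Hand-built beat series; DBP is SBP minus a constant."""
    sbp = np.asarray(sbp, dtype=float)
    return BeatSeries.from_arrays(np.asarray(t, float), sbp, sbp - dbp_offset, np.asarray(pi, float))


@pytest.fixture
def sinusoid_waveform():
    """p(t) = 100 + 20 sin(2*pi*6 t) mmHg, 10 s at 1000 Hz."""
    from barovar import WaveformRecord

    t = np.arange(10_000) / 1000.0
    return WaveformRecord(1000.0, 100.0 + 20.0 * np.sin(2 * np.pi * 6.0 * t))
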