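"""Core containers: uniformly sampled pressure waveforms and per-beat series.

Units follow telemetry convention throughout the package: pressure in mmHg,
pulse interval (PI) in ms, heart rate in beats min^-1, time in s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MonotonicityViolated

BEAT_COLUMNS = ("t_s", "sbp_mmHg", "dbp_mmHg", "pi_ms", "hr_bpm")


@dataclass(frozen=True)
class WaveformRecord:
    """A uniformly sampled arterial pressure trace.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (Hz), > 0.
    pressure : numpy.ndarray
        Pressure samples in mmHg; finite, non-empty.
    start_time : float
        Time of the first sample in seconds (default 0).
    """

    sampling_rate: float
    pressure: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        p = np.asarray(self.pressure, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("pressure must be a non-empty 1-D series")
        if not np.all(np.isfinite(p)):
            raise ValueError("pressure values must be finite")
        object.__setattr__(self, "pressure", p)

    @property
    def duration(self) -> float:
        """Span of the trace in seconds."""
        return (len(self.pressure) - 1) / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(len(self.pressure)) / self.sampling_rate


@dataclass
class BeatSeries:
    """Per-beat event series.

    ``t`` is the time of each systolic maximum (s); ``sbp``/``dbp`` are the
    per-beat systolic/diastolic pressures (mmHg); ``pi`` is the pulse interval
    preceding each beat (ms) and ``hr = 60000 / pi`` (beats min^-1).  The first
    beat has no preceding interval, so ``pi[0]`` and ``hr[0]`` are NaN.
    """

    t: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    pi: np.ndarray
    hr: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in (self.t, self.sbp, self.dbp, self.pi, self.hr)]
        n = len(arrays[0])
        if any(len(a) != n for a in arrays):
            raise ValueError("all beat fields must have equal length")
        self.t, self.sbp, self.dbp, self.pi, self.hr = arrays
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise MonotonicityViolated("beat times must be strictly increasing")
        if n:
            with np.errstate(invalid="ignore"):
                bad = self.sbp <= self.dbp
            if np.any(bad):
                raise ValueError(f"sbp must exceed dbp beat-wise (first violation at beat {int(np.argmax(bad))})")
            ok = np.isfinite(self.pi)
            if np.any(self.pi[ok] <= 0):
                raise ValueError("pi must be positive")
            if not np.allclose(self.hr[ok], 60000.0 / self.pi[ok], rtol=1e-9, atol=0):
                raise ValueError("hr must equal 60000/pi")

    @classmethod
    def from_arrays(cls, t, sbp, dbp, pi) -> "BeatSeries":
        """Build a series from beat times, pressures and pulse intervals; HR is derived."""
        pi = np.asarray(pi, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            hr = np.where(np.isfinite(pi), 60000.0 / pi, np.nan)
        return cls(np.asarray(t, float), np.asarray(sbp, float), np.asarray(dbp, float), pi, hr)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def window(self, t_start: float, t_stop: float) -> "BeatSeries":
        """Beats with ``t_start <= t < t_stop`` (half-open window)."""
        m = (self.t >= t_start) & (self.t < t_stop)
        return BeatSeries(self.t[m], self.sbp[m], self.dbp[m], self.pi[m], self.hr[m])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "sbp_mmHg": self.sbp,
                "dbp_mmHg": self.dbp,
                "pi_ms": self.pi,
                "hr_bpm": self.hr,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BeatSeries":
        return cls(*(frame[c].to_numpy(dtype=float) for c in BEAT_COLUMNS))
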