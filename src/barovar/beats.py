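"""Beat-wise pressure-feature extraction from the arterial pulse wave.

Each cardiac cycle is reduced to four numbers: systolic pressure (SBP, the
pulse-wave maximum), diastolic pressure (DBP, the minimum of the inter-systolic
interval preceding the peak), pulse interval (PI, systole-to-systole, ms) and
heart rate (HR = 60000/PI).  Systolic peaks are the sharpest landmark of the
pulse wave, so PI is measured peak-to-peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import BeatSeries, WaveformRecord
from .errors import NoBeatsDetected

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BeatDetectConfig:
    """Systolic-peak detector settings.

    refractory : minimum distance between peaks in ms (default 100, i.e. a
        600 beats min^-1 ceiling, above any physiological rat heart rate).
    min_prominence : peak prominence threshold in mmHg (default 10; rat pulse
        pressure is around 30 mmHg).
    pi_outlier_filter : when True, reject beats whose PI falls outside
        median +/- 50% (artifact/ectopy guard; off by default).
    """

    refractory: float = 100.0
    min_prominence: float = 10.0
    pi_outlier_filter: bool = False

    def __post_init__(self) -> None:
        if not self.refractory > 0:
            raise ValueError("refractory must be positive")
        if self.min_prominence < 0:
            raise ValueError("min_prominence must be non-negative")


def detect_beats(waveform: WaveformRecord, cfg: BeatDetectConfig | None = None) -> BeatSeries:
    """Detect systolic peaks and derive the per-beat series.

    SBP is the waveform maximum of each cycle, DBP the minimum between the
    previous systolic peak and the current one (for the first beat, the
    minimum of the samples preceding its peak).  PI is the time between
    successive systolic maxima in ms; the first beat carries NaN PI/HR.

    Raises
    ------
    NoBeatsDetected
        If no peak satisfies the prominence/refractory constraints.
    """
    cfg = cfg or BeatDetectConfig()
    p = waveform.pressure
    fs = waveform.sampling_rate
    distance = max(1, int(round(cfg.refractory * 1e-3 * fs)))
    peaks, _ = find_peaks(p, distance=distance, prominence=cfg.min_prominence or None)
    if peaks.size == 0:
        raise NoBeatsDetected("no systolic peak satisfies the detector constraints")

    t = waveform.start_time + peaks / fs
    sbp = p[peaks]
    dbp = np.empty_like(sbp)
    # first beat: minimum of whatever precedes its peak (peak value if nothing does)
    dbp[0] = p[: peaks[0]].min() if peaks[0] > 0 else p[0]
    for i in range(1, len(peaks)):
        dbp[i] = p[peaks[i - 1] : peaks[i]].min()

    pi = np.full(len(peaks), np.nan)
    pi[1:] = np.diff(t) * 1000.0

    if cfg.pi_outlier_filter and len(peaks) > 2:
        med = np.nanmedian(pi)
        keep = np.isnan(pi) | ((pi > 0.5 * med) & (pi < 1.5 * med))
        n_drop = int((~keep).sum())
        if n_drop:
            log.info("PI outlier filter removed %d of %d beats", n_drop, len(peaks))
            t, sbp, dbp = t[keep], sbp[keep], dbp[keep]
            pi = np.full(len(t), np.nan)
            pi[1:] = np.diff(t) * 1000.0

    log.info("detected %d beats over %.1f s", len(t), waveform.duration)
    return BeatSeries.from_arrays(t, sbp, dbp, pi)
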