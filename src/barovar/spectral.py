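"""Short-term BP/HR variability spectra.

The beat-indexed series (systogram, diastogram or tachogram) is linearly
interpolated onto a uniform 20 Hz grid, optionally smoothed with a nine-point
Hanning-coefficient FIR filter, split into overlapping 2048-point segments
(linearly detrended), and Fourier-transformed.  Band powers use the rat
short-term variability scheme: VLF 0.0195-0.195 Hz, LF 0.195-0.8 Hz,
HF 0.8-3 Hz, total 0.0195-3 Hz; LF blood-pressure power indexes sympathetic
vasomotor modulation, HF reflects respiration, and the LF/HF heart-rate ratio
indexes sympathovagal balance.  Powers are variance-preserving one-sided bin
powers (mmHg^2 or (beats min^-1)^2), so the sum over all non-DC bins equals
the segment variance (Parseval).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import detrend as _lin_detrend
from scipy.signal.windows import hann

from .core import BeatSeries
from .errors import SeriesShorterThanNfft, SeriesTooShort, TooFewBeats

log = logging.getLogger(__name__)

#: Rat short-term variability band edges (Hz), half-open [low, high).
BANDS = {"vlf": (0.0195, 0.195), "lf": (0.195, 0.8), "hf": (0.8, 3.0)}
TOTAL_BAND = (0.0195, 3.0)


@dataclass(frozen=True)
class EvenSeries:
    """An evenly resampled beat-derived signal."""

    rate: float
    values: np.ndarray
    variable: str = "sbp"
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SpectralConfig:
    """Spectral-analysis settings (defaults follow the 410 s / 20 Hz scheme)."""

    resample_rate: float = 20.0
    nfft: int = 2048
    n_segments: int = 15
    window_length: float = 410.0
    hann9: bool = True
    detrend: bool = True
    segment_taper: bool = False  # optional per-segment Hann taper, off by default
    bands: dict = field(default_factory=lambda: dict(BANDS))
    total_band: tuple[float, float] = TOTAL_BAND

    def __post_init__(self) -> None:
        if self.nfft < 2 or self.n_segments < 1:
            raise ValueError("nfft and n_segments must be positive")
        if self.nfft > self.window_length * self.resample_rate:
            raise ValueError("nfft exceeds the samples available in one window")
        edges = sorted(self.bands.values())
        for (a, b), (c, d) in zip(edges, edges[1:]):
            if not (a < b <= c < d):
                raise ValueError("band edges must be ordered and non-overlapping")
        lo = min(b[0] for b in self.bands.values())
        hi = max(b[1] for b in self.bands.values())
        if (lo, hi) != tuple(self.total_band):
            raise ValueError("bands must partition the total interval exactly")


@dataclass(frozen=True)
class BandPowers:
    """Band powers for one variable; NaN marks undefined ratio/peak."""

    vlf: float
    lf: float
    hf: float
    total: float
    vlf_nu: float
    lf_nu: float
    hf_nu: float
    lf_hf_ratio: float
    hf_peak_freq: float
    freqs: np.ndarray = field(repr=False, compare=False, default=None)
    power: np.ndarray = field(repr=False, compare=False, default=None)

    def to_dict(self) -> dict:
        return {
            "vlf": self.vlf,
            "lf": self.lf,
            "hf": self.hf,
            "total": self.total,
            "vlf_nu": self.vlf_nu,
            "lf_nu": self.lf_nu,
            "hf_nu": self.hf_nu,
            "lf_hf_ratio": self.lf_hf_ratio,
            "hf_peak_freq_hz": self.hf_peak_freq,
        }


def resample_even(beats: BeatSeries, variable: str, rate: float = 20.0) -> EvenSeries:
    """Linearly interpolate a per-beat variable onto a uniform grid.

    ``variable`` is one of ``sbp``, ``dbp``, ``hr`` (or ``pi``).  Beats with a
    missing value (the first beat's PI/HR) are dropped, so HR resampling
    starts at the second beat.  The grid covers the span of the valid beats;
    no extrapolation is performed.
    """
    values = getattr(beats, variable)
    ok = np.isfinite(values)
    t, v = beats.t[ok], values[ok]
    if len(t) < 2:
        raise TooFewBeats("resampling needs at least two beats with defined values")
    n = int(math.floor((t[-1] - t[0]) * rate)) + 1
    grid = t[0] + np.arange(n) / rate
    return EvenSeries(rate, np.interp(grid, t, v), variable, t0=float(t[0]))


# nine-point Hann-coefficient smoothing kernel: w_k ∝ sin²(πk/8), k = 0..8,
# zero at the endpoints, normalised to unit sum (DC gain 1)
HANN9_KERNEL = (lambda w: w / w.sum())(np.sin(np.pi * np.arange(9) / 8.0) ** 2)


def hann9_response(freq: float, rate: float) -> float:
    """Analytic magnitude response of the nine-point kernel at ``freq`` Hz."""
    k = np.arange(9) - 4
    return float(abs(np.sum(HANN9_KERNEL * np.exp(-2j * np.pi * freq / rate * k))))


def hann9_filter(series: EvenSeries) -> EvenSeries:
    """Zero-phase nine-point Hanning smoothing with reflect padding."""
    if len(series) < 9:
        raise SeriesTooShort("nine-point filter needs at least 9 samples")
    padded = np.pad(series.values, 4, mode="reflect")
    out = np.convolve(padded, HANN9_KERNEL, mode="valid")
    return EvenSeries(series.rate, out, series.variable, series.t0)


def segment_series(series: EvenSeries, cfg: SpectralConfig | None = None) -> list[np.ndarray]:
    """Split a series into overlapping nfft-point segments.

    The segment step is ``floor((N - nfft) / (n_seg - 1))`` so the requested
    number of segments tiles the window (a single segment when N == nfft);
    overlap follows from (N, nfft, n_segments) rather than being fixed.  Each
    segment is independently linearly detrended when ``cfg.detrend`` is on.
    """
    cfg = cfg or SpectralConfig()
    x = series.values
    n = len(x)
    if n < cfg.nfft:
        raise SeriesShorterThanNfft(f"series of {n} samples is shorter than nfft={cfg.nfft}")
    if n == cfg.nfft:
        starts = [0]
    else:
        n_seg = min(cfg.n_segments, n - cfg.nfft + 1)
        if n_seg == 1:
            starts = [0]
        else:
            step = (n - cfg.nfft) // (n_seg - 1)
            starts = [i * step for i in range(n_seg)]
    segments = [x[s : s + cfg.nfft].copy() for s in starts]
    if cfg.detrend:
        segments = [_lin_detrend(seg, type="linear") for seg in segments]
    log.info("segmented %d samples into %d segments of %d", n, len(segments), cfg.nfft)
    return segments


def _segment_power(seg: np.ndarray, taper: bool) -> np.ndarray:
    """One-sided bin powers (DC excluded) scaled so their sum is the variance."""
    n = len(seg)
    if taper:
        w = hann(n, sym=False)
        seg = (seg - seg.mean()) * w
        norm = np.mean(w**2)
    else:
        norm = 1.0
    spec = np.fft.rfft(seg)
    p = (np.abs(spec) ** 2) / (n * n) / norm
    p[1:] *= 2.0
    if n % 2 == 0:
        p[-1] /= 2.0  # Nyquist bin is not duplicated
    return p[1:]  # DC excluded


def band_spectrum(segments: list[np.ndarray], cfg: SpectralConfig | None = None) -> BandPowers:
    """Average the per-segment spectra and integrate over the VLF/LF/HF bands.

    Band membership assigns each bin's centre frequency ``k * rate / nfft`` to
    the half-open interval [low, high) containing it, so the three bands
    partition the total interval exactly and band powers are additive.  When
    every segment is constant the powers are zero and the ratio and HF peak
    are undefined (NaN).
    """
    cfg = cfg or SpectralConfig()
    if not segments:
        raise ValueError("need at least one segment")
    power = np.mean([_segment_power(np.asarray(s, float), cfg.segment_taper) for s in segments], axis=0)
    freqs = np.arange(1, len(power) + 1) * cfg.resample_rate / cfg.nfft

    band_power = {
        name: float(power[(freqs >= lo) & (freqs < hi)].sum()) for name, (lo, hi) in cfg.bands.items()
    }
    total = float(sum(band_power.values()))
    vlf, lf, hf = band_power["vlf"], band_power["lf"], band_power["hf"]

    if total > 0:
        vlf_nu, lf_nu, hf_nu = vlf / total, lf / total, hf / total
    else:
        vlf_nu = lf_nu = hf_nu = math.nan
    lf_hf = lf / hf if hf > 0 else math.nan
    hf_mask = (freqs >= cfg.bands["hf"][0]) & (freqs < cfg.bands["hf"][1])
    if np.any(hf_mask) and power[hf_mask].max() > 0:
        hf_peak = float(freqs[hf_mask][np.argmax(power[hf_mask])])
    else:
        hf_peak = math.nan
    return BandPowers(vlf, lf, hf, total, vlf_nu, lf_nu, hf_nu, lf_hf, hf_peak, freqs, power)


def analyze_spectrum(beats: BeatSeries, variable: str, cfg: SpectralConfig | None = None) -> BandPowers:
    """Full spectral chain for one variable of a beat series.

    resample_even -> hann9_filter (if enabled) -> segment_series (with
    per-segment detrend) -> band_spectrum.
    """
    cfg = cfg or SpectralConfig()
    series = resample_even(beats, variable, cfg.resample_rate)
    if cfg.hann9:
        series = hann9_filter(series)
    segments = segment_series(series, cfg)
    return band_spectrum(segments, cfg)
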