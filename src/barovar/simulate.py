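"""Synthetic baroreflex-coupled hemodynamics.

The generator produces beat series (and, via :func:`render_waveform`,
pulse-pressure traces) with known ground truth.  Systolic pressure is a mean
plus sinusoidal components defined in continuous time and sampled at the
irregular beat times — so downstream spectral estimates inherit the same
resampling distortions as real telemetry.  The pulse interval follows a lagged
linear baroreflex law: the interval ending at beat ``n`` is

    PI_n = 60000/mean_hr + gain * (SBP_{n-lag} - mean_sbp) + noise

whenever the reflex is engaged, so the sequence method applied to the output
recovers ``gain`` at exactly ``lag`` beats.  Reflex engagement is drawn once
per monotonic SBP run (Bernoulli with ``coupling_prob``); a turning-point beat
shared by two runs is engaged if either run is, so a flagged ramp is coupled
end-to-end and the effectiveness index is binomial around ``coupling_prob``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core import BeatSeries, WaveformRecord
from .errors import RateTooLow, UnknownPreset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic beat series.

    components / hr_components are (frequency Hz, amplitude, phase rad)
    triples; amplitudes are mmHg on SBP and beats min^-1 on HR (HR components
    enter through PI, converted at the operating point).  ``gain`` is the
    baroreflex slope in ms mmHg^-1, ``lag`` the reflex delay in beats.
    """

    duration: float = 410.0
    mean_sbp: float = 120.0
    pulse_pressure: float = 30.0
    mean_hr: float = 350.0
    components: tuple = ()
    hr_components: tuple = ()
    gain: float = 1.5
    lag: int = 3
    coupling_prob: float = 1.0
    sbp_noise_sd: float = 0.0
    pi_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not self.mean_sbp > self.pulse_pressure > 0:
            raise ValueError("need mean_sbp > pulse_pressure > 0")
        if not self.mean_hr > 0:
            raise ValueError("mean_hr must be positive")
        if self.lag < 1:
            raise ValueError("lag must be at least 1 beat")
        if not 0 <= self.coupling_prob <= 1:
            raise ValueError("coupling_prob must lie in [0, 1]")
        for f, a, _ in tuple(self.components) + tuple(self.hr_components):
            if f <= 0 or a < 0:
                raise ValueError("component frequencies must be positive, amplitudes non-negative")
        object.__setattr__(self, "components", tuple(tuple(c) for c in self.components))
        object.__setattr__(self, "hr_components", tuple(tuple(c) for c in self.hr_components))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did: per-beat reflex engagement and parameters."""

    coupled: np.ndarray
    gain: float
    lag: int
    components: tuple
    hr_components: tuple
    seed: int

    def to_dict(self) -> dict:
        return {
            "gain_ms_per_mmHg": self.gain,
            "lag_beats": self.lag,
            "components": [list(c) for c in self.components],
            "hr_components": [list(c) for c in self.hr_components],
            "seed": self.seed,
            "coupled": [bool(b) for b in self.coupled],
        }


@dataclass(frozen=True)
class RenderConfig:
    """Waveform rendering settings: sampling rate and systolic upstroke fraction."""

    rate: float = 1000.0
    systolic_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.rate < 100:
            raise RateTooLow("rendering rate below 100 Hz cannot resolve the pulse wave")
        if not 0 < self.systolic_fraction < 1:
            raise ValueError("systolic_fraction must lie in (0, 1)")


def _osc(components, t: float) -> float:
    return sum(a * np.sin(2 * np.pi * f * t + ph) for f, a, ph in components)


def simulate_beats(cfg: SimConfig) -> tuple[BeatSeries, GroundTruth]:
    """Generate a beat series by the lagged baroreflex recursion.

    Beats are produced until the series spans ``cfg.duration`` seconds (the
    final beat may slightly exceed it so a full analysis window is always
    covered).  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    pi0 = 60000.0 / cfg.mean_hr
    # HR-band oscillation amplitude converted to PI at the operating point
    pi_components = tuple(
        (f, a * 60000.0 / cfg.mean_hr**2, ph) for f, a, ph in cfg.hr_components
    )

    t = [0.0]
    sbp = [cfg.mean_sbp + _osc(cfg.components, 0.0) + (rng.normal(0.0, cfg.sbp_noise_sd) if cfg.sbp_noise_sd else 0.0)]
    pi = [np.nan]
    run_flags: list[bool] = []  # one engagement flag per monotone SBP run
    diff_run: list[int] = []  # diff_run[m] = run id of the SBP step (m-1 -> m)
    prev_dir = 0

    def coupled(j: int) -> bool:
        """Beat j is engaged if either monotone run touching it is engaged."""
        flags = []
        if j >= 1 and j - 1 < len(diff_run):
            flags.append(run_flags[diff_run[j - 1]])
        if j < len(diff_run):
            flags.append(run_flags[diff_run[j]])
        return any(flags)

    n = 0
    max_beats = int(cfg.duration * cfg.mean_hr / 60.0 * 3) + 16
    while t[-1] < cfg.duration and n < max_beats:
        n += 1
        src = n - cfg.lag
        interval = pi0
        if src >= 0 and cfg.gain != 0.0 and coupled(src):
            interval += cfg.gain * (sbp[src] - cfg.mean_sbp)
        if pi_components:
            interval -= _osc(pi_components, t[-1])
        if cfg.pi_noise_sd:
            interval += rng.normal(0.0, cfg.pi_noise_sd)
        interval = max(interval, 20.0)  # physiological floor, never hit at sane settings
        t.append(t[-1] + interval / 1000.0)
        pi.append(interval)
        s = cfg.mean_sbp + _osc(cfg.components, t[-1])
        if cfg.sbp_noise_sd:
            s += rng.normal(0.0, cfg.sbp_noise_sd)
        sbp.append(s)
        d = 1 if sbp[-1] > sbp[-2] else (-1 if sbp[-1] < sbp[-2] else 0)
        if d != prev_dir or not run_flags:
            run_flags.append(bool(rng.random() < cfg.coupling_prob))
            prev_dir = d
        diff_run.append(len(run_flags) - 1)

    sbp_arr = np.asarray(sbp)
    beats = BeatSeries.from_arrays(np.asarray(t), sbp_arr, sbp_arr - cfg.pulse_pressure, np.asarray(pi))
    flags = np.array([coupled(j) for j in range(len(beats))], dtype=bool)
    log.info("simulated %d beats over %.1f s (seed %d)", len(beats), beats.duration, cfg.seed)
    return beats, GroundTruth(flags, cfg.gain, cfg.lag, cfg.components, cfg.hr_components, cfg.seed)


def render_waveform(beats: BeatSeries, cfg: RenderConfig | None = None) -> WaveformRecord:
    """Render a pulse-pressure trace whose beat-wise features match ``beats``.

    Each inter-systolic interval decays exponential-like from the previous
    beat's SBP to the next beat's DBP, then rises to the next SBP along a
    raised cosine spanning ``systolic_fraction`` of the interval, so systolic
    peaks fall exactly on the beat times.  A short synthetic lead-in before
    the first beat and tail after the last make every peak detectable.
    """
    cfg = cfg or RenderConfig()
    if len(beats) < 1:
        raise ValueError("need at least one beat")
    dt = 1.0 / cfg.rate
    mean_pi_s = float(np.nanmean(beats.pi)) / 1000.0 if np.any(np.isfinite(beats.pi)) else 60.0 / 350.0

    lead = cfg.systolic_fraction * mean_pi_s
    t0 = beats.t[0] - lead
    t1 = beats.t[-1] + lead
    n = int(round((t1 - t0) / dt)) + 1
    grid = t0 + np.arange(n) * dt
    out = np.empty(n)

    def upstroke(tt, ta, tb, va, vb):
        u = (tt - ta) / (tb - ta)
        return va + (vb - va) * 0.5 * (1.0 - np.cos(np.pi * u))

    def decay(tt, ta, tb, va, vb):
        tau = (tb - ta) / 3.0
        e = np.exp(-(tt - ta) / tau)
        e_end = np.exp(-(tb - ta) / tau)
        return vb + (va - vb) * (e - e_end) / (1.0 - e_end)

    # lead-in: raised-cosine rise from DBP_0 to SBP_0 ending at the first beat
    m = grid < beats.t[0]
    out[m] = upstroke(grid[m], t0, beats.t[0], beats.dbp[0], beats.sbp[0])
    # each inter-systolic interval: decay to the next DBP, then upstroke to the next SBP
    for i in range(len(beats) - 1):
        ta, tb = beats.t[i], beats.t[i + 1]
        trough = tb - cfg.systolic_fraction * (tb - ta)
        m = (grid >= ta) & (grid < trough)
        out[m] = decay(grid[m], ta, trough, beats.sbp[i], beats.dbp[i + 1])
        m = (grid >= trough) & (grid < tb)
        out[m] = upstroke(grid[m], trough, tb, beats.dbp[i + 1], beats.sbp[i + 1])
    # tail: decay after the last beat so the final peak has a right flank
    m = grid >= beats.t[-1]
    out[m] = decay(grid[m], beats.t[-1], t1 + dt, beats.sbp[-1], beats.dbp[-1])
    return WaveformRecord(cfg.rate, out, start_time=t0)


#: Simulator presets.  The two baseline presets use the study-group means
#: (Wistar: SBP 109, DBP 79, HR 352, BRS 1.5; borderline hypertensive:
#: SBP 134, DBP 99, HR 328, BRS 2.2) as generative parameters; the demo
#: presets place a single oscillation at the Mayer-wave (0.4 Hz) or rat
#: respiratory (1.33 Hz) frequency.
_PRESETS = {
    "wistar_baseline": SimConfig(
        duration=410.0,
        mean_sbp=109.0,
        pulse_pressure=30.0,
        mean_hr=352.0,
        components=((0.08, 2.5, 0.0), (0.4, 1.5, 0.0), (1.33, 1.0, 0.0)),
        gain=1.5,
        lag=3,
        coupling_prob=0.9,
        sbp_noise_sd=3.0,
        pi_noise_sd=2.0,
    ),
    "bhr_baseline": SimConfig(
        duration=410.0,
        mean_sbp=134.0,
        pulse_pressure=35.0,
        mean_hr=328.0,
        components=((0.08, 2.0, 0.0), (0.4, 1.5, 0.0), (1.33, 1.0, 0.0)),
        gain=2.2,
        lag=3,
        coupling_prob=0.8,
        sbp_noise_sd=3.0,
        pi_noise_sd=2.0,
    ),
    "lf_tone_demo": SimConfig(
        duration=410.0,
        mean_sbp=120.0,
        pulse_pressure=30.0,
        mean_hr=350.0,
        components=((0.4, 2.0, 0.0),),
        gain=1.5,
        lag=3,
        coupling_prob=1.0,
    ),
    "resp_demo": SimConfig(
        duration=410.0,
        mean_sbp=120.0,
        pulse_pressure=30.0,
        mean_hr=350.0,
        components=((1.33, 2.0, 0.0),),
        gain=1.5,
        lag=3,
        coupling_prob=1.0,
    ),
}


def make_preset(name: str, seed: int | None = None, **overrides) -> SimConfig:
    """Return a documented preset configuration, optionally reseeded/overridden."""
    try:
        cfg = _PRESETS[name]
    except KeyError:
        raise UnknownPreset(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None
    if seed is not None:
        overrides["seed"] = seed
    return replace(cfg, **overrides) if overrides else cfg


def preset_names() -> list[str]:
    return sorted(_PRESETS)
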