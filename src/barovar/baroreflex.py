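"""Spontaneous baroreflex quantification by the sequence method.

A baroreflex *sequence* is a spontaneous ramp of consecutively rising (or
falling) systolic pressures followed, 3-5 beats later, by a same-direction
monotonic run of pulse intervals.  Four features summarise the reflex:

* sensitivity (BRS, ms mmHg^-1) — the least-squares slope of PI on SBP,
  averaged over all identified sequences;
* effectiveness index (BEI) — the fraction of SBP ramps that evoke a
  qualifying PI response;
* operating range (ms·mmHg) — the area of the axis-aligned rectangle
  covering the central 95% of sequence (SBP, PI) pairs;
* set point — the component-wise median of all sequence (SBP, PI) pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import BeatSeries
from .errors import DegenerateFit

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequenceConfig:
    """Sequence-method thresholds.

    min_len : minimum ramp/response length in beats (default 4).
    lags : candidate PI delays in beats (default (3, 4, 5)).
    delta_sbp, delta_pi : per-step amplitude thresholds; 0 means strict
        monotonicity only.  Common literature values (1 mmHg, 1 ms) can be set
        here.
    r_min : minimum Pearson correlation for an accepted sequence (default
        0.85, standard sequence-method practice).
    """

    min_len: int = 4
    lags: tuple[int, ...] = (3, 4, 5)
    delta_sbp: float = 0.0
    delta_pi: float = 0.0
    r_min: float = 0.85

    def __post_init__(self) -> None:
        if self.min_len < 2:
            raise ValueError("min_len must be at least 2")
        if not self.lags:
            raise ValueError("lags must be non-empty")
        if any(l < 1 for l in self.lags):
            raise ValueError("lags must be positive")
        if self.delta_sbp < 0 or self.delta_pi < 0:
            raise ValueError("amplitude thresholds must be non-negative")
        if not 0 <= self.r_min <= 1:
            raise ValueError("r_min must lie in [0, 1]")
        object.__setattr__(self, "lags", tuple(sorted(self.lags)))


@dataclass(frozen=True)
class Ramp:
    """A maximal run of strictly monotonic SBP of at least ``min_len`` beats."""

    start_index: int
    direction: int  # +1 up, -1 down
    length: int
    sbp_values: np.ndarray


@dataclass(frozen=True)
class BaroSequence:
    """A ramp matched by a monotonic PI response at one lag."""

    ramp: Ramp
    lag: int
    pi_values: np.ndarray
    slope: float
    intercept: float
    r: float


@dataclass(frozen=True)
class BaroreflexResult:
    """Sequence-method summary; undefined fields are NaN when no sequence exists."""

    brs: float
    bei: float
    operating_range_area: float
    sbp_span: float
    pi_span: float
    set_point_sbp: float
    set_point_pi: float
    n_sequences: int
    n_ramps: int

    def to_dict(self) -> dict:
        return {
            "brs_ms_per_mmHg": self.brs,
            "bei": self.bei,
            "operating_range": {
                "sbp_span_mmHg": self.sbp_span,
                "pi_span_ms": self.pi_span,
                "area_ms_mmHg": self.operating_range_area,
            },
            "set_point": {"sbp_mmHg": self.set_point_sbp, "pi_ms": self.set_point_pi},
            "n_ramps": self.n_ramps,
            "n_sequences": self.n_sequences,
        }


def _monotone_runs(x: np.ndarray, delta: float) -> list[tuple[int, int, int]]:
    """Maximal runs (start, stop_exclusive, direction) with per-step |change| > delta.

    NaN steps and steps at or below the threshold break runs.
    """
    d = np.diff(x)
    with np.errstate(invalid="ignore"):
        step = np.where(d > delta, 1, np.where(-d > delta, -1, 0))
    step[~np.isfinite(d)] = 0
    runs: list[tuple[int, int, int]] = []
    i = 0
    n = len(step)
    while i < n:
        s = step[i]
        if s == 0:
            i += 1
            continue
        j = i
        while j < n and step[j] == s:
            j += 1
        runs.append((i, j + 1, int(s)))  # beats i .. j inclusive
        i = j
    return runs


def find_ramps(sbp: np.ndarray, cfg: SequenceConfig | None = None) -> list[Ramp]:
    """Identify maximal monotonic SBP ramps of at least ``min_len`` beats.

    A 6-beat monotonic run is one ramp, not three overlapping 4-beat ramps; a
    turning-point beat terminates one ramp and can open the next.
    """
    cfg = cfg or SequenceConfig()
    sbp = np.asarray(sbp, dtype=float)
    ramps = [
        Ramp(start, direction, stop - start, sbp[start:stop])
        for start, stop, direction in _monotone_runs(sbp, cfg.delta_sbp)
        if stop - start >= cfg.min_len
    ]
    log.info("found %d SBP ramps in %d beats", len(ramps), len(sbp))
    return ramps


def fit_sequence_slope(sbp_values: np.ndarray, pi_values: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least-squares fit PI = slope * SBP + intercept; returns (slope, intercept, r).

    A constant PI response yields slope 0 and r 0 (rejected downstream by
    ``r_min``).  Raises :class:`DegenerateFit` when SBP has zero variance.
    """
    x = np.asarray(sbp_values, dtype=float)
    y = np.asarray(pi_values, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need at least two aligned points")
    if np.ptp(x) == 0:
        raise DegenerateFit("SBP values are all equal")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def _response_monotone(pi: np.ndarray, direction: int, delta: float) -> bool:
    d = np.diff(pi) * direction
    return bool(np.all(np.isfinite(d)) and np.all(d > delta))


def match_sequences(
    ramps: list[Ramp], pi: np.ndarray, cfg: SequenceConfig | None = None
) -> tuple[list[BaroSequence], int]:
    """Match each ramp against its delayed PI stream.

    For each ramp the PI run at every candidate lag is tested for
    same-direction monotonicity over the ramp's length; among qualifying lags
    the one with the largest |r| wins, so each ramp yields at most one
    sequence (keeping BEI <= 1).  Sequences with |r| below ``r_min`` are
    discarded.

    Returns
    -------
    (sequences, n_evaluable)
        ``n_evaluable`` counts ramps whose PI stream fits within the series at
        every candidate lag; a ramp at the series edge whose response window
        would overrun at some lag is skipped (not an error) and excluded from
        the BEI denominator, since it cannot be fully evaluated.
    """
    cfg = cfg or SequenceConfig()
    pi = np.asarray(pi, dtype=float)
    sequences: list[BaroSequence] = []
    n_evaluable = 0
    for ramp in ramps:
        if ramp.start_index + max(cfg.lags) + ramp.length > len(pi):
            continue
        n_evaluable += 1
        best: BaroSequence | None = None
        for lag in cfg.lags:
            lo = ramp.start_index + lag
            pi_run = pi[lo : lo + ramp.length]
            if not _response_monotone(pi_run, ramp.direction, cfg.delta_pi):
                continue
            slope, intercept, r = fit_sequence_slope(ramp.sbp_values, pi_run)
            if best is None or abs(r) > abs(best.r):
                best = BaroSequence(ramp, lag, pi_run, slope, intercept, r)
        if best is not None and abs(best.r) >= cfg.r_min and best.slope > 0:
            sequences.append(best)
    log.info("%d of %d evaluable ramps matched by a PI sequence", len(sequences), n_evaluable)
    return sequences, n_evaluable


def summarize_baroreflex(sequences: list[BaroSequence], n_ramps: int) -> BaroreflexResult:
    """Aggregate sequences into the four baroreflex features.

    BRS is the unweighted mean of per-sequence slopes.  The operating range
    pools every beat-level (SBP, PI) pair belonging to a sequence and takes
    the 2.5th-97.5th percentile width on each axis (linear-interpolation
    percentiles); the set point is the component-wise median of the same
    pooled points.  With no sequences the counts are kept and every other
    field is NaN.
    """
    n_seq = len(sequences)
    bei = n_seq / n_ramps if n_ramps > 0 else math.nan
    if n_seq == 0:
        nan = math.nan
        return BaroreflexResult(nan, bei, nan, nan, nan, nan, nan, 0, n_ramps)
    brs = float(np.mean([s.slope for s in sequences]))
    sbp_pool = np.concatenate([s.ramp.sbp_values for s in sequences])
    pi_pool = np.concatenate([s.pi_values for s in sequences])
    sbp_lo, sbp_hi = np.percentile(sbp_pool, [2.5, 97.5])
    pi_lo, pi_hi = np.percentile(pi_pool, [2.5, 97.5])
    sbp_span = float(sbp_hi - sbp_lo)
    pi_span = float(pi_hi - pi_lo)
    return BaroreflexResult(
        brs=brs,
        bei=bei,
        operating_range_area=sbp_span * pi_span,
        sbp_span=sbp_span,
        pi_span=pi_span,
        set_point_sbp=float(np.median(sbp_pool)),
        set_point_pi=float(np.median(pi_pool)),
        n_sequences=n_seq,
        n_ramps=n_ramps,
    )


def analyze_baroreflex(beats: BeatSeries, cfg: SequenceConfig | None = None) -> BaroreflexResult:
    """Full sequence-method analysis of a beat series.

    Composition of :func:`find_ramps` -> :func:`match_sequences` ->
    :func:`summarize_baroreflex` on the systogram/tachogram pair.
    """
    cfg = cfg or SequenceConfig()
    ramps = find_ramps(beats.sbp, cfg)
    sequences, n_evaluable = match_sequences(ramps, beats.pi, cfg)
    return summarize_baroreflex(sequences, n_evaluable)
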