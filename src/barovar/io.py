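"""Readers, writers and configuration for the interchange formats.

Waveforms and beat series travel as comma-separated UTF-8 CSV with '.'
decimals; beat files carry a mandatory header (t_s, sbp_mmHg, dbp_mmHg,
pi_ms, hr_bpm).  All writer/reader pairs round-trip values at full float
precision.  Analysis configuration can be loaded from YAML mirroring
:class:`AnalysisConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .baroreflex import SequenceConfig
from .beats import BeatDetectConfig
from .core import BEAT_COLUMNS, BeatSeries, WaveformRecord
from .errors import MissingColumn, MonotonicityViolated, NonUniformSampling, ParseError
from .spectral import SpectralConfig


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline-wide settings: window length plus the per-stage sub-configs."""

    window_length: float = 410.0
    beat: BeatDetectConfig = field(default_factory=BeatDetectConfig)
    sequence: SequenceConfig = field(default_factory=SequenceConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)

    def __post_init__(self) -> None:
        if not self.window_length > 0:
            raise ValueError("window_length must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "window_length" in raw:
            kwargs["window_length"] = float(raw["window_length"])
        for key, sub_cls in (("beat", BeatDetectConfig), ("sequence", SequenceConfig), ("spectral", SpectralConfig)):
            if key in raw:
                sub = dict(raw[key])
                if key == "sequence" and "lags" in sub:
                    sub["lags"] = tuple(sub["lags"])
                kwargs[key] = sub_cls(**sub)
        return cls(**kwargs)


def _numeric_frame(path, **kwargs) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, float_precision="round_trip", **kwargs)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error variety
        raise ParseError(f"could not parse {path}: {exc}") from exc
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(f"non-numeric value {frame[col][row]!r} in column {col!r} at data row {row}")
        frame[col] = coerced
    return frame


def read_waveform(path, rate: float) -> WaveformRecord:
    """Read a waveform CSV: one column (pressure) or two (time, pressure).

    An optional single header line is detected and skipped.  When a time
    column is present, its spacing must match ``1/rate`` within 0.1%.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    tokens = [t.strip() for t in first.strip().split(",") if t.strip() != ""]
    try:
        [float(t) for t in tokens]
        header = None
    except ValueError:
        header = 0
    frame = _numeric_frame(path, header=header)
    if frame.shape[1] not in (1, 2):
        raise ParseError(f"expected 1 or 2 columns, found {frame.shape[1]}")
    if frame.isna().any().any():
        row = int(frame.isna().any(axis=1).idxmax())
        raise ParseError(f"missing value at data row {row}")
    if frame.shape[1] == 2:
        t = frame.iloc[:, 0].to_numpy(dtype=float)
        p = frame.iloc[:, 1].to_numpy(dtype=float)
        dt = np.diff(t)
        if len(dt) and np.any(np.abs(dt * rate - 1.0) > 1e-3):
            raise NonUniformSampling(f"time column spacing inconsistent with {rate} Hz beyond 0.1%")
        start = float(t[0])
    else:
        p = frame.iloc[:, 0].to_numpy(dtype=float)
        start = 0.0
    return WaveformRecord(sampling_rate=rate, pressure=p, start_time=start)


def write_waveform(record: WaveformRecord, path, include_time: bool = True) -> None:
    """Write a waveform CSV (time_s, pressure_mmHg) at full float precision."""
    if include_time:
        frame = pd.DataFrame({"time_s": record.time, "pressure_mmHg": record.pressure})
    else:
        frame = pd.DataFrame({"pressure_mmHg": record.pressure})
    frame.to_csv(path, index=False, float_format="%.17g")


def read_beats(path) -> BeatSeries:
    """Read a beat CSV with the mandatory five-column header.

    Raises :class:`MissingColumn` for absent columns and
    :class:`MonotonicityViolated` for a decreasing time column.  A file with
    a header and no rows yields an empty series.
    """
    frame = _numeric_frame(path, header=0)
    for col in BEAT_COLUMNS:
        if col not in frame.columns:
            raise MissingColumn(f"beat file lacks mandatory column {col!r}")
    return BeatSeries.from_frame(frame)


def write_beats(series: BeatSeries, path) -> None:
    """Write a beat CSV at full float precision (lossless round trip)."""
    series.to_frame().to_csv(path, index=False, float_format="%.17g")
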