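"""End-to-end analysis: beats -> per-window baroreflex + spectra -> JSON report.

The recording is cut into non-overlapping windows of ``window_length`` seconds,
left-aligned at the first beat.  Each window gets a full sequence-method
baroreflex summary and VLF/LF/HF band powers for SBP, DBP and HR; the report
closes with mean ± SEM of every scalar metric across windows.  The report is a
pure function of (input, config), so identical inputs give identical JSON.
"""

from __future__ import annotations

import json
import logging
import math

import numpy as np

from .baroreflex import analyze_baroreflex
from .beats import detect_beats
from .core import BeatSeries, WaveformRecord
from .errors import WindowTooShort
from .io import AnalysisConfig
from .spectral import analyze_spectrum
from .stats import summarize

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"
SPECTRAL_VARIABLES = ("sbp", "dbp", "hr")


def _flatten(prefix: str, d: dict, out: dict) -> None:
    for k, v in d.items():
        key = f"{prefix}.{k}" if prefix else k
        if isinstance(v, dict):
            _flatten(key, v, out)
        elif isinstance(v, (int, float)):
            out[key] = v


def run_pipeline(data: BeatSeries | WaveformRecord, config: AnalysisConfig | None = None) -> dict:
    """Run the full analysis and return the report as a JSON-serialisable dict.

    ``data`` may be a raw waveform (beats are detected first) or an existing
    beat series.  Raises :class:`WindowTooShort` when the recording does not
    cover one analysis window.
    """
    config = config or AnalysisConfig()
    if isinstance(data, WaveformRecord):
        beats = detect_beats(data, config.beat)
    else:
        beats = data

    span = beats.duration
    n_windows = int(math.floor(span / config.window_length))
    if n_windows < 1:
        raise WindowTooShort(
            f"recording spans {span:.1f} s, shorter than one {config.window_length:.0f} s window"
        )
    log.info("analyzing %d window(s) of %.0f s (%d beats total)", n_windows, config.window_length, len(beats))

    windows = []
    for k in range(n_windows):
        t0 = beats.t[0] + k * config.window_length
        t1 = t0 + config.window_length
        wb = beats.window(t0, t1 + (1e-9 if k == n_windows - 1 else 0.0))
        baro = analyze_baroreflex(wb, config.sequence)
        spectra = {v: analyze_spectrum(wb, v, config.spectral).to_dict() for v in SPECTRAL_VARIABLES}
        windows.append(
            {
                "index": k,
                "t_start_s": float(t0),
                "t_end_s": float(t1),
                "n_beats": len(wb),
                "baroreflex": baro.to_dict(),
                "spectra": spectra,
            }
        )

    metrics: dict[str, list[float]] = {}
    for w in windows:
        flat: dict[str, float] = {}
        _flatten("baroreflex", w["baroreflex"], flat)
        for v in SPECTRAL_VARIABLES:
            _flatten(f"spectra.{v}", w["spectra"][v], flat)
        for key, val in flat.items():
            if isinstance(val, float) and math.isnan(val):
                continue
            metrics.setdefault(key, []).append(float(val))

    summary = {
        key: summarize(vals, key).to_dict() for key, vals in sorted(metrics.items()) if vals
    }
    return {
        "schema_version": SCHEMA_VERSION,
        "window_length_s": config.window_length,
        "n_windows": n_windows,
        "n_beats": len(beats),
        "windows": windows,
        "summary": summary,
    }


def _jsonify(obj):
    """Replace NaN with None recursively so the report is strict JSON."""
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def report_to_json(report: dict) -> str:
    """Deterministic strict-JSON rendering of a pipeline report."""
    return json.dumps(_jsonify(report), indent=2, sort_keys=True, allow_nan=False)
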