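"""End-to-end report: simulate 3 x 410 s, analyze every window, summarize.

The pipeline cuts the recording into non-overlapping 410 s windows and emits,
per window, the sequence-method baroreflex features and the VLF/LF/HF band
powers of SBP, DBP and HR, plus mean +/- SEM across windows.
"""

from barovar import make_preset, run_pipeline, simulate_beats

beats, _ = simulate_beats(make_preset("bhr_baseline", seed=5, duration=1230.0))
report = run_pipeline(beats)

print(f"{report['n_windows']} windows of {report['window_length_s']:.0f} s, "
      f"{report['n_beats']} beats total")
for key in ("baroreflex.brs_ms_per_mmHg", "baroreflex.bei",
            "spectra.sbp.lf", "spectra.hr.lf_hf_ratio"):
    s = report["summary"][key]
    sem = "n/a" if s["sem"] != s["sem"] else f"{s['sem']:.3f}"
    print(f"  {key}: {s['mean']:.3f} +/- {sem} (n={s['n']})")
print("-> values are mean +/- SEM across windows; BRS approaches the preset's "
      "2.2 ms/mmHg reflex gain, and the spectra summarize vasomotor and "
      "sympathovagal modulation per window.")
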