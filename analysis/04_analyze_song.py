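#!/usr/bin/env python
"""Analyze the synthetic song: eR trace, transition detection, focus recovery.

Generates a seeded sygyt scenario with a step transition (so the ground-truth
instant is unambiguous), synthesizes it, and runs the full analysis chain:
spectrogram (4096-sample Hamming window, 95% overlap), per-frame eR(1,2),
hysteresis transition detection, and harmonic-ladder recovery of the focused
overtone.  Compares every recovered quantity against the generator's ground
truth and writes the tables under results/.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from khoomei.acoustics import AcousticConstants
from khoomei.analysis import (
    StftParams,
    compute_spectrogram,
    detect_transitions,
    estimate_f0,
    focus_trace,
    pick_harmonics,
)
from khoomei.io import write_trace_csv
from khoomei.simulate import make_designed_area_function, make_song_scenario
from khoomei.synthesis import build_focused_tract, synthesize_dynamic

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

SEED = 4
constants = AcousticConstants()
scn = make_song_scenario("sygyt", f0_hz=150.0, duration=3.0, seed=SEED)
scn.transition_ms = 1.0
truth_focus = [s for s in scn.segments if s.state == "focused"][0].focus_hz
truth_t = scn.transition_times()[0]

af0 = make_designed_area_function()
af_foc = build_focused_tract(af0, truth_focus, const=constants)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    clip = synthesize_dynamic(scn, af0, af_foc, constants)

spec = compute_spectrogram(clip, StftParams(window_samples=4096, overlap=0.95))
trace = focus_trace(spec)
write_trace_csv(trace.times, trace.eR, RESULTS / "04_eR_trace.csv")

pre = float(np.nanmedian(trace.eR[(trace.times > 0.3) & (trace.times < truth_t - 0.2)]))
post = float(np.nanmedian(trace.eR[(trace.times > truth_t + 0.2) & (trace.times < 2.9)]))
entries, exits = detect_transitions(trace, threshold=0.10, hysteresis=0.03, min_hold=0.1)

i = int(np.searchsorted(spec.times, truth_t + 0.5))
frame = spec.frame(i)
f0_est = estimate_f0(spec.freqs, frame)
hf, hl = pick_harmonics(spec.freqs, frame, f0_est, 20)
band = (hf >= 1000.0) & (hf <= 2100.0)
k_best = int(np.nanargmax(np.where(band, hl, -np.inf)))
recovered_focus = float(hf[k_best])

report = pd.DataFrame([
    {"quantity": "f0_hz", "truth": scn.f0_hz, "recovered": round(f0_est, 1)},
    {"quantity": "transition_s", "truth": round(truth_t, 4),
     "recovered": round(entries[0], 4) if entries else np.nan},
    {"quantity": "focus_hz", "truth": truth_focus, "recovered": round(recovered_focus, 1)},
    {"quantity": "median_eR_normal", "truth": np.nan, "recovered": round(pre, 3)},
    {"quantity": "median_eR_focused", "truth": np.nan, "recovered": round(post, 3)},
])
report.to_csv(RESULTS / "04_recovery_report.csv", index=False)
print(report.to_string(index=False))
print(f"eR contrast focused/normal = {post / pre:.1f}x; "
      f"{len(entries)} transition entr{'y' if len(entries) == 1 else 'ies'} detected "
      f"(threshold 0.10 matched to the synthetic generator's contrast).")
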