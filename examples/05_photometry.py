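"""Acetylcholine photometry at slow (state) and fast (event) timescales.

Fits the 405 nm isosbestic reference to the 470 nm sensor channel to
cancel motion/hemodynamic artifacts, Z-scores DF/F over the -60 s..+90 s
analysis window, reports the per-epoch seizure-related ACh change, and
quantifies fast post-stimulus transients (P1: 0-250 ms cue-related;
P2: 750-1500 ms lick-related) for baseline hit trials.
"""

import numpy as np

from ictal import SimConfig, generate_session, photometry as ph

session, truth = generate_session(SimConfig(seed=21, signals=("photo",)))
win = ph.analysis_window(truth.epochs)
ct = ph.isosbestic_correct(session.signals["photo_470"], session.signals["photo_405"], win)
print(f"isosbestic fit: 470 ~ {ct.fit_slope:.3f} * 405 + {ct.fit_intercept:.2f}")

z = ph.zscore_recording(ct.dff)
state = ph.seizure_related_change(z, ct.times_s, truth.epochs)
for period, change in state.period_change.items():
    print(f"{period:16s} seizure-related ACh change {change:+.3f}")

dff = ct.as_signal()
hits = truth.sounds[(truth.sounds.period == "baseline") & truth.sounds.hit]
events = [ph.event_related_change(dff, float(t)) for t in hits["time_s"]]
events = [e for e in events if e is not None]
table = ph.phase_contrast({"baseline-hit": events})
print(table.to_string(index=False))
print("P1/P2 means are in pre-stimulus Z units; negative state change = less ACh.")
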