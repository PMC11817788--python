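"""Generate a synthetic seizure session and inspect its ground truth.

Builds one seeded session (LFP, MUA, photometry, wheel, sounds, licks),
writes it to a bundle directory, and prints the per-period sound/hit
counts the generator injected.
"""

from ictal import SimConfig, generate_session, truth_report
from ictal.simulate import write_bundle

cfg = SimConfig(seed=7)
session, truth = generate_session(cfg)

print(f"session {session.session_id}: {len(session.signals)} signals, "
      f"{len(session.events['sound'])} sounds, {len(session.events['lick'])} licks")
print("epochs:")
for name, (a, b) in truth.epochs.items():
    print(f"  {name:16s} [{a:7.1f}, {b:7.1f}) s")

# counts per period; delta_gain is the injected 1-4 Hz amplitude multiplier
print(truth_report(truth).to_string(index=False))

write_bundle(session, truth, "scratch/example_bundle")
print("bundle written to scratch/example_bundle/ (meta.json, CSVs, truth.json)")
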