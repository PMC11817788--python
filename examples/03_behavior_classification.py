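"""Hit/miss classification, seizure typing, and wheel speed.

Applies the behavioral rules (4 s sound separation, 1 s hit window, 3 s
no-lick horizon) to a generated session, then summarizes lick metrics and
locomotion per epoch.  A seizure is 'spared' when every analyzable ictal
sound is a hit, 'impaired' when every one is a miss, 'mixed' otherwise.
"""

from ictal import SimConfig, analyze_session, generate_session

session, truth = generate_session(SimConfig(seed=12, signals=("ofc_lfp", "wheel")))
res = analyze_session(session, event_spectra=False)

print(res.responses[["sound_time_s", "epoch", "analyzable", "label", "delay_s"]]
      .to_string(index=False))
print(f"\nseizure class: {res.seizure_class}")
s = res.behavior_summary
for period in ("baseline", "ictal"):
    print(f"{period}: max lick rate {s.get(f'max_lick_rate_{period}', float('nan')):.1f} licks/s, "
          f"mean first-lick delay {s.get(f'mean_delay_{period}')} s, "
          f"wheel {s.get(f'wheel_speed_{period}', float('nan')):.1f} cm/s")
print(f"running-eligible (baseline >= 10 cm/s): {s['running_eligible']}")
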