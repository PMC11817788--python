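# ictal

Quantification pipeline for awake, head-fixed mouse focal-seizure
experiments: recordings in which a brief electrical stimulus to the dorsal
hippocampus (HC) triggers a focal limbic seizure while the animal performs
an auditory lick-detection task on a running wheel, with orbitofrontal
cortex (OFC) LFP, multiunit activity (MUA), and GRAB-ACh fiber photometry
recorded alongside.

The package is aimed at systems-neuroscience analysts who have such
sessions (or want to prototype against realistic synthetic ones) and need
the full analysis chain as reusable, tested functions rather than one-off
scripts.

## What it computes

Every analysis is organized around four epochs derived from the seizure
annotation: **baseline** = 60 s before stimulation onset, **ictal** =
stimulation offset to the latest per-channel seizure end (seizures under
5 s are excluded), **early postictal** = 30 s, **late postictal** = 60 s.

- **Spectral** (`ictal.spectral`) — DC removal (0.1 s time constant),
  post-stimulation polynomial artifact subtraction, short-time Hann
  periodogram (1000 ms windows, 1 Hz resolution) giving PSD in µV²/Hz.
  Normalized power at frequency *f* and time *t* is
  `P(f,t) / mean_baseline P(f)`; band/period summaries average that ratio
  over δ = 1–4 Hz or β = 15–30 Hz and over period windows, then report
  `10·log10(·)` dB/Hz. Event-aligned ±2 s spectra support hit-vs-miss
  contrasts.
- **Behavior** (`ictal.behavior`) — *hit* = first lick ≤ 1 s after a
  sound, *miss* = later or no first lick (3 s horizon); sounds closer than
  4 s drop the earlier one; seizures are *spared* (all ictal hits),
  *impaired* (all misses), or *mixed*. Peri-stimulus lick rate in 0.1 s
  bins, peak rate in −0.1…1.05 s, first-lick delays, and wheel speed with
  the ≥ 10 cm/s baseline running filter.
- **MUA** (`ictal.mua`) — V_RMS = √mean(x²) of the >400 Hz signal in
  overlapping 1 s bins as a firing surrogate; percent change
  `(V_RMS − mean_baseline)/mean_baseline × 100` with stimulation bins
  (−2 s…+1 s) removed; up/down-state analysis correlating the 0.05 s-bin
  MUA envelope with processed OFC vs HC LFP (Pearson r).
- **Photometry** (`ictal.photometry`) — isosbestic correction
  (OLS fit `F470 ≈ a·F405 + b`, `ΔF/F = (F470 − fit)/fit`), Z-score over
  the −60 s…+90 s analysis window, seizure-related ACh change
  `(Z − mean_baseline Z)/mean_baseline Z`, and event-related transients
  re-baselined per trial with Pre-Aud (−1–0 s), P1 (0–250 ms) and
  P2 (750–1500 ms) phase means.
- **Statistics** (`ictal.stats`, `ictal.pipeline`) — one-way ANOVA across
  periods with Bonferroni-corrected baseline-vs-period t contrasts
  (family size 3), Mann-Whitney U (exact for small tie-free samples) for
  hit-vs-miss, spared-vs-impaired and phase contrasts, and a cohort
  orchestrator emitting tidy tables.
- **Synthetic sessions** (`ictal.simulate`) — a seeded generator producing
  full sessions with ground truth: 9–12 Hz HC spike-and-wave discharges,
  OFC slow waves with per-period delta gains, up/down-gated MUA,
  state-dependent lick behavior, wheel slowing, and a photometry pair with
  a shared motion artifact, a slow ictal ACh drop, and fast P1/P2
  transients. Identical configs give byte-identical bundles.

## Worked example

`examples/` holds one short script per capability. For instance,
`python examples/02_spectral_analysis.py` generates a session with the
default ictal delta gain, removes the stimulation artifact, and prints:

```
delta (1-4 Hz):
  baseline          -0.00 dB/Hz  (119 windows)
  ictal             +5.01 dB/Hz  (26 windows)
  early_postictal   +5.02 dB/Hz  (58 windows)
  late_postictal    +1.92 dB/Hz  (118 windows)
beta (15-30 Hz):
  baseline          +0.00 dB/Hz  (119 windows)
  ictal             -0.30 dB/Hz  (26 windows)
  ...
```

Baseline self-normalizes to 0 dB; the ictal/early/late delta rises read
out the injected slow-wave amplitude gains (the default ictal gain of
1.95 corresponds to 20·log10(1.95) ≈ +5.8 dB of delta power), while the
unprogrammed beta band stays near 0 dB. The other examples cover
behavioral classification, V_RMS percent change and up/down correlations,
photometry state and event analysis, and a cohort-level spared-vs-impaired
report.

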