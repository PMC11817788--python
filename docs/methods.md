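# Methods

This note records the models, conventions, and design choices behind the
package, in the spirit of a methods appendix: enough detail that a reader
can tell exactly what each number means and what the synthetic benchmark
does and does not establish.

## Time, epochs, and sample selection

All times are seconds on a single session clock starting at recording
onset. Every interval is half-open `[start, end)` and sample membership is
by sample time, so slices over a partition reconstruct a signal exactly and
no boundary sample is counted twice.

Epochs derive from the stimulation annotation: baseline `[stim_on − 60,
stim_on)`, ictal `[stim_off, max(end_ipsi, end_contra))`, early postictal
30 s, late postictal 60 s. The ictal period starts at stimulation *offset*
because the 2 s train itself is artifact; the alternative (onset) is a
documented open choice and would shift all ictal summaries by the masked
stimulation window only. Seizures under 5 s are excluded
(`ExcludedSeizure`). Sham stimulations substitute a matched sham duration
for the ictal interval and flow through the same code path.

NaN/Inf samples are rejected at construction and load: several downstream
formulas divide by means, and silent NaN propagation would be worse than a
hard error. Missing data must be represented as shorter signals with an
explicit `t0_s`.

## Spectral conventions

- Spectrogram: Hann-tapered short-time periodogram, 1000 ms windows, 1 Hz
  frequency spacing, 50% overlap (overlap is configurable; it reduces
  variance without changing expectations). Density scaling: summing
  `PSD·Δf` over frequencies recovers the windowed variance, and a unit
  sinusoid carries total power 1/2.
- Normalization: per frequency, divide by the mean baseline PSD. Summaries
  average the **pre-log ratio** over band frequencies and period windows
  and only then apply `10·log10` (log of the mean). Averaging per-window
  dB instead is exposed as a flag but off by default; the two differ by
  Jensen's inequality and must not be mixed.
- Period membership requires **full window containment**, so windows
  straddling an epoch boundary contribute to neither side; windows
  intersecting the stimulation train are masked everywhere. The ictal
  period is truncated to its first 15 s for spectral summaries (seizure
  durations vary); V_RMS and photometry period statistics use the full
  ictal period, with the 15 s cutoff only for plotted timecourses.
- "DC removal filter (τ)" and "smoothing filter (τ)" are single-pole
  exponential filters (high-pass as input minus its exponential moving
  average), matching the time-constant semantics of common acquisition
  software. The first 5τ after onset is warm-up.
- The post-stimulation artifact on the cortical LFP is fit with an
  order-3 polynomial over the 10 s after stimulation offset and
  subtracted in that window only. A 1.5 Hz sinusoid loses at most a few
  percent RMS to the cubic basis over a 10 s window (verified numerically
  in the tests).

## Behavioral conventions

- First lick strictly after the sound; delay ≤ 1.0 s (closed bound) is a
  hit. The closed bound is measure-zero in practice and fixed for
  determinism.
- Delay beyond 3 s counts as "no lick" (delay = none). The mean delay
  excludes no-lick trials by default; censoring them at 3 s is available
  as a flag.
- Sounds closer than 4 s drop the **earlier** sound; the last sound is
  always analyzable by this rule.
- Peak lick rate is taken on the averaged per-period timecourse over bins
  whose centers lie in −0.1…1.05 s (per-event mode available).
- A sound's epoch assignment uses its onset time only.
- Wheel angle is unwrapped with a 360° period; speed is smoothed with a
  0.5 s exponential average (unstated upstream; chosen to suppress encoder
  quantization; configurable).

## MUA conventions

- A software 4th-order, zero-phase 400 Hz Butterworth high-pass stands in
  for the acquisition hardware filter, since the generator emits broadband
  MUA.
- V_RMS bins are 1 s with a 0.5 s step ("overlapping" with unstated
  overlap upstream; the step is configurable and reported).
- The up/down analysis follows the fixed chain: V_RMS in 0.05 s bins
  (0.025 s step) → DC removal (0.5 s) → linear interpolation to 1000 Hz;
  LFPs: exponential smoothing (0.05 s) → DC removal (0.5 s); Pearson r
  within the ictal interval.

## Photometry conventions

- The isosbestic regression is fit on the −60 s…+90 s analysis window (not
  the whole recording; the window is what downstream statistics consume).
  ΔF/F divides by the **scaled** reference `a·F405 + b` (dividing by the
  raw reference is a flag); any component affine in the reference —
  including a shared motion artifact — cancels exactly.
- Z-scores use the sample SD (n−1) everywhere.
- The seizure-related change `(Z − m_b)/m_b` divides by the mean baseline
  Z, which is legitimately near zero when nothing changes in the window;
  sessions with `|m_b| < 0.05` are flagged and excluded from that metric
  (their per-period mean Z is still reported). The formula is kept as
  stated rather than silently stabilized. A consequence is that the
  *ratio* metric is undefined on effect-free sessions, so the type-I
  calibration test exercises the photometry family through the per-period
  mean Z one step earlier in the chain.
- Event analysis: line fit on the 2 s pre-stimulus segment, subtracted
  from the whole 4 s; Z against the re-baselined pre-stimulus mean and SD;
  Pre-Aud `[−1, 0)` half-open, P1 `[0, 0.25]` and P2 `[0.75, 1.5]` closed.
  Because the pre-aud window lies inside the fitted segment, its variance
  is much smaller than the extrapolated P1/P2 windows'; the Mann-Whitney
  phase contrasts therefore run slightly above nominal α on null data
  (measured ≈ 7% per 100-event pool), which the acceptance test
  accommodates by judging null contrasts on a majority of disjoint pools.
- Photometry stays at its native 1200 Hz; no resampling to the LFP rate.

## Statistics

Period contrasts: one-way ANOVA across the four periods treating seizures
as independent samples (matching per-seizure n; a repeated-measures option
is out of scope), followed by baseline-vs-each-period t tests with p
multiplied by the family size 3 and capped at 1. Two-group contrasts use
Mann-Whitney U: exact enumeration when min(n) ≤ 8 without ties, otherwise
the normal approximation with tie and continuity corrections. α = 0.05.
Mixed seizures contribute their events to event-level contrasts but are
excluded from spared-vs-impaired seizure-level contrasts. The sample unit
is the seizure for period/type contrasts and the sound event for hit/miss
and phase contrasts.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
biophysics. Where the study conditions are printed they are the defaults:
stimulus train 2 s; seizure durations 8.5 s (ipsi) and 13.9 s (contra);
HC discharge rate 10.5 Hz within the 9–12 Hz band; sounds every 10–15 s at
baseline and 3–7 s during the seizure/sham period; lick bouts at 10 Hz
(peak rates ≈ 10.8 licks/s); first-lick latency means 0.17 / 0.65 / 0.34 /
0.35 s per state; baseline hit probability 1.0; wheel speeds 18.26
(baseline) and 14.10 (ictal) cm/s; per-period OFC delta amplitude gains
1.95 / 1.75 / 1.29 (ictal/early/late, i.e. +5.8 / +4.9 / +2.2 dB of
power), with spared-type (1.49 / 1.44 / 1.19) and impaired-type
(2.35 / 2.03 / 1.41) profiles for cohort mixtures. Session length defaults
to 180 s with stimulation at 65 s — one seizure per session, as acquired.

Free parameters the study does not print, chosen once as realistic and
documented here: LFP background is 1/f-shaped noise with 50 µV SD; the
slow wave is a fixed 1.5 Hz sinusoid of 30 µV embedded in the delta band
(the per-period gain multiplies the *entire* 1–4 Hz component, making the
programmed power ratio exact in expectation); HC discharges are
spike-and-wave kernels (400 µV) with 15% interval jitter plus an 8×
ictal delta gain so hippocampal band power rises broadly as observed in
recordings; MUA is white noise whose SD scales as √rate (shot-noise
scaling) with up/down rates 50/15 Hz gated by the slow-wave half-cycles
during the seizure (giving ≈ −19% ictal V_RMS; note the half-cycle gate
bounds the achievable drop at 1 − √½ ≈ 29.3% when down states are fully
silent); photometry uses F405 ≈ 100 a.u., F470 = 2·F405 + 20, 1% ΔF/F per
latent ACh unit, a slow ictal drop of 2 Z-units (1 spared / 3 impaired)
recovering with τ = 45 s, causal smoothed-boxcar P1/P2 transients (P2
injected only when a lick bout occurs), a low-pass motion artifact of 1
a.u. entering both channels through the affine map, and 1.5 a.u. white
sensor noise per channel. The sensor-noise floor matters: in the
noise-free limit the Z-normalized state metric is scale-invariant and
spared/impaired drops would be indistinguishable, exactly as a noiseless
ratio of z-scores must be.

Generator hygiene: one RNG per named block (OFC, each HC channel, MUA,
behavior, wheel, photometry) spawned from the session seed, so excluding
or re-parameterizing one block never perturbs another's draws; spontaneous
licks are suppressed for 3 s after each sound and bouts truncate at the
next sound so the emitted lick train reproduces the drawn hit/miss labels
exactly; sham sessions carry no seizure physiology.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: electrode drift and line noise, real
spike waveforms or refractoriness, bleaching and hemodynamic nonlinearity
beyond the affine reference model, seizure-morphology variability,
satiation dynamics, or any animal-to-animal heterogeneity beyond the
seizure-type profiles. Results on synthetic cohorts validate the
*computations*, not biological effect sizes.

## Problem sizes

The shipped tests and the acceptance script run on deliberately modest
problem sizes chosen to exercise each property with comfortable
statistical margins: 180 s sessions, 20-seed spectral recovery, 100-run
correlation ordering, 50 cohorts of 40 sessions for type recovery, 200
8-session null cohorts for type-I calibration, and 100-event pools for
phase contrasts. Each generated session carries only the signal blocks the
check consumes.

## Known limitations

- The epoch model assumes one seizure per session with a clean 60 s
  baseline; sessions with earlier events in the baseline error out rather
  than silently shortening it.
- The exact Mann-Whitney path requires tie-free data; heavily quantized
  metrics fall back to the corrected normal approximation.
- `remove_stim_artifact` also removes the projection of genuine signal
  onto the polynomial basis inside its 10 s window (bounded, see tests),
  so summaries of that window slightly underestimate low-frequency power.
- The HDF5 bundle mirror is not implemented; the CSV + JSON bundle is the
  interchange format and is byte-stable under load/write round trips.
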