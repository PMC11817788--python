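"""Seeded synthetic seizure sessions with ground truth.

The generator emits sessions with the statistical structure the analysis
assumes: 9-12 Hz hippocampal ictal spike trains, a cortical 1-4 Hz slow
wave whose amplitude is multiplied per period by configurable delta gains,
MUA white noise whose envelope is gated by the slow-wave up/down phase
during the seizure, state-dependent lick responses to sounds (10-15 s
apart at baseline, 3-7 s during the seizure), wheel motion with ictal
slowing, and a photometry pair in which the 470 nm channel is affine in
the 405 nm reference (shared motion artifact) plus a DF/F-scaled latent
ACh trajectory with a slow ictal drop and fast post-stimulus P1/P2
transients.

Defaults mirror the study conditions where printed (seizure durations,
sound intervals, lick rates and latencies, wheel speeds, per-period delta
gains); amplitudes the study does not print are free parameters documented
in the methods note.  Identical configs (including the seed) produce
byte-identical bundles; each signal family draws from its own named
substream so changing one block's parameters does not perturb the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erf

from ._filters import ema_lowpass
from .session import (
    ContinuousSignal,
    EpochSet,
    EventSeries,
    SeizureAnnotation,
    Session,
    ValidationError,
    derive_epochs,
    write_session,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_session",
    "generate_cohort",
    "truth_report",
    "write_bundle",
    "load_truth",
    "SPARED_PROFILE",
    "IMPAIRED_PROFILE",
]

ALL_SIGNALS = ("hc_ipsi", "hc_contra", "ofc_lfp", "mua", "photo", "wheel")

# Seizure-type profiles: amplitude gains back-computed from the printed
# per-period delta power changes (dB = 20*log10(gain)); hit probabilities
# degenerate so the drawn type equals the classified type.
SPARED_PROFILE: dict = {
    "p_hit_ictal": 1.0,
    "ofc_delta_gain_ictal": 1.49,
    "ofc_delta_gain_early": 1.44,
    "ofc_delta_gain_late": 1.19,
    "ach_state_drop": 1.0,
}
IMPAIRED_PROFILE: dict = {
    "p_hit_ictal": 0.0,
    "ofc_delta_gain_ictal": 2.35,
    "ofc_delta_gain_early": 2.03,
    "ofc_delta_gain_late": 1.41,
    "ach_state_drop": 3.0,
}


def _default_latency() -> dict[str, float]:
    # Mean first-lick latency per state, seconds.
    return {
        "baseline": 0.17,
        "ictal": 0.65,
        "early_postictal": 0.34,
        "late_postictal": 0.35,
        "other": 0.17,
    }


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; all times in seconds on the session clock."""

    seed: int = 0
    duration_s: float = 180.0
    stim_on_s: float = 65.0
    stim_duration_s: float = 2.0
    seizure_duration_ipsi_s: float = 8.5
    seizure_duration_contra_s: float = 13.9
    is_sham: bool = False
    sham_duration_s: float | None = None
    signals: tuple[str, ...] = ALL_SIGNALS

    # LFP block (uV, 1 kHz)
    lfp_rate_hz: float = 1000.0
    lfp_noise_sd_uv: float = 50.0
    hc_spike_rate_hz: float = 10.5
    hc_spike_amp_uv: float = 400.0
    hc_ictal_delta_gain: float = 8.0
    slow_wave_freq_hz: float = 1.5
    slow_wave_amp_uv: float = 30.0
    ofc_delta_gain_ictal: float = 1.95
    ofc_delta_gain_early: float = 1.75
    ofc_delta_gain_late: float = 1.29
    stim_artifact_amp_uv: float = 2000.0
    stim_tail_amp_uv: float = 300.0

    # MUA block (uV, 20 kHz); envelope SD scales with sqrt(rate)
    mua_sample_rate_hz: float = 20000.0
    mua_noise_sd_uv: float = 10.0
    mua_rate_up_hz: float = 50.0
    mua_rate_down_hz: float = 15.0

    # Behavior block
    sound_interval_baseline_s: tuple[float, float] = (10.0, 15.0)
    sound_interval_ictal_s: tuple[float, float] = (3.0, 7.0)
    p_hit_baseline: float = 1.0
    p_hit_ictal: float = 0.55
    first_lick_latency_mean_s: dict = field(default_factory=_default_latency)
    lick_bout_rate_hz: float = 10.0
    lick_bout_duration_s: float = 1.0
    lick_bout_keep_prob: float = 0.9
    p_late_lick_on_miss: float = 0.5
    spont_lick_rate_ictal_hz: float = 0.4
    spont_lick_rate_other_hz: float = 1.2

    # Wheel block (degrees, 1 kHz)
    wheel_rate_hz: float = 1000.0
    wheel_speed_baseline_cm_s: float = 18.26
    wheel_speed_ictal_cm_s: float = 14.10
    wheel_speed_noise_cm_s: float = 1.0
    wheel_circumference_cm: float = 50.0

    # Photometry block (a.u., 1.2 kHz post-decimation)
    photo_rate_hz: float = 1200.0
    f405_mean: float = 100.0
    photo_slope: float = 2.0
    photo_intercept: float = 20.0
    ach_state_drop: float = 2.0
    ach_recovery_tau_s: float = 45.0
    ach_p1_amp: float = 0.3
    ach_p2_amp: float = 0.5
    ach_dff_per_unit: float = 0.01
    motion_artifact_sd: float = 1.0
    motion_artifact_tau_s: float = 0.2
    noise_sd_405: float = 1.5
    noise_sd_470: float = 1.5

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed must be an integer")
        if self.duration_s <= 0 or self.stim_duration_s <= 0:
            raise ValidationError("durations must be > 0")
        if self.stim_on_s < 60.0:
            raise ValidationError("stim_on_s must leave a clean 60 s baseline")
        if not 9.0 <= self.hc_spike_rate_hz <= 12.0:
            raise ValidationError("hc_spike_rate_hz must lie in [9, 12] Hz")
        for p in (self.p_hit_baseline, self.p_hit_ictal, self.lick_bout_keep_prob,
                  self.p_late_lick_on_miss):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        if self.is_sham and self.sham_duration_s is None:
            raise ValidationError("sham config requires sham_duration_s")
        for name in self.signals:
            if name not in ALL_SIGNALS:
                raise ValidationError(f"unknown signal {name!r}")
        if self.annotation().stim_off_s >= self.duration_s:
            raise ValidationError("stimulation extends past the session")

    def annotation(self) -> SeizureAnnotation:
        stim_off = self.stim_on_s + self.stim_duration_s
        if self.is_sham:
            return SeizureAnnotation(
                stim_on_s=self.stim_on_s, stim_off_s=stim_off,
                is_sham=True, sham_duration_s=self.sham_duration_s,
            )
        return SeizureAnnotation(
            stim_on_s=self.stim_on_s,
            stim_off_s=stim_off,
            end_ipsi_s=stim_off + self.seizure_duration_ipsi_s,
            end_contra_s=stim_off + self.seizure_duration_contra_s,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["signals"] = list(self.signals)
        d["sound_interval_baseline_s"] = list(self.sound_interval_baseline_s)
        d["sound_interval_ictal_s"] = list(self.sound_interval_ictal_s)
        return d


@dataclass
class GroundTruth:
    """What the generator actually injected, for parameter-recovery oracles."""

    epochs: EpochSet
    sounds: pd.DataFrame  # time_s, period, hit, first_lick_delay_s, p1_amp, p2_amp
    delta_gain: dict[str, float]
    ach: dict
    mua_gate: dict
    spontaneous_lick_times: np.ndarray

    def to_dict(self) -> dict:
        return {
            "epochs": {name: list(iv) for name, iv in self.epochs.items()},
            "sounds": self.sounds.to_dict(orient="list"),
            "delta_gain": self.delta_gain,
            "ach": self.ach,
            "mua_gate": self.mua_gate,
            "spontaneous_lick_times": list(map(float, self.spontaneous_lick_times)),
        }


def _pinkish_split(
    rng: np.random.Generator, n: int, rate: float, sd: float,
    split_band: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Background LFP noise with a 1/f power envelope above 1 Hz.

    When ``split_band`` is given, returns ``(in_band, out_of_band)``
    components whose sum is the full noise, so a per-period gain can scale
    the in-band part alone.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    shape = 1.0 / np.sqrt(np.maximum(f, 1.0))
    spec = spec * shape
    if split_band is None:
        x = np.fft.irfft(spec, n)
        x *= sd / x.std()
        return x, None
    lo, hi = split_band
    mask = (f >= lo) & (f < hi)
    in_band = np.fft.irfft(spec * mask, n)
    out_band = np.fft.irfft(spec * ~mask, n)
    scale = sd / np.sqrt(in_band.var() + out_band.var())
    return in_band * scale, out_band * scale


def _spike_train(
    t0: float, n: int, rate: float, start: float, end: float,
    spike_rate: float, amp: float, rng: np.random.Generator,
    jitter_frac: float = 0.15,
) -> np.ndarray:
    """Spike-and-wave discharge train between start and end.

    Each event is a sharp Mexican-hat spike followed by a slower negative
    wave; inter-event intervals are jittered around 1/spike_rate so the
    discharge carries broadband power (including the delta band) as ictal
    discharges do, rather than a pure harmonic comb.
    """
    out = np.zeros(n)
    sigma = 0.008
    kt = np.arange(-0.04, 0.16, 1.0 / rate)
    spike = (1.0 - (kt / sigma) ** 2) * np.exp(-(kt**2) / (2 * sigma**2))
    wave = -0.5 * np.exp(-((kt - 0.06) ** 2) / (2 * 0.035**2))
    kernel = amp * (spike + wave)
    ts = start
    while ts < end:
        i = int(round((ts - t0) * rate)) - int(round(0.04 * rate))
        a, b = max(i, 0), min(i + kernel.size, n)
        if a < b:
            out[a:b] += kernel[a - i : b - i]
        ts += (1.0 / spike_rate) * max(0.3, 1.0 + jitter_frac * rng.standard_normal())
    return out


def _smooth_box(t: np.ndarray, lo: float, hi: float, sigma: float = 0.02) -> np.ndarray:
    """Boxcar on [lo, hi] convolved with a Gaussian of width sigma (unit height)."""
    return 0.5 * (erf((t - lo) / (np.sqrt(2) * sigma)) - erf((t - hi) / (np.sqrt(2) * sigma)))


def _event_kernel(t_rel: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Causal smoothed-boxcar transient: identically zero before the stimulus.

    Evoked release cannot precede its cue; truncating the smoothed edge also
    keeps the pre-stimulus re-baselining window free of kernel leakage.
    """
    k = _smooth_box(t_rel, lo, hi)
    k[t_rel < 0] = 0.0
    return k


def _truncated_exp(rng: np.random.Generator, mean: float, cap: float) -> float:
    u = rng.random()
    return float(-mean * np.log1p(-u * (1.0 - np.exp(-cap / mean))))


def generate_session(config: SimConfig) -> tuple[Session, GroundTruth]:
    """Generate one session plus its ground truth.  Deterministic in config."""
    cfg = config
    annotation = cfg.annotation()
    epochs = derive_epochs(annotation)
    stim_on, stim_off = annotation.stim_on_s, annotation.stim_off_s
    ictal_start, ictal_end = epochs.ictal
    seizing = not cfg.is_sham

    streams = np.random.SeedSequence(cfg.seed).spawn(7)
    (rng_lfp, rng_hc_ipsi, rng_hc_contra, rng_mua, rng_beh, rng_wheel, rng_photo) = map(
        np.random.default_rng, streams
    )
    rng_hc = {"hc_ipsi": rng_hc_ipsi, "hc_contra": rng_hc_contra}

    signals: dict[str, ContinuousSignal] = {}

    # --- behavior: sounds, truth labels, licks --------------------------------
    sounds: list[float] = []
    t = float(rng_beh.uniform(1.0, 4.0))
    while t < cfg.duration_s - 2.5:
        sounds.append(t)
        fast = stim_on <= t < ictal_end
        lo, hi = cfg.sound_interval_ictal_s if fast else cfg.sound_interval_baseline_s
        t += float(rng_beh.uniform(lo, hi))
    sounds_arr = np.array(sounds)

    truth_rows = []
    bout_licks: list[float] = []
    for i, s in enumerate(sounds):
        next_s = sounds[i + 1] if i + 1 < len(sounds) else cfg.duration_s
        period = epochs.label_for(s)
        p_hit = cfg.p_hit_ictal if period == "ictal" else cfg.p_hit_baseline
        hit = bool(rng_beh.random() < p_hit)
        delay: float | None = None
        licks_this = np.empty(0)
        if hit:
            mean_lat = cfg.first_lick_latency_mean_s.get(period, 0.2)
            delay = _truncated_exp(rng_beh, mean_lat, cap=1.0)
            delay = min(max(delay, 1e-3), 1.0)
            bout = s + delay + np.arange(
                0.0, cfg.lick_bout_duration_s, 1.0 / cfg.lick_bout_rate_hz
            )
            keep = rng_beh.random(bout.size) < cfg.lick_bout_keep_prob
            keep[0] = True  # the first lick defines the hit
            licks_this = bout[keep]
        elif rng_beh.random() < cfg.p_late_lick_on_miss:
            late = s + float(rng_beh.uniform(1.0 + 1e-3, 3.0))
            bout = late + np.arange(0.0, cfg.lick_bout_duration_s, 1.0 / cfg.lick_bout_rate_hz)
            keep = rng_beh.random(bout.size) < cfg.lick_bout_keep_prob
            keep[0] = True
            licks_this = bout[keep]
            if licks_this.size and licks_this[0] < next_s:
                delay = float(licks_this[0] - s)
        # licking stops when the next trial starts
        licks_this = licks_this[licks_this < next_s - 1e-6]
        if licks_this.size == 0 and not hit:
            delay = None
        bout_licks.extend(licks_this.tolist())
        truth_rows.append(
            {
                "time_s": s,
                "period": period,
                "hit": hit,
                "first_lick_delay_s": delay,
                "p1_amp": cfg.ach_p1_amp,
                "p2_amp": cfg.ach_p2_amp if hit else 0.0,
            }
        )

    # spontaneous licks: ictal rate differs; none within 3 s after any sound
    spont: list[float] = []
    regions = [(0.0, ictal_start, cfg.spont_lick_rate_other_hz)]
    regions.append((ictal_start, ictal_end, cfg.spont_lick_rate_ictal_hz))
    regions.append((ictal_end, cfg.duration_s, cfg.spont_lick_rate_other_hz))
    for lo, hi, rate in regions:
        if hi <= lo or rate <= 0:
            continue
        k = rng_beh.poisson(rate * (hi - lo))
        spont.extend(np.sort(rng_beh.uniform(lo, hi, k)).tolist())
    spont_arr = np.array(spont)
    if spont_arr.size and sounds_arr.size:
        idx = np.searchsorted(sounds_arr, spont_arr) - 1
        prev = np.where(idx >= 0, sounds_arr[np.maximum(idx, 0)], -np.inf)
        spont_arr = spont_arr[spont_arr - prev > 3.0]

    licks = np.unique(np.concatenate([np.array(bout_licks), spont_arr]))
    licks = licks[(licks > 0) & (licks < cfg.duration_s)]

    events = {
        "sound": EventSeries(name="sound", times_s=sounds_arr),
        "lick": EventSeries(name="lick", times_s=licks),
    }
    truth_sounds = pd.DataFrame(
        truth_rows,
        columns=["time_s", "period", "hit", "first_lick_delay_s", "p1_amp", "p2_amp"],
    )

    # --- LFP channels ---------------------------------------------------------
    n_lfp = int(round(cfg.duration_s * cfg.lfp_rate_hz))
    t_lfp = np.arange(n_lfp) / cfg.lfp_rate_hz

    gains = {
        "baseline": 1.0,
        "ictal": cfg.ofc_delta_gain_ictal if seizing else 1.0,
        "early_postictal": cfg.ofc_delta_gain_early if seizing else 1.0,
        "late_postictal": cfg.ofc_delta_gain_late if seizing else 1.0,
    }

    if "ofc_lfp" in cfg.signals:
        delta, rest = _pinkish_split(
            rng_lfp, n_lfp, cfg.lfp_rate_hz, cfg.lfp_noise_sd_uv, split_band=(0.5, 4.5)
        )
        g = np.ones(n_lfp)
        for period in ("ictal", "early_postictal", "late_postictal"):
            a, b = epochs[period]
            g[(t_lfp >= a) & (t_lfp < b)] = gains[period]
        slow = cfg.slow_wave_amp_uv * np.sin(2 * np.pi * cfg.slow_wave_freq_hz * t_lfp)
        ofc = rest + g * (delta + slow)
        stim_sel = (t_lfp >= stim_on) & (t_lfp < stim_off)
        ofc[stim_sel] += cfg.stim_artifact_amp_uv * np.sign(
            np.sin(2 * np.pi * 60.0 * (t_lfp[stim_sel] - stim_on))
        )
        tail_sel = (t_lfp >= stim_off) & (t_lfp < stim_off + 10.0)
        u = (t_lfp[tail_sel] - stim_off) / 10.0
        ofc[tail_sel] += cfg.stim_tail_amp_uv * (1.0 - u) ** 3
        signals["ofc_lfp"] = ContinuousSignal(
            name="ofc_lfp", samples=ofc, rate_hz=cfg.lfp_rate_hz, units="uV"
        )

    for chan, dur in (
        ("hc_ipsi", cfg.seizure_duration_ipsi_s),
        ("hc_contra", cfg.seizure_duration_contra_s),
    ):
        if chan not in cfg.signals:
            continue
        delta_hc, rest_hc = _pinkish_split(
            rng_hc[chan], n_lfp, cfg.lfp_rate_hz, cfg.lfp_noise_sd_uv, split_band=(0.5, 4.5)
        )
        g_hc = np.ones(n_lfp)
        if seizing:
            sel = (t_lfp >= stim_off) & (t_lfp < stim_off + dur)
            g_hc[sel] = cfg.hc_ictal_delta_gain
        x = rest_hc + g_hc * delta_hc
        if seizing:
            x = x + _spike_train(
                0.0, n_lfp, cfg.lfp_rate_hz, stim_off, stim_off + dur,
                cfg.hc_spike_rate_hz, cfg.hc_spike_amp_uv, rng_hc[chan],
            )
        signals[chan] = ContinuousSignal(
            name=chan, samples=x, rate_hz=cfg.lfp_rate_hz, units="uV"
        )

    # --- MUA ------------------------------------------------------------------
    if "mua" in cfg.signals:
        n_mua = int(round(cfg.duration_s * cfg.mua_sample_rate_hz))
        t_mua = np.arange(n_mua) / cfg.mua_sample_rate_hz
        rate = np.full(n_mua, cfg.mua_rate_up_hz)
        if seizing:
            in_ictal = (t_mua >= ictal_start) & (t_mua < ictal_end)
            down = in_ictal & (np.sin(2 * np.pi * cfg.slow_wave_freq_hz * t_mua) <= 0)
            rate[down] = cfg.mua_rate_down_hz
        sigma = cfg.mua_noise_sd_uv * np.sqrt(rate / cfg.mua_rate_up_hz)
        mua = rng_mua.standard_normal(n_mua) * sigma
        stim_sel = (t_mua >= stim_on) & (t_mua < stim_off)
        mua[stim_sel] += cfg.stim_artifact_amp_uv * np.sign(
            np.sin(2 * np.pi * 60.0 * (t_mua[stim_sel] - stim_on))
        )
        signals["mua"] = ContinuousSignal(
            name="mua", samples=mua, rate_hz=cfg.mua_sample_rate_hz, units="uV"
        )

    # --- wheel ----------------------------------------------------------------
    if "wheel" in cfg.signals:
        n_w = int(round(cfg.duration_s * cfg.wheel_rate_hz))
        t_w = np.arange(n_w) / cfg.wheel_rate_hz
        speed = np.full(n_w, cfg.wheel_speed_baseline_cm_s)
        if seizing:
            sel = (t_w >= ictal_start) & (t_w < ictal_end)
            speed[sel] = cfg.wheel_speed_ictal_cm_s
        if cfg.wheel_speed_noise_cm_s > 0:
            noise = rng_wheel.standard_normal(n_w)
            noise = ema_lowpass(noise, 0.5, cfg.wheel_rate_hz)
            sd = noise.std()
            if sd > 0:
                speed = speed + cfg.wheel_speed_noise_cm_s * noise / sd
        speed = np.clip(speed, 0.0, None)
        theta = np.cumsum(speed) / cfg.wheel_rate_hz / cfg.wheel_circumference_cm * 360.0
        signals["wheel_deg"] = ContinuousSignal(
            name="wheel_deg", samples=np.mod(theta, 360.0),
            rate_hz=cfg.wheel_rate_hz, units="degrees",
        )

    # --- photometry -----------------------------------------------------------
    ach_latent_params = {
        "state_drop": cfg.ach_state_drop if seizing else 0.0,
        "recovery_tau_s": cfg.ach_recovery_tau_s,
        "ictal_interval": [ictal_start, ictal_end],
        "dff_per_unit": cfg.ach_dff_per_unit,
    }
    if "photo" in cfg.signals:
        n_p = int(round(cfg.duration_s * cfg.photo_rate_hz))
        t_p = np.arange(n_p) / cfg.photo_rate_hz
        latent = np.zeros(n_p)
        drop = cfg.ach_state_drop if seizing else 0.0
        if drop != 0.0:
            ramp = (t_p >= ictal_start) & (t_p < ictal_end)
            latent[ramp] = -drop * (t_p[ramp] - ictal_start) / (ictal_end - ictal_start)
            after = t_p >= ictal_end
            latent[after] = -drop * np.exp(-(t_p[after] - ictal_end) / cfg.ach_recovery_tau_s)
        for row in truth_rows:
            s = row["time_s"]
            near = (t_p >= s - 0.2) & (t_p <= s + 2.0)
            tr = t_p[near] - s
            latent[near] += row["p1_amp"] * _event_kernel(tr, 0.0, 0.25)
            if row["p2_amp"]:
                latent[near] += row["p2_amp"] * _event_kernel(tr, 0.75, 1.5)

        artifact = np.zeros(n_p)
        if cfg.motion_artifact_sd > 0:
            artifact = ema_lowpass(
                rng_photo.standard_normal(n_p), cfg.motion_artifact_tau_s, cfg.photo_rate_hz
            )
            artifact *= cfg.motion_artifact_sd / artifact.std()
        n405 = rng_photo.standard_normal(n_p) * cfg.noise_sd_405
        n470 = rng_photo.standard_normal(n_p) * cfg.noise_sd_470
        f405 = cfg.f405_mean + artifact + n405
        fitted_level = cfg.photo_slope * cfg.f405_mean + cfg.photo_intercept
        f470 = (
            cfg.photo_slope * f405
            + cfg.photo_intercept
            + fitted_level * cfg.ach_dff_per_unit * latent
            + n470
        )
        signals["photo_470"] = ContinuousSignal(
            name="photo_470", samples=f470, rate_hz=cfg.photo_rate_hz, units="a.u."
        )
        signals["photo_405"] = ContinuousSignal(
            name="photo_405", samples=f405, rate_hz=cfg.photo_rate_hz, units="a.u."
        )

    session = Session(
        session_id=f"sim-{cfg.seed:08d}",
        signals=signals,
        events=events,
        annotation=annotation,
        meta={
            "animal_id": f"simmouse-{cfg.seed % 97:02d}",
            "wheel_circumference_cm": cfg.wheel_circumference_cm,
            "seed": int(cfg.seed),
            "generator": "ictal.simulate",
        },
    )
    truth = GroundTruth(
        epochs=epochs,
        sounds=truth_sounds,
        delta_gain=gains,
        ach=ach_latent_params,
        mua_gate={
            "rate_up_hz": cfg.mua_rate_up_hz,
            "rate_down_hz": cfg.mua_rate_down_hz if seizing else cfg.mua_rate_up_hz,
            "slow_wave_freq_hz": cfg.slow_wave_freq_hz,
            "gated_interval": [ictal_start, ictal_end] if seizing else None,
        },
        spontaneous_lick_times=spont_arr,
    )
    return session, truth


def generate_cohort(
    config: SimConfig,
    n_sessions: int,
    mixture_weight: float | None = None,
    profiles: tuple[dict, dict] = (SPARED_PROFILE, IMPAIRED_PROFILE),
) -> list[tuple[Session, GroundTruth]]:
    """n sessions seeded ``seed, seed+1, ...``.

    With ``mixture_weight`` set, each session draws a spared-type profile
    with that probability and an impaired-type profile otherwise
    (deterministically from the cohort seed); the profile name is recorded
    in session meta.
    """
    if n_sessions < 1:
        raise ValidationError("n_sessions must be >= 1")
    chooser = np.random.default_rng(np.random.SeedSequence([config.seed, 2**20]))
    out = []
    for i in range(n_sessions):
        overrides: dict = {}
        profile_name = None
        if mixture_weight is not None:
            spared = bool(chooser.random() < mixture_weight)
            overrides = profiles[0] if spared else profiles[1]
            profile_name = "spared" if spared else "impaired"
        cfg_i = replace(config, seed=config.seed + i, **overrides)
        session, truth = generate_session(cfg_i)
        if profile_name is not None:
            session.meta["profile"] = profile_name
        out.append((session, truth))
    return out


def truth_report(truth: GroundTruth) -> pd.DataFrame:
    """Per-period counts of sounds and true hits/misses plus injected gains."""
    periods = ["baseline", "ictal", "early_postictal", "late_postictal", "other"]
    rows = []
    for period in periods:
        sel = truth.sounds[truth.sounds["period"] == period]
        rows.append(
            {
                "period": period,
                "n_sounds": int(len(sel)),
                "n_hits": int(sel["hit"].sum()),
                "n_misses": int((~sel["hit"]).sum()),
                "delta_gain": truth.delta_gain.get(period, 1.0),
            }
        )
    return pd.DataFrame(rows)


def write_bundle(
    session: Session, truth: GroundTruth | None, bundle_path: str | Path
) -> None:
    """Write a session bundle, with the ground truth as truth.json when given."""
    write_session(session, bundle_path)
    if truth is not None:
        with open(Path(bundle_path) / "truth.json", "w", newline="\n") as f:
            json.dump(truth.to_dict(), f, indent=2, sort_keys=True, default=float)
            f.write("\n")


def load_truth(bundle_path: str | Path) -> dict:
    with open(Path(bundle_path) / "truth.json") as f:
        return json.load(f)
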