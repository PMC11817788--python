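"""Multiunit-activity quantification via the V_RMS firing surrogate.

The root-mean-square voltage of the high-pass (>400 Hz) extracellular
signal in overlapping 1 s bins tracks population firing.  Percent change
relative to the baseline-period mean gives the seizure timecourse, with
bins contaminated by the electrical stimulus (-2 s before onset to +1 s
after offset) removed.  A finer 0.05 s-bin envelope, DC-removed and
resampled to the LFP rate, supports the ictal up/down-state correlation
between cortical MUA and cortical versus hippocampal LFP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from ._filters import dc_remove, ema_lowpass, highpass_butter
from .session import (
    ContinuousSignal,
    EpochSet,
    Interval,
    SeizureAnnotation,
    ValidationError,
    slice_signal,
)

__all__ = [
    "VrmsSeries",
    "CorrelationResult",
    "compute_vrms",
    "vrms_percent_change",
    "updown_correlation",
    "mua_highpass",
    "STIM_MASK_PRE_S",
    "STIM_MASK_POST_S",
]

log = logging.getLogger(__name__)

STIM_MASK_PRE_S = 2.0  # bins from stim onset - 2 s ...
STIM_MASK_POST_S = 1.0  # ... to stim offset + 1 s are removed
MUA_HIGHPASS_HZ = 400.0


@dataclass(frozen=True)
class VrmsSeries:
    """Root-mean-square voltage per (overlapping) time bin."""

    times_s: np.ndarray  # bin centers
    vrms: np.ndarray
    bin_width_s: float
    step_s: float

    def __post_init__(self) -> None:
        if self.times_s.shape != self.vrms.shape:
            raise ValidationError("times and vrms must align")


@dataclass(frozen=True)
class CorrelationResult:
    r_mua_ofc: float
    r_mua_hc: float
    n_samples: int


def mua_highpass(mua: ContinuousSignal, cutoff_hz: float = MUA_HIGHPASS_HZ) -> ContinuousSignal:
    """4th-order zero-phase high pass isolating the >400 Hz MUA band."""
    return ContinuousSignal(
        name=mua.name,
        samples=highpass_butter(mua.samples, cutoff_hz, mua.rate_hz),
        rate_hz=mua.rate_hz,
        t0_s=mua.t0_s,
        units=mua.units,
    )


def compute_vrms(
    mua: ContinuousSignal, bin_width_s: float = 1.0, step_s: float = 0.5
) -> VrmsSeries:
    """``sqrt(mean(x^2))`` in consecutive overlapping bins at the native rate."""
    n_bin = int(round(bin_width_s * mua.rate_hz))
    n_step = int(round(step_s * mua.rate_hz))
    if n_bin < 1 or n_step < 1:
        raise ValidationError("bin and step must span at least one sample")
    if mua.n_samples < n_bin:
        raise ValidationError("signal shorter than one V_RMS bin")
    x = mua.samples
    starts = np.arange(0, mua.n_samples - n_bin + 1, n_step)
    vrms = np.empty(starts.size)
    for k, i in enumerate(starts):
        vrms[k] = np.sqrt(np.mean(x[i : i + n_bin] ** 2))
    centers = mua.t0_s + (starts + n_bin / 2.0) / mua.rate_hz
    return VrmsSeries(times_s=centers, vrms=vrms, bin_width_s=bin_width_s, step_s=step_s)


def vrms_percent_change(
    vrms: VrmsSeries,
    epochs: EpochSet,
    annotation: SeizureAnnotation | None = None,
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Percent change of V_RMS from the baseline mean.

    Returns ``(times, pct_change, period_means)`` where masked bins
    (intersecting the stimulation exclusion interval) are NaN in the
    timecourse and excluded from every mean.  Period means use the full
    ictal period; the 15 s ictal cutoff applies only to plotted timecourses.
    """
    half = vrms.bin_width_s / 2.0
    masked = np.zeros(vrms.times_s.size, dtype=bool)
    if annotation is not None:
        a = annotation.stim_on_s - STIM_MASK_PRE_S
        b = annotation.stim_off_s + STIM_MASK_POST_S
        masked = (vrms.times_s + half > a) & (vrms.times_s - half < b)

    def in_period(interval: Interval) -> np.ndarray:
        return (
            (vrms.times_s - half >= interval[0] - 1e-9)
            & (vrms.times_s + half <= interval[1] + 1e-9)
            & ~masked
        )

    base_sel = in_period(epochs.baseline)
    if not base_sel.any():
        raise ValidationError("no usable baseline V_RMS bins")
    m0 = float(vrms.vrms[base_sel].mean())
    if m0 == 0:
        raise ValidationError("baseline mean V_RMS is zero")
    pct = (vrms.vrms - m0) / m0 * 100.0
    pct_masked = pct.copy()
    pct_masked[masked] = np.nan
    period_means = {}
    for period, interval in epochs.items():
        sel = in_period(interval)
        if not sel.any():
            log.info("vrms_percent_change: no bins in %s", period)
            continue
        period_means[period] = float(pct[sel].mean())
    return vrms.times_s, pct_masked, period_means


def _resample_linear(
    times: np.ndarray, values: np.ndarray, rate_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    grid = np.arange(times[0], times[-1], 1.0 / rate_hz)
    return grid, np.interp(grid, times, values)


def updown_correlation(
    mua: ContinuousSignal,
    ofc_lfp: ContinuousSignal,
    hc_lfp: ContinuousSignal,
    interval: Interval,
    envelope_bin_s: float = 0.05,
    envelope_step_s: float = 0.025,
    dc_tau_s: float = 0.5,
    smooth_tau_s: float = 0.05,
    lfp_rate_hz: float = 1000.0,
    apply_mua_highpass: bool = True,
) -> CorrelationResult:
    """Pearson r between the MUA envelope and each processed LFP.

    MUA: (high pass) -> V_RMS in overlapping 0.05 s bins -> DC removal
    (0.5 s time constant) -> linear resample to the LFP rate.  LFPs:
    exponential smoothing (0.05 s) -> DC removal (0.5 s).  All computed
    within the requested (normally ictal) interval.
    """
    if interval[1] - interval[0] < 2.0:
        raise ValidationError("correlation interval must span at least 2 s")
    mua_seg = slice_signal(mua, interval)
    if apply_mua_highpass:
        mua_seg = mua_highpass(mua_seg)
    env = compute_vrms(mua_seg, bin_width_s=envelope_bin_s, step_s=envelope_step_s)
    env_v = dc_remove(env.vrms, dc_tau_s, 1.0 / envelope_step_s)
    grid, env_rs = _resample_linear(env.times_s, env_v, lfp_rate_hz)

    def process_lfp(sig: ContinuousSignal) -> np.ndarray:
        seg = slice_signal(sig, (grid[0], grid[-1] + 1.0 / lfp_rate_hz))
        x = ema_lowpass(seg.samples, smooth_tau_s, seg.rate_hz)
        x = dc_remove(x, dc_tau_s, seg.rate_hz)
        t = seg.t0_s + np.arange(x.size) / seg.rate_hz
        return np.interp(grid, t, x)

    ofc = process_lfp(ofc_lfp)
    hc = process_lfp(hc_lfp)
    r_ofc = float(sstats.pearsonr(env_rs, ofc).statistic)
    r_hc = float(sstats.pearsonr(env_rs, hc).statistic)
    return CorrelationResult(r_mua_ofc=r_ofc, r_mua_hc=r_hc, n_samples=int(grid.size))
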