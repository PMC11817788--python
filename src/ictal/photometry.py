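"""Two-channel (470/405 nm) fiber-photometry ACh analysis.

Slow, state-related analysis: the isosbestic 405 nm reference is scaled to
the 470 nm sensor channel by ordinary least squares, the scaled reference is
subtracted and divided out to give DF/F, DF/F is Z-scored over the analysis
window (60 s before seizure onset to 90 s after seizure offset), and the
"seizure-related change" timecourse divides the Z trace by its baseline
mean.  Fast, event-related analysis: each +/-2 s sound segment of DF/F is
re-baselined with a line fit to the 2 s pre-stimulus part, Z-scored against
the pre-stimulus mean and SD, and summarized by Pre-Aud (-1 to 0 s), P1
(0-250 ms) and P2 (750-1500 ms) phase means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .session import ContinuousSignal, EpochSet, IctalError, Interval, ValidationError, slice_signal

__all__ = [
    "CorrectedTrace",
    "SeizureAChResult",
    "EventAChResult",
    "isosbestic_correct",
    "zscore_recording",
    "seizure_related_change",
    "event_related_change",
    "phase_contrast",
    "BaselineDegenerateError",
    "ANALYSIS_PRE_S",
    "ANALYSIS_POST_S",
    "PHASES",
]

log = logging.getLogger(__name__)

ANALYSIS_PRE_S = 60.0  # analysis window starts 60 s before seizure onset
ANALYSIS_POST_S = 90.0  # ... and extends 90 s past seizure offset
BASELINE_GUARD = 0.05  # |mean baseline Z| below this flags the session
EVENT_HALF_S = 2.0
# Pre-Aud is half-open, P1/P2 closed (deterministic boundary membership).
PHASES: dict[str, tuple[float, float, bool]] = {
    "pre_aud": (-1.0, 0.0, False),
    "p1": (0.0, 0.25, True),
    "p2": (0.75, 1.5, True),
}


class BaselineDegenerateError(IctalError):
    """Mean baseline Z too close to zero for the seizure-related ratio."""


@dataclass(frozen=True)
class CorrectedTrace:
    """Motion-corrected DF/F with the isosbestic regression coefficients."""

    times_s: np.ndarray
    dff: np.ndarray
    fit_slope: float
    fit_intercept: float
    rate_hz: float

    def as_signal(self, name: str = "dff") -> ContinuousSignal:
        return ContinuousSignal(
            name=name, samples=self.dff, rate_hz=self.rate_hz,
            t0_s=float(self.times_s[0]), units="dF/F",
        )


@dataclass(frozen=True)
class SeizureAChResult:
    times_s: np.ndarray
    z_dff: np.ndarray
    change: np.ndarray  # (z - mean baseline z) / mean baseline z
    baseline_mean_z: float
    period_change: dict[str, float]
    period_mean_z: dict[str, float]
    flagged: bool


@dataclass(frozen=True)
class EventAChResult:
    sound_time_s: float
    times_rel_s: np.ndarray
    z_event: np.ndarray
    phase_means: dict[str, float]


def isosbestic_correct(
    f470: ContinuousSignal,
    f405: ContinuousSignal,
    window: Interval,
    divide_by: str = "scaled",
) -> CorrectedTrace:
    """Regress the 405 nm reference onto the 470 nm channel and form DF/F.

    ``f470 ~ a*f405 + b`` by OLS on the window; DF/F = (f470 - scaled) /
    scaled with ``scaled = a*f405 + b``.  Any fluorescence component affine
    in the reference (shared motion or hemodynamic artifact) cancels
    exactly.  ``divide_by="raw"`` divides by the raw reference instead.
    """
    if not np.isclose(f470.rate_hz, f405.rate_hz):
        raise ValidationError("470 and 405 channels must share a sampling rate")
    s470 = slice_signal(f470, window)
    s405 = slice_signal(f405, window)
    if s470.n_samples != s405.n_samples:
        raise ValidationError("channels do not cover the window equally")
    x = s405.samples
    y = s470.samples
    if np.ptp(x) == 0:
        raise ValidationError("isosbestic channel has zero variance; regression degenerate")
    a, b = np.polyfit(x, y, 1)
    scaled = a * x + b
    denom = scaled if divide_by == "scaled" else x
    if np.any(denom <= 0):
        raise ValidationError("fitted reference crosses zero; DF/F undefined")
    dff = (y - scaled) / denom
    return CorrectedTrace(
        times_s=s470.times(), dff=dff, fit_slope=float(a), fit_intercept=float(b),
        rate_hz=f470.rate_hz,
    )


def analysis_window(epochs: EpochSet) -> Interval:
    """60 s before seizure onset through 90 s after seizure offset."""
    return (epochs.ictal[0] - ANALYSIS_PRE_S, epochs.ictal[1] + ANALYSIS_POST_S)


def zscore_recording(dff: np.ndarray) -> np.ndarray:
    """Z-score over the analysis window (sample SD, n-1 denominator)."""
    x = np.asarray(dff, dtype=float)
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValidationError("zero variance; Z-score undefined")
    return (x - float(np.mean(x))) / sd


def seizure_related_change(
    z: np.ndarray,
    times_s: np.ndarray,
    epochs: EpochSet,
    guard: float = BASELINE_GUARD,
    ictal_cutoff_s: float = 15.0,
) -> SeizureAChResult:
    """Per-period "seizure-related ACh change": Z relative to its baseline mean.

    ``change(t) = (z(t) - m_b) / m_b`` with ``m_b`` the mean baseline Z.  The
    ratio is unstable when ``m_b`` is near zero, so sessions with ``|m_b| <
    guard`` are flagged and their change values set to NaN (the per-period
    mean Z values are still reported).  Period means use the full ictal
    period; the 15 s cutoff is only for plotted timecourses.
    """
    z = np.asarray(z, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if z.shape != times_s.shape:
        raise ValidationError("z and times must align")

    def sel(interval: Interval) -> np.ndarray:
        return (times_s >= interval[0] - 1e-9) & (times_s < interval[1] - 1e-9)

    base = sel(epochs.baseline)
    if not base.any():
        raise ValidationError("no baseline samples in window")
    m_b = float(z[base].mean())
    flagged = abs(m_b) < guard
    if flagged:
        log.warning(
            "seizure_related_change: |mean baseline z| = %.4f < %.2f; session flagged", m_b, guard
        )
        change = np.full_like(z, np.nan)
    else:
        change = (z - m_b) / m_b
    period_change: dict[str, float] = {}
    period_mean_z: dict[str, float] = {}
    for period, interval in epochs.items():
        s = sel(interval)
        if not s.any():
            continue
        period_mean_z[period] = float(z[s].mean())
        period_change[period] = float(change[s].mean()) if not flagged else float("nan")
    return SeizureAChResult(
        times_s=times_s, z_dff=z, change=change, baseline_mean_z=m_b,
        period_change=period_change, period_mean_z=period_mean_z, flagged=flagged,
    )


def event_related_change(
    dff: ContinuousSignal, sound_time: float, half_width_s: float = EVENT_HALF_S
) -> EventAChResult | None:
    """Event-related ACh change for one sound (Z units).

    The 4 s segment is re-baselined by subtracting a line fit to the 2 s
    pre-stimulus part, then Z-scored by the re-baselined pre-stimulus mean
    and SD.  Returns ``None`` (event skipped) when the pre-stimulus SD is
    zero or coverage is incomplete.
    """
    if (
        sound_time - half_width_s < dff.t0_s - 1e-9
        or sound_time + half_width_s > dff.end_s + 1e-9
    ):
        log.info("event_related_change: event at %.2f s lacks +/-2 s coverage", sound_time)
        return None
    seg = slice_signal(dff, (sound_time - half_width_s, sound_time + half_width_s))
    t_rel = seg.times() - sound_time
    pre = t_rel < 0
    coeffs = np.polyfit(t_rel[pre], seg.samples[pre], 1)
    rebased = seg.samples - np.polyval(coeffs, t_rel)
    mu = float(rebased[pre].mean())
    sd = float(np.std(rebased[pre], ddof=1))
    # treat float residue of an exactly-fit pre segment as zero variance
    if sd <= 1e-10 * max(1.0, float(np.abs(seg.samples).max())):
        log.info("event_related_change: zero pre-stimulus SD at %.2f s; skipped", sound_time)
        return None
    z = (rebased - mu) / sd
    phase_means = {}
    for phase, (lo, hi, closed_hi) in PHASES.items():
        if closed_hi:
            m = (t_rel >= lo - 1e-9) & (t_rel <= hi + 1e-9)
        else:
            m = (t_rel >= lo - 1e-9) & (t_rel < hi - 1e-9)
        phase_means[phase] = float(z[m].mean())
    return EventAChResult(
        sound_time_s=float(sound_time), times_rel_s=t_rel, z_event=z, phase_means=phase_means
    )


def phase_contrast(groups: dict[str, list[EventAChResult]]):
    """Per-group Pre-Aud/P1/P2 phase statistics with Mann-Whitney contrasts.

    For each group (e.g. baseline-hit, ictal-hit, ictal-miss): mean and SEM
    of each phase across events, plus Pre-Aud-vs-P1 and Pre-Aud-vs-P2
    Mann-Whitney tests.  Empty groups are omitted with a log line.
    Returns a tidy DataFrame.
    """
    import pandas as pd

    from .stats import mann_whitney_u

    rows = []
    for group, events in groups.items():
        if not events:
            log.info("phase_contrast: group %r empty; omitted", group)
            continue
        arr = {ph: np.array([e.phase_means[ph] for e in events]) for ph in PHASES}
        n = len(events)
        for ph in PHASES:
            row = {
                "group": group,
                "phase": ph,
                "n": n,
                "mean": float(arr[ph].mean()),
                "sem": float(arr[ph].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
            }
            if ph != "pre_aud":
                res = mann_whitney_u(arr[ph], arr["pre_aud"])
                row["u"] = res.u
                row["p_vs_pre_aud"] = res.p
            rows.append(row)
    return pd.DataFrame(rows)
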