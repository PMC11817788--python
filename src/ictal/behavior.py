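"""Lick and locomotion quantification.

Hit/miss classification of each auditory trial (first lick within 1 s =
hit; later or absent first lick = miss, with a 3 s no-lick horizon),
seizure typing from ictal trials (spared = all hits, impaired = all misses,
mixed = both), peri-stimulus lick-rate timecourses in 0.1 s bins over
+/-2 s, peak-rate and first-lick-delay metrics, and wheel-encoder speed
with the 10 cm/s baseline running filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._filters import ema_lowpass
from .session import ContinuousSignal, EpochSet, ValidationError, slice_signal

__all__ = [
    "ResponseRecord",
    "LickTimecourse",
    "WheelSummary",
    "select_analyzable_sounds",
    "classify_response",
    "classify_seizure",
    "lick_rate_timecourse",
    "response_metrics",
    "wheel_speed",
    "HIT_WINDOW_S",
    "NOLICK_WINDOW_S",
    "MIN_SOUND_GAP_S",
]

HIT_WINDOW_S = 1.0
NOLICK_WINDOW_S = 3.0
MIN_SOUND_GAP_S = 4.0
PRE_STIM_WINDOW_S = 2.0
PEAK_WINDOW_S = (-0.1, 1.05)
TIMECOURSE_HALF_S = 2.0
TIMECOURSE_BIN_S = 0.1
RUNNING_MIN_CM_S = 10.0


@dataclass(frozen=True)
class ResponseRecord:
    """One sound presentation with its behavioral outcome."""

    sound_time_s: float
    epoch: str
    label: str  # "hit" | "miss"
    first_lick_delay_s: float | None  # None = no lick within 3 s
    analyzable: bool
    pre_stim_lick_rate_hz: float

    def __post_init__(self) -> None:
        if self.label not in ("hit", "miss"):
            raise ValidationError(f"label must be hit/miss, got {self.label!r}")
        if self.label == "hit" and not (
            self.first_lick_delay_s is not None and self.first_lick_delay_s <= HIT_WINDOW_S
        ):
            raise ValidationError("hit requires a first lick within the 1 s window")
        if self.label == "miss" and (
            self.first_lick_delay_s is not None and self.first_lick_delay_s <= HIT_WINDOW_S
        ):
            raise ValidationError("miss cannot have a first lick within the 1 s window")


@dataclass(frozen=True)
class LickTimecourse:
    """Average peri-stimulus lick rate, 40 non-overlapping 0.1 s bins on [-2, 2)."""

    bin_centers_s: np.ndarray
    rate_hz: np.ndarray
    n_events: int


@dataclass(frozen=True)
class WheelSummary:
    period_speed_cm_s: dict[str, float]
    running_eligible: bool


def select_analyzable_sounds(
    sound_times: np.ndarray, min_gap_s: float = MIN_SOUND_GAP_S
) -> np.ndarray:
    """Flag sounds usable for behavioral analysis.

    When two sounds fall closer than ``min_gap_s``, the earlier one is
    discarded; the last sound is always kept by this rule.
    """
    t = np.asarray(sound_times, dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValidationError("sound times must be strictly increasing")
    keep = np.ones(t.size, dtype=bool)
    if t.size > 1:
        keep[:-1] = np.diff(t) >= min_gap_s
    return keep


def classify_response(
    lick_times: np.ndarray,
    sound_time: float,
    hit_window_s: float = HIT_WINDOW_S,
    nolick_window_s: float = NOLICK_WINDOW_S,
    epoch: str = "other",
    analyzable: bool = True,
) -> ResponseRecord:
    """Classify one sound from the lick train.

    The first lick is the earliest lick strictly after the sound.  Delay at
    exactly the hit-window bound counts as a hit (closed upper bound).
    Licks later than ``nolick_window_s`` count as no lick (delay ``None``).
    """
    licks = np.asarray(lick_times, dtype=float)
    after = licks[licks > sound_time]
    delay: float | None = None
    if after.size:
        d = float(after[0] - sound_time)
        if d <= nolick_window_s:
            delay = d
    label = "hit" if (delay is not None and delay <= hit_window_s) else "miss"
    pre = int(np.count_nonzero((licks >= sound_time - PRE_STIM_WINDOW_S) & (licks < sound_time)))
    return ResponseRecord(
        sound_time_s=float(sound_time),
        epoch=epoch,
        label=label,
        first_lick_delay_s=delay,
        analyzable=bool(analyzable),
        pre_stim_lick_rate_hz=pre / PRE_STIM_WINDOW_S,
    )


def classify_seizure(responses: list[ResponseRecord]) -> str:
    """Type a seizure from its analyzable ictal responses.

    spared = only hits, impaired = only misses, mixed = both,
    unclassifiable = no analyzable ictal responses.
    """
    labels = {r.label for r in responses}
    if not labels:
        return "unclassifiable"
    if labels == {"hit"}:
        return "spared"
    if labels == {"miss"}:
        return "impaired"
    return "mixed"


def lick_rate_timecourse(lick_times: np.ndarray, event_times: np.ndarray) -> LickTimecourse:
    """Average peri-stimulus lick rate across events (0.1 s bins on [-2, 2))."""
    events = np.asarray(event_times, dtype=float)
    if events.size == 0:
        raise ValidationError("lick_rate_timecourse needs at least one event")
    licks = np.asarray(lick_times, dtype=float)
    edges = np.arange(
        -TIMECOURSE_HALF_S, TIMECOURSE_HALF_S + TIMECOURSE_BIN_S / 2, TIMECOURSE_BIN_S
    )
    counts = np.zeros(edges.size - 1)
    for t in events:
        counts += np.histogram(licks - t, bins=edges)[0]
    rate = counts / events.size / TIMECOURSE_BIN_S
    centers = (edges[:-1] + edges[1:]) / 2.0
    return LickTimecourse(bin_centers_s=centers, rate_hz=rate, n_events=int(events.size))


def response_metrics(
    timecourse: LickTimecourse,
    responses: list[ResponseRecord] | None = None,
    peak_window_s: tuple[float, float] = PEAK_WINDOW_S,
    censor_no_lick_at_s: float | None = None,
) -> tuple[float, float | None]:
    """(max lick rate, mean first-lick delay).

    The peak is taken over timecourse bins whose centers fall in the -0.1 to
    1.05 s window around the stimulus.  The delay mean excludes no-lick
    trials unless ``censor_no_lick_at_s`` substitutes a censoring value.
    """
    lo, hi = peak_window_s
    in_win = (timecourse.bin_centers_s >= lo - 1e-9) & (timecourse.bin_centers_s <= hi + 1e-9)
    max_rate = float(timecourse.rate_hz[in_win].max())
    mean_delay: float | None = None
    if responses is not None:
        delays = []
        for r in responses:
            if r.first_lick_delay_s is not None:
                delays.append(r.first_lick_delay_s)
            elif censor_no_lick_at_s is not None:
                delays.append(censor_no_lick_at_s)
        if delays:
            mean_delay = float(np.mean(delays))
    return max_rate, mean_delay


def wheel_speed(
    wheel_deg: ContinuousSignal,
    circumference_cm: float,
    epochs: EpochSet,
    smooth_s: float = 0.5,
) -> WheelSummary:
    """Per-period mean wheel speed (cm/s) from the 0-360 degree encoder signal.

    The angle is unwrapped (jumps above 180 degrees are wraparound), speed is
    ``|d(theta)/dt| * circumference / 360`` smoothed with a ``smooth_s``
    exponential average, and sessions qualify as running when the baseline
    mean reaches 10 cm/s.
    """
    theta = np.unwrap(wheel_deg.samples, period=360.0)
    dt = 1.0 / wheel_deg.rate_hz
    dist_cm = np.abs(np.gradient(theta)) / 360.0 * circumference_cm
    speed = dist_cm / dt
    speed = ema_lowpass(speed, smooth_s, wheel_deg.rate_hz)
    sig = ContinuousSignal(
        name="wheel_speed", samples=speed, rate_hz=wheel_deg.rate_hz,
        t0_s=wheel_deg.t0_s, units="cm/s",
    )
    period_speed = {
        period: float(np.mean(slice_signal(sig, interval).samples))
        for period, interval in epochs.items()
    }
    return WheelSummary(
        period_speed_cm_s=period_speed,
        running_eligible=period_speed["baseline"] >= RUNNING_MIN_CM_S,
    )
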