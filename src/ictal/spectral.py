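"""Baseline-normalized LFP time-frequency analysis.

Pipeline: optional DC removal (0.1 s time constant) and post-stimulation
polynomial artifact subtraction, then a short-time periodogram (1000 ms Hann
windows, 1 Hz frequency resolution, power spectral density in signal
units^2/Hz).  Each frequency row is divided by its mean baseline PSD; period
or band summaries average the pre-log ratio over frequencies and windows and
only then take ``10*log10`` to report dB/Hz.  Delta is 1-4 Hz, beta 15-30 Hz,
and ictal spectra are restricted to the first 15 s of the seizure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ._filters import dc_remove
from .session import (
    ContinuousSignal,
    EpochSet,
    Interval,
    IctalError,
    ValidationError,
    slice_signal,
)

__all__ = [
    "TFMap",
    "NormalizedTFMap",
    "BandSummary",
    "BANDS",
    "remove_dc",
    "remove_stim_artifact",
    "compute_spectrogram",
    "normalize_to_baseline",
    "band_period_summary",
    "event_aligned_spectrum",
    "DegenerateBaselineError",
]

log = logging.getLogger(__name__)

BANDS: dict[str, tuple[float, float]] = {"delta": (1.0, 4.0), "beta": (15.0, 30.0)}

PERIODS = ("baseline", "ictal", "early_postictal", "late_postictal")


class DegenerateBaselineError(IctalError):
    """Baseline mean PSD is zero at some frequency."""


@dataclass(frozen=True)
class TFMap:
    """Time-frequency power map: ``psd[freq, time]`` in units^2/Hz."""

    freqs_hz: np.ndarray
    times_s: np.ndarray
    psd: np.ndarray
    window_s: float

    def __post_init__(self) -> None:
        if self.psd.shape != (self.freqs_hz.size, self.times_s.size):
            raise ValidationError("psd shape must be (n_freqs, n_times)")


@dataclass(frozen=True)
class NormalizedTFMap:
    """TF map expressed as a power ratio to the per-frequency baseline mean.

    ``ratio[f, t] = psd[f, t] / mean_baseline_psd[f]``.  ``norm_db`` is the
    elementwise ``10*log10`` view used for display; summaries always average
    the ratio first and log afterwards.
    """

    freqs_hz: np.ndarray
    times_s: np.ndarray
    ratio: np.ndarray
    baseline_mean_psd: np.ndarray
    window_s: float

    @property
    def norm_db(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 10.0 * np.log10(self.ratio)


@dataclass(frozen=True)
class BandSummary:
    band: str
    lo_hz: float
    hi_hz: float
    period_db: dict[str, float]
    period_n_windows: dict[str, int]


def remove_dc(signal: ContinuousSignal, time_constant_s: float = 0.1) -> ContinuousSignal:
    """Single-pole DC removal: subtract the exponential moving average.

    Steady-state response to a constant input is zero; a sinusoid well above
    the corner ``1/(2*pi*tau)`` passes essentially unchanged.
    """
    if time_constant_s <= 0:
        raise ValidationError("time_constant_s must be > 0")
    return ContinuousSignal(
        name=signal.name,
        samples=dc_remove(signal.samples, time_constant_s, signal.rate_hz),
        rate_hz=signal.rate_hz,
        t0_s=signal.t0_s,
        units=signal.units,
    )


def remove_stim_artifact(
    signal: ContinuousSignal,
    stim_off_s: float,
    fit_window_s: float = 10.0,
    poly_order: int = 3,
) -> ContinuousSignal:
    """Fit and subtract a polynomial from the first 10 s after stimulation.

    The slow tail the electrical stimulus leaves on the cortical LFP is
    modeled as a low-order polynomial over ``[stim_off, stim_off +
    fit_window_s]``; the fit is subtracted on that window only and the rest
    of the signal is unchanged.
    """
    x = signal.samples.copy()
    i0 = int(np.ceil((stim_off_s - signal.t0_s) * signal.rate_hz - 1e-9))
    i1 = int(np.ceil((stim_off_s + fit_window_s - signal.t0_s) * signal.rate_hz - 1e-9))
    i0 = max(i0, 0)
    i1 = min(i1, x.size)
    if i1 - i0 < poly_order + 1:
        raise ValidationError(
            f"artifact fit window has {i1 - i0} samples; need at least {poly_order + 1}"
        )
    t = (np.arange(i0, i1) / signal.rate_hz) - (stim_off_s - signal.t0_s)
    coeffs = np.polyfit(t, x[i0:i1], poly_order)
    x[i0:i1] = x[i0:i1] - np.polyval(coeffs, t)
    return ContinuousSignal(
        name=signal.name, samples=x, rate_hz=signal.rate_hz, t0_s=signal.t0_s, units=signal.units
    )


def compute_spectrogram(
    signal: ContinuousSignal,
    window_s: float = 1.0,
    freq_resolution_hz: float = 1.0,
    overlap_frac: float = 0.5,
) -> TFMap:
    """Short-time Hann periodogram PSD.

    Window length is ``window_s * rate`` samples and the frequency grid is
    spaced at ``freq_resolution_hz``.  PSD normalization is scipy's density
    convention, so summing ``psd * df`` over frequencies recovers the
    (windowed) signal variance, and a unit sinusoid carries total power 1/2.
    """
    nperseg = int(round(window_s * signal.rate_hz))
    if signal.n_samples < nperseg:
        raise ValidationError("signal shorter than one spectrogram window")
    nfft = int(round(signal.rate_hz / freq_resolution_hz))
    if nfft < nperseg:
        raise ValidationError("frequency resolution finer than the window allows")
    noverlap = int(round(overlap_frac * nperseg))
    freqs, times, psd = sps.spectrogram(
        signal.samples,
        fs=signal.rate_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=nfft,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    return TFMap(freqs_hz=freqs, times_s=times + signal.t0_s, psd=psd, window_s=window_s)


def _windows_within(tf_times: np.ndarray, window_s: float, interval: Interval) -> np.ndarray:
    """Boolean mask of windows fully contained in ``interval``.

    Full containment (not just center membership) keeps windows that straddle
    a period boundary out of both periods' summaries.
    """
    half = window_s / 2.0
    return (tf_times - half >= interval[0] - 1e-9) & (tf_times + half <= interval[1] + 1e-9)


def normalize_to_baseline(
    tf: TFMap, baseline: Interval, min_baseline_windows: int = 5
) -> NormalizedTFMap:
    """Divide each frequency row by its mean PSD over the baseline period."""
    mask = _windows_within(tf.times_s, tf.window_s, baseline)
    if int(mask.sum()) < min_baseline_windows:
        raise ValidationError(
            f"baseline contains {int(mask.sum())} spectrogram windows; "
            f"need at least {min_baseline_windows}"
        )
    base = tf.psd[:, mask].mean(axis=1)
    if np.any(base == 0):
        raise DegenerateBaselineError("baseline mean PSD is zero at some frequency")
    return NormalizedTFMap(
        freqs_hz=tf.freqs_hz,
        times_s=tf.times_s,
        ratio=tf.psd / base[:, None],
        baseline_mean_psd=base,
        window_s=tf.window_s,
    )


def _band_rows(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)


def band_period_summary(
    ntf: NormalizedTFMap,
    epochs: EpochSet,
    bands: dict[str, tuple[float, float]] | None = None,
    ictal_cutoff_s: float | None = 15.0,
    mask_intervals: list[Interval] | None = None,
) -> dict[str, BandSummary]:
    """Per-band, per-period mean normalized power in dB/Hz.

    The pre-log power ratio is averaged over band frequencies and over all
    windows fully inside the period, then converted with ``10*log10``.  The
    ictal period is truncated to its first ``ictal_cutoff_s`` seconds
    (seizure durations vary); windows intersecting ``mask_intervals`` (e.g.
    the stimulation train) are dropped everywhere.
    """
    bands = BANDS if bands is None else bands
    drop = np.zeros(ntf.times_s.size, dtype=bool)
    half = ntf.window_s / 2.0
    for a, b in mask_intervals or []:
        drop |= (ntf.times_s + half > a) & (ntf.times_s - half < b)

    out: dict[str, BandSummary] = {}
    for band, (lo, hi) in bands.items():
        rows = _band_rows(ntf.freqs_hz, lo, hi)
        if not rows.any():
            raise ValidationError(f"band {band}: no frequency bins in [{lo}, {hi}] Hz")
        period_db: dict[str, float] = {}
        period_n: dict[str, int] = {}
        for period, interval in epochs.items():
            if period == "ictal" and ictal_cutoff_s is not None:
                interval = (interval[0], min(interval[1], interval[0] + ictal_cutoff_s))
            cols = _windows_within(ntf.times_s, ntf.window_s, interval) & ~drop
            if not cols.any():
                raise ValidationError(f"period {period}: no spectrogram windows")
            mean_ratio = float(ntf.ratio[np.ix_(rows, cols)].mean())
            period_db[period] = 10.0 * np.log10(mean_ratio)
            period_n[period] = int(cols.sum())
        out[band] = BandSummary(
            band=band, lo_hz=lo, hi_hz=hi, period_db=period_db, period_n_windows=period_n
        )
    return out


@dataclass(frozen=True)
class EventSpectrum:
    event_time_s: float
    ntf: NormalizedTFMap
    delta_db: float


def event_aligned_spectrum(
    signal: ContinuousSignal,
    event_times: np.ndarray,
    baseline_mean_psd: np.ndarray,
    half_width_s: float = 2.0,
    window_s: float = 1.0,
    freq_resolution_hz: float = 1.0,
    overlap_frac: float = 0.5,
    band: tuple[float, float] = BANDS["delta"],
) -> tuple[list[EventSpectrum], int]:
    """Per-event +/-2 s spectra normalized by the session baseline PSD.

    Returns the surviving events and the number dropped for incomplete
    coverage.  Each event also carries its delta-band mean in dB (average of
    the pre-log ratio over the 4 s segment, then log), the quantity used for
    hit-versus-miss contrasts.
    """
    results: list[EventSpectrum] = []
    dropped = 0
    for t in np.asarray(event_times, dtype=float):
        if t - half_width_s < signal.t0_s - 1e-9 or t + half_width_s > signal.end_s + 1e-9:
            dropped += 1
            continue
        seg = slice_signal(signal, (t - half_width_s, t + half_width_s))
        tf = compute_spectrogram(
            seg, window_s=window_s, freq_resolution_hz=freq_resolution_hz, overlap_frac=overlap_frac
        )
        if np.any(baseline_mean_psd == 0):
            raise DegenerateBaselineError("baseline mean PSD is zero at some frequency")
        ratio = tf.psd / baseline_mean_psd[:, None]
        ntf = NormalizedTFMap(
            freqs_hz=tf.freqs_hz,
            times_s=tf.times_s,
            ratio=ratio,
            baseline_mean_psd=baseline_mean_psd,
            window_s=tf.window_s,
        )
        rows = _band_rows(tf.freqs_hz, *band)
        delta_db = 10.0 * np.log10(float(ratio[rows, :].mean()))
        results.append(EventSpectrum(event_time_s=float(t), ntf=ntf, delta_db=delta_db))
    if dropped:
        log.info("event_aligned_spectrum: dropped %d events lacking coverage", dropped)
    if not results:
        raise ValidationError("no events with full coverage")
    return results, dropped
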