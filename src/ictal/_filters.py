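"""Shared single-pole "time constant" filters.

The acquisition-software operations the analysis mirrors ("DC removal
filter", "smoothing filter", each with a stated time constant) are
first-order exponential filters: smoothing is a single-pole low pass with
coefficient ``alpha = 1 - exp(-dt/tau)``, DC removal subtracts that low-pass
from the input.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps


def ema_lowpass(x: np.ndarray, tau_s: float, rate_hz: float) -> np.ndarray:
    """Exponential moving average with time constant ``tau_s``.

    Initialized at the first sample, so a constant input is passed through
    unchanged from the start.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be > 0")
    x = np.asarray(x, dtype=np.float64)
    alpha = 1.0 - np.exp(-1.0 / (tau_s * rate_hz))
    b = [alpha]
    a = [1.0, -(1.0 - alpha)]
    zi = np.array([(1.0 - alpha) * x[0]])
    y, _ = sps.lfilter(b, a, x, zi=zi)
    return y


def dc_remove(x: np.ndarray, tau_s: float, rate_hz: float) -> np.ndarray:
    """Subtract the exponential moving average (single-pole high pass)."""
    x = np.asarray(x, dtype=np.float64)
    return x - ema_lowpass(x, tau_s, rate_hz)


def highpass_butter(x: np.ndarray, cutoff_hz: float, rate_hz: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth high pass (used to isolate MUA above 400 Hz)."""
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=rate_hz, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=np.float64))
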