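"""Shared Butterworth filter designs.

The synthetic generator and the feature extractor use the *same* band
filters, so that band-power parameters written into a synthetic recording
are recoverable by the analysis path without a model mismatch.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import signal

DEFAULT_ORDER = 4


@lru_cache(maxsize=256)
def bandpass_sos(low_hz: float, high_hz: float, fs_hz: float, order: int = DEFAULT_ORDER) -> np.ndarray:
    """Second-order sections for a Butterworth band-pass [low_hz, high_hz]."""
    nyq = fs_hz / 2.0
    if not 0.0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band edges [{low_hz}, {high_hz}] Hz invalid for fs={fs_hz} Hz (Nyquist {nyq} Hz)"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs_hz, output="sos")


def lowpass_sos(cutoff_hz: float, fs_hz: float, order: int = 8) -> np.ndarray:
    """Second-order sections for a Butterworth low-pass (anti-alias) filter."""
    nyq = fs_hz / 2.0
    if not 0.0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz invalid for fs={fs_hz} Hz")
    return signal.butter(order, cutoff_hz, btype="lowpass", fs=fs_hz, output="sos")


def filtfilt(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Zero-phase filtering along the last axis with reflective padding."""
    return signal.sosfiltfilt(sos, x, axis=-1)
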