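"""Shared signal-processing helpers: zero-phase low-pass filtering and
central-difference differentiation on uniformly sampled marker signals."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

#: Default low-pass cutoff for gait kinematics at ~100-200 Hz capture rates.
DEFAULT_CUTOFF_HZ = 6.0


def lowpass(x: np.ndarray, fs: float, cutoff: float = DEFAULT_CUTOFF_HZ,
            order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0.

    ``filtfilt`` doubles the effective order, so ``order=4`` is built from a
    2nd-order section pair, the usual convention when a "4th-order
    zero-phase" filter is quoted.
    """
    if cutoff <= 0 or cutoff >= fs / 2:
        return np.asarray(x, float)
    x = np.asarray(x, float)
    if x.shape[0] < 15:  # too short for stable edge padding
        return x
    sos = sps.butter(order // 2, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def central_diff(x: np.ndarray, fs: float) -> np.ndarray:
    """Central-difference derivative along axis 0 (one-sided at the ends)."""
    return np.gradient(np.asarray(x, float), 1.0 / fs, axis=0)
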