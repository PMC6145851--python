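"""Canonical double-gamma haemodynamic response function.

One kernel is shared by every consumer that needs haemodynamic
convolution: the optional smoothing of synthetic BOLD, the pupil
regressor, and the task-design boxcars.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as gamma_dist

# SPM-convention shape/scale parameters (times in seconds):
# peak gamma(6, 1), undershoot gamma(16, 1), undershoot ratio 1/6.
_PEAK_SHAPE = 6.0
_UNDER_SHAPE = 16.0
_SCALE = 1.0
_UNDER_RATIO = 1.0 / 6.0


def double_gamma_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Sample the canonical double-gamma HRF on a TR grid.

    Parameters
    ----------
    tr
        Sampling interval in seconds.
    duration
        Kernel length in seconds (default 32 s covers the undershoot).

    Returns
    -------
    Kernel normalised to unit sum, first sample at t = 0.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, duration, tr)
    h = gamma_dist.pdf(t, _PEAK_SHAPE, scale=_SCALE) - _UNDER_RATIO * gamma_dist.pdf(
        t, _UNDER_SHAPE, scale=_SCALE
    )
    total = h.sum()
    if abs(total) < 1e-12:
        raise ValueError("degenerate HRF kernel (tr too coarse for duration)")
    return h / total


def hrf_convolve(x: np.ndarray, tr: float, duration: float = 32.0) -> np.ndarray:
    """Convolve a series (or each column of a matrix) with the canonical HRF.

    Causal convolution truncated to the input length, so the output is
    aligned with the input's time grid.
    """
    x = np.asarray(x, dtype=float)
    h = double_gamma_hrf(tr, duration)
    if x.ndim == 1:
        return np.convolve(x, h)[: x.shape[0]]
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j] = np.convolve(x[:, j], h)[: x.shape[0]]
    return out
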