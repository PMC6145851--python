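"""Multiplication of Temporal Derivatives (MTD) coupling.

The MTD between regions i and j in the window centred at t is the
windowed mean of the product of their standardised first temporal
derivatives:

    MTD_ijt = (1/w) * sum_{u in window(t)} dt_iu * dt_ju / (sigma_i * sigma_j)

where dt is the backward first difference of the series and sigma the
standard deviation of the full derivative series of that region (the
normalisation is per-region and run-wide, outside the window sum).  The
result is a signed, weighted region x region x window coupling tensor.

Edge handling: windows are centred on the derivative-index grid and
only full ("valid") windows are emitted, giving (frames - 1) - w + 1
windows.  For even w the window spans [t - w/2, t + w/2) on that grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ParcellatedTimeSeries

__all__ = ["MTDTensor", "temporal_derivative", "mtd_coupling"]


@dataclass(frozen=True)
class MTDTensor:
    """Signed coupling tensor: ``coupling`` is regions x regions x windows."""

    coupling: np.ndarray
    window_length: int
    window_centers: np.ndarray  # derivative-grid index of each window centre
    region_labels: tuple[str, ...]

    def __post_init__(self):
        c = np.asarray(self.coupling, dtype=float)
        if c.ndim != 3 or c.shape[0] != c.shape[1]:
            raise ValueError("coupling must be regions x regions x windows")
        object.__setattr__(self, "coupling", c)
        object.__setattr__(
            self, "window_centers", np.asarray(self.window_centers, dtype=int)
        )
        object.__setattr__(
            self, "region_labels", tuple(str(x) for x in self.region_labels)
        )

    @property
    def n_regions(self) -> int:
        return self.coupling.shape[0]

    @property
    def n_windows(self) -> int:
        return self.coupling.shape[2]

    def window(self, t: int) -> np.ndarray:
        """Return window t's region x region coupling matrix (copy)."""
        return self.coupling[:, :, t].copy()


def temporal_derivative(
    ts: ParcellatedTimeSeries,
) -> tuple[np.ndarray, np.ndarray]:
    """Backward first difference and its per-region standard deviation.

    Returns the (frames-1) x regions derivative matrix and the
    population sd of each region's derivative series.  A constant region
    (zero derivative sd) is an error: its MTD normalisation is undefined.
    """
    if ts.n_frames < 3:
        raise ValueError("need at least 3 frames")
    d = np.diff(ts.data, axis=0)
    sigma = d.std(axis=0)  # population sd over the full derivative series
    if np.any(sigma == 0):
        bad = [ts.region_labels[i] for i in np.flatnonzero(sigma == 0)]
        raise ValueError(f"constant series (zero derivative sd) in regions: {bad}")
    return d, sigma


def mtd_coupling(
    ts: ParcellatedTimeSeries, w: int = 15, stride: int = 1
) -> MTDTensor:
    """Sliding-window MTD coupling tensor.

    Parameters
    ----------
    ts
        Input series (frames >= w + 2).
    w
        Window length in time points (default 15, ~33 s at TR 2.2 s).
    stride
        Step between successive window centres (default 1).
    """
    if w < 1:
        raise ValueError("window length must be >= 1")
    if ts.n_frames < w + 2:
        raise ValueError(f"need at least w + 2 = {w + 2} frames, got {ts.n_frames}")
    d, sigma = temporal_derivative(ts)
    dz = d / sigma  # standardised derivatives, (T-1) x N
    n_deriv, n = dz.shape
    # windowed mean of the outer-product series via cumulative sums; a window
    # starting at derivative index s spans [s, s + w) and is centred at
    # s + w//2 (for even w the extra element sits on the left, i.e. the window
    # is [t - w/2, t + w/2)).  Only full windows are emitted.
    prod = dz[:, :, None] * dz[:, None, :]  # (T-1) x N x N
    cs = np.concatenate([np.zeros((1, n, n)), np.cumsum(prod, axis=0)], axis=0)
    starts = np.arange(0, n_deriv - w + 1, stride, dtype=int)
    sums = cs[starts + w] - cs[starts]
    centers = starts + w // 2
    tensor = np.moveaxis(sums / w, 0, 2)
    return MTDTensor(
        coupling=tensor,
        window_length=w,
        window_centers=centers,
        region_labels=ts.region_labels,
    )
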