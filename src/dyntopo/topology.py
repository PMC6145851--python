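"""Regional cartography: module-degree z-score, participation, flexibility.

For each window's partition, every region gets a within-module degree
z-score

    W_i = (kappa_i - mean_s(kappa)) / sd_s(kappa)

(kappa_i = positive strength of i to other members of its module s, the
mean/sd taken over the members of s) and a participation coefficient

    B_i = 1 - sum_s (kappa_is / kappa_i)^2

over positive connections (0 when every positive link stays inside the
region's own module, 1 - 1/n_M when strength spreads uniformly over n_M
modules).  Pooling (B, W) samples over regions and windows into a joint
histogram gives the cartographic profile whose occupancy along B tracks
network integration.

Flexibility is the fraction of window-to-window transitions at which a
region changes module, after module labels have been aligned across
consecutive windows by Hungarian maximum-overlap matching.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .community import SignedGraph, WindowPartitionSet
from .mtd import MTDTensor

__all__ = [
    "TopologySeries",
    "CartographicProfile",
    "FlexibilityVector",
    "module_degree_zscore",
    "participation_coef",
    "topology_series",
    "cartographic_profile",
    "match_labels",
    "regional_flexibility",
]


@dataclass(frozen=True)
class TopologySeries:
    """Per-window, per-region W (module-degree z) and B (participation)."""

    W: np.ndarray  # windows x regions
    B: np.ndarray  # windows x regions, in [0, 1]

    def __post_init__(self):
        w = np.atleast_2d(np.asarray(self.W, dtype=float))
        b = np.atleast_2d(np.asarray(self.B, dtype=float))
        if w.shape != b.shape:
            raise ValueError("W and B must have identical shapes")
        if not np.all(np.isfinite(w)):
            raise ValueError("W must be finite")
        if b.min() < -1e-12 or b.max() > 1 + 1e-12:
            raise ValueError("B must lie in [0, 1]")
        object.__setattr__(self, "W", w)
        object.__setattr__(self, "B", np.clip(b, 0.0, 1.0))

    @property
    def mean_B(self) -> np.ndarray:
        """Per-window mean participation (the global integration series)."""
        return self.B.mean(axis=1)

    @property
    def mean_W(self) -> np.ndarray:
        return self.W.mean(axis=1)


@dataclass(frozen=True)
class CartographicProfile:
    """Joint (B, W) occupancy histogram with fixed bin edges."""

    occupancy: np.ndarray  # nB x nW, proportions summing to 1
    b_edges: np.ndarray
    w_edges: np.ndarray
    n_clipped: int = 0

    def __post_init__(self):
        occ = np.asarray(self.occupancy, dtype=float)
        be = np.asarray(self.b_edges, dtype=float)
        we = np.asarray(self.w_edges, dtype=float)
        if occ.shape != (len(be) - 1, len(we) - 1):
            raise ValueError("occupancy shape must match bin edges")
        if abs(occ.sum() - 1.0) > 1e-9:
            raise ValueError("occupancy must sum to 1")
        if np.any(np.diff(be) <= 0) or np.any(np.diff(we) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "b_edges", be)
        object.__setattr__(self, "w_edges", we)

    @property
    def b_centers(self) -> np.ndarray:
        return 0.5 * (self.b_edges[:-1] + self.b_edges[1:])

    def b_center_of_mass(self) -> float:
        """Occupancy-weighted mean B — a scalar integration summary."""
        return float(self.b_centers @ self.occupancy.sum(axis=1))


@dataclass(frozen=True)
class FlexibilityVector:
    """Per-region module-switch fraction plus the normalisation used."""

    values: np.ndarray
    normalization: str = "switch_fraction"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("flexibility values must lie in [0, 1]")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))


def _positive_strengths(weights: np.ndarray, partition: np.ndarray):
    """Per-node positive strength to each module (off-diagonal)."""
    wp = np.clip(weights, 0, None).copy()
    np.fill_diagonal(wp, 0.0)
    part = np.asarray(partition)
    mods = np.unique(part)
    onehot = (part[:, None] == mods[None, :]).astype(float)  # n x m
    return wp @ onehot, part, mods  # kappa_is: n x m


def module_degree_zscore(g: SignedGraph, partition: np.ndarray) -> np.ndarray:
    """Within-module degree z-score per region (positive weights).

    Members of a module whose within-module strengths have zero spread
    get W = 0 (the z-score is undefined there).
    """
    kis, part, mods = _positive_strengths(g.weights, partition)
    w = np.zeros(g.n_nodes)
    for k, m in enumerate(mods):
        members = part == m
        kappa = kis[members, k]
        sd = kappa.std()
        if sd > 0:
            w[members] = (kappa - kappa.mean()) / sd
    return w


def participation_coef(g: SignedGraph, partition: np.ndarray) -> np.ndarray:
    """Participation coefficient per region over positive connections.

    B_i = 1 - sum_s (kappa_is / kappa_i)^2; regions with no positive
    strength get B = 0.
    """
    kis, _, _ = _positive_strengths(g.weights, partition)
    ki = kis.sum(axis=1)
    b = np.zeros(g.n_nodes)
    pos = ki > 0
    b[pos] = 1.0 - np.sum((kis[pos] / ki[pos, None]) ** 2, axis=1)
    return b


def topology_series(
    tensor: MTDTensor,
    parts: WindowPartitionSet | np.ndarray,
) -> TopologySeries:
    """W and B in every window of an MTD tensor.

    ``parts`` is either a :class:`WindowPartitionSet` (one partition per
    window) or a single fixed partition applied to all windows — the
    latter is the reduced pipeline used by large calibration and power
    simulations where per-window community detection is not the question
    under test.
    """
    n_win, n_reg = tensor.n_windows, tensor.n_regions
    if not isinstance(parts, WindowPartitionSet):
        fixed = np.asarray(parts)
        if fixed.shape != (n_reg,):
            raise ValueError("fixed partition must have one id per region")
        return _topology_series_fixed(tensor, fixed)
    if parts.assignments.shape != (n_win, n_reg):
        raise ValueError("partition set does not match tensor shape")
    w = np.empty((n_win, n_reg))
    b = np.empty((n_win, n_reg))
    for t in range(n_win):
        g = SignedGraph(tensor.window(t))
        part = parts.assignments[t]
        w[t] = module_degree_zscore(g, part)
        b[t] = participation_coef(g, part)
    return TopologySeries(W=w, B=b)


def _topology_series_fixed(tensor: MTDTensor, partition: np.ndarray) -> TopologySeries:
    """Vectorised W/B across windows for one shared partition."""
    n_reg = tensor.n_regions
    mods = np.unique(partition)
    onehot = (partition[:, None] == mods[None, :]).astype(float)
    wpos = np.clip(np.moveaxis(tensor.coupling, 2, 0), 0, None).copy()
    eye = np.eye(n_reg, dtype=bool)
    wpos[:, eye] = 0.0
    kis = wpos @ onehot  # (win, N, m)
    ki = kis.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = 1.0 - np.sum((kis / ki[..., None]) ** 2, axis=2)
    b[ki <= 0] = 0.0
    mod_index = np.searchsorted(mods, partition)
    kappa = kis[:, np.arange(n_reg), mod_index]  # within-module strength
    w = np.zeros_like(kappa)
    for k in range(len(mods)):
        members = mod_index == k
        kap = kappa[:, members]
        mu = kap.mean(axis=1, keepdims=True)
        sd = kap.std(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, (kap - mu) / sd, 0.0)
        w[:, members] = z
    return TopologySeries(W=w, B=b)


def cartographic_profile(
    topo: TopologySeries,
    n_bins_b: int = 100,
    n_bins_w: int = 100,
    b_range: tuple[float, float] = (0.0, 1.0),
    w_range: tuple[float, float] = (-5.0, 5.0),
) -> CartographicProfile:
    """Joint (B, W) occupancy histogram pooled over regions and windows.

    W samples outside ``w_range`` are clipped into the edge bins and
    counted in ``n_clipped``.  Occupancy is normalised to proportions.
    """
    b = topo.B.ravel()
    w = topo.W.ravel()
    if b.size == 0:
        raise ValueError("empty topology series")
    n_clipped = int(np.sum((w < w_range[0]) | (w > w_range[1])))
    n_clipped += int(np.sum((b < b_range[0]) | (b > b_range[1])))
    eps = 1e-12
    b = np.clip(b, b_range[0], b_range[1] - eps)
    w = np.clip(w, w_range[0], w_range[1] - eps)
    b_edges = np.linspace(*b_range, n_bins_b + 1)
    w_edges = np.linspace(*w_range, n_bins_w + 1)
    hist, _, _ = np.histogram2d(b, w, bins=(b_edges, w_edges))
    return CartographicProfile(
        occupancy=hist / hist.sum(),
        b_edges=b_edges,
        w_edges=w_edges,
        n_clipped=n_clipped,
    )


def match_labels(parts: WindowPartitionSet) -> WindowPartitionSet:
    """Align module labels across consecutive windows (Hungarian matching).

    Window t's modules are relabelled to maximise member overlap with
    window t-1's (already matched) labels; modules without a match keep
    receiving fresh ids.  Groupings and per-window modularity are
    untouched — this is a pure relabelling.
    """
    if parts.n_windows < 2:
        raise ValueError("need at least 2 windows to match labels")
    out = np.empty_like(parts.assignments)
    out[0] = parts.assignments[0]
    next_id = int(out[0].max()) + 1
    for t in range(1, parts.n_windows):
        prev = out[t - 1]
        cur = parts.assignments[t]
        prev_ids = np.unique(prev)
        cur_ids = np.unique(cur)
        overlap = np.zeros((len(cur_ids), len(prev_ids)))
        for a, ca in enumerate(cur_ids):
            in_a = cur == ca
            for b, pb in enumerate(prev_ids):
                overlap[a, b] = np.sum(in_a & (prev == pb))
        rows, cols = linear_sum_assignment(-overlap)
        mapping: dict[int, int] = {}
        for r, c in zip(rows, cols):
            if overlap[r, c] > 0:
                mapping[int(cur_ids[r])] = int(prev_ids[c])
        relabeled = np.empty_like(cur)
        for ca in cur_ids:
            if int(ca) in mapping:
                relabeled[cur == ca] = mapping[int(ca)]
            else:
                relabeled[cur == ca] = next_id
                next_id += 1
        out[t] = relabeled
    return replace(parts, assignments=out)


def regional_flexibility(
    parts: WindowPartitionSet,
    normalization: str = "switch_fraction",
) -> FlexibilityVector:
    """Fraction of transitions at which each region switches module.

    Assumes ``parts`` has label-matched assignments (see
    :func:`match_labels`).  ``normalization='per_module'`` additionally
    divides by the mean per-window module count, the reading of
    "normalised to the total number of modules" that keeps values in
    [0, 1].
    """
    if normalization not in ("switch_fraction", "per_module"):
        raise ValueError(f"unknown normalization {normalization!r}")
    a = parts.assignments
    if a.shape[0] < 2:
        raise ValueError("need at least 2 windows")
    switches = (np.diff(a, axis=0) != 0).mean(axis=0)
    if normalization == "per_module":
        switches = switches / parts.n_modules.mean()
    return FlexibilityVector(values=switches, normalization=normalization)
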