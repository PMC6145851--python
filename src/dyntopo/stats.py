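"""Group-level inference for time-resolved topology.

Implements the study's statistical surface: per-bin crossover (2 x 2
within-subject) ANOVA on cartographic-profile occupancy with FDR
control, pupil-topology Spearman correlations tested at the group level
on Fisher-z values, the task GLM with main-effect and load-effect F
contrasts, permutation and bootstrap tests for correlations between
regional effect maps, and the Dunn & Clark z for comparing dependent
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import TaskDesign
from .hrf import double_gamma_hrf

__all__ = [
    "CohortProfiles",
    "StatMap",
    "fdr_bh",
    "bin_anova_2x2",
    "pupil_to_windows",
    "pupil_topology_correlation",
    "task_glm",
    "TaskGlmResult",
    "permutation_corr_test",
    "bootstrap_corr_ci",
    "dunn_clark_z",
]

SESSIONS = ("placebo", "drug")
PHASES = ("pre", "post")


@dataclass(frozen=True)
class CohortProfiles:
    """Occupancy per subject x session x phase, on a shared bin grid.

    ``occupancy`` has shape (n_subjects, 2, 2, n_bins...) with axis 1
    indexed by session (placebo, drug) and axis 2 by phase (pre, post).
    """

    occupancy: np.ndarray
    subjects: tuple[str, ...]

    def __post_init__(self):
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim < 4 or occ.shape[1:3] != (2, 2):
            raise ValueError(
                "occupancy must be (subjects, 2 sessions, 2 phases, bins...)"
            )
        if not np.all(np.isfinite(occ)):
            bad = [
                self.subjects[i]
                for i in range(occ.shape[0])
                if not np.all(np.isfinite(occ[i]))
            ]
            raise ValueError(f"incomplete 2x2 design for subjects: {bad}")
        if len(self.subjects) != occ.shape[0]:
            raise ValueError("one subject label per occupancy row required")
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "subjects", tuple(self.subjects))

    @property
    def n_subjects(self) -> int:
        return self.occupancy.shape[0]

    @property
    def bin_shape(self) -> tuple[int, ...]:
        return self.occupancy.shape[3:]


@dataclass(frozen=True)
class StatMap:
    """Per-bin (or per-region) statistic with FDR-adjusted decisions."""

    statistic: np.ndarray
    pvalues: np.ndarray
    significant: np.ndarray
    q: float
    fdr_threshold: float
    name: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        p = np.asarray(self.pvalues, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        object.__setattr__(self, "pvalues", p)
        object.__setattr__(self, "statistic", np.asarray(self.statistic, dtype=float))
        object.__setattr__(self, "significant", np.asarray(self.significant, dtype=bool))


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up FDR control at level ``q``.

    Returns the rejection mask (same shape as the input) and the p-value
    threshold actually applied (0 when nothing is rejected).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(p.shape, dtype=bool), 0.0
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    flat = p.ravel()
    reject, *_ = multipletests(flat, alpha=q, method="fdr_bh")
    thresh = float(flat[reject].max()) if reject.any() else 0.0
    return reject.reshape(p.shape), thresh


def bin_anova_2x2(profiles: CohortProfiles, q: float = 0.05) -> StatMap:
    """Within-subject 2 x 2 interaction ANOVA per profile bin.

    The drug-by-phase interaction in a complete within-subject crossover
    is the paired contrast d = (post - pre)_drug - (post - pre)_placebo;
    its F statistic equals the squared paired t of d against zero with
    (1, n - 1) degrees of freedom.  FDR is controlled across bins.
    """
    occ = profiles.occupancy
    n = profiles.n_subjects
    if n < 2:
        raise ValueError("need at least 2 subjects")
    d = (occ[:, 1, 1] - occ[:, 1, 0]) - (occ[:, 0, 1] - occ[:, 0, 0])
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    f = t**2
    p = sps.f.sf(f, 1, n - 1)
    p = np.where((sd == 0) & (mean == 0), 1.0, p)
    sig, thresh = fdr_bh(p, q=q)
    return StatMap(
        statistic=f,
        pvalues=p,
        significant=sig,
        q=q,
        fdr_threshold=thresh,
        name="2x2 within-subject interaction F",
        extra={"df": (1, n - 1), "effect": mean},
    )


def pupil_to_windows(
    pupil_frames: np.ndarray, window_centers: np.ndarray, w: int
) -> np.ndarray:
    """Average a frame-rate pupil series over each MTD window.

    ``window_centers`` index the derivative grid; frame u of the raw
    series contributes to derivative index u - 1 and u, so the window
    [c - w//2, c - w//2 + w) on the derivative grid is read as frames
    [c - w//2, c - w//2 + w] on the acquisition grid.
    """
    x = np.asarray(pupil_frames, dtype=float)
    out = np.empty(len(window_centers))
    for k, c in enumerate(window_centers):
        lo = c - w // 2
        out[k] = x[lo : lo + w + 1].mean()
    return out


def pupil_topology_correlation(
    pupil_windowed: Sequence[np.ndarray | None],
    bin_series: Sequence[np.ndarray | None],
    tr: float | None = None,
    kernel: np.ndarray | None = None,
    q: float = 0.05,
) -> tuple[np.ndarray, StatMap]:
    """Spearman correlation of pupil diameter with each profile-bin series.

    Per subject, the (optionally HRF-convolved) windowed pupil series is
    rank-correlated with the occupancy time series of every cartographic
    bin; the group-level test is a one-sample t on the Fisher-z rho per
    bin (equivalent to the subject-random-intercept model when each
    subject contributes one rho), FDR-controlled across bins.

    Subjects passed as ``None`` (e.g. excluded for pupil quality) are
    skipped; their count is recorded in the result.
    """
    if kernel is None and tr is not None:
        kernel = double_gamma_hrf(tr)
    rhos = []
    n_dropped = 0
    for pup, bins in zip(pupil_windowed, bin_series):
        if pup is None or bins is None:
            n_dropped += 1
            continue
        pup = np.asarray(pup, dtype=float)
        if kernel is not None:
            pup = np.convolve(pup, kernel)[: pup.shape[0]]
        bins = np.asarray(bins, dtype=float)
        if bins.shape[0] != pup.shape[0]:
            raise ValueError("pupil and bin series must share the window grid")
        r = np.empty(bins.shape[1:])
        flat = bins.reshape(bins.shape[0], -1)
        rf = np.empty(flat.shape[1])
        for j in range(flat.shape[1]):
            col = flat[:, j]
            if col.std() == 0 or pup.std() == 0:
                rf[j] = 0.0
            else:
                rf[j] = sps.spearmanr(pup, col).statistic
        rhos.append(rf.reshape(r.shape))
    if len(rhos) < 2:
        raise ValueError("need at least 2 usable subjects")
    rho = np.stack(rhos)
    z = np.arctanh(np.clip(rho, -0.999999, 0.999999))
    n = z.shape[0]
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    p = 2 * sps.t.sf(np.abs(t), n - 1)
    p = np.where((sd == 0) & (mean == 0), 1.0, p)
    sig, thresh = fdr_bh(p, q=q)
    return rho, StatMap(
        statistic=t,
        pvalues=p,
        significant=sig,
        q=q,
        fdr_threshold=thresh,
        name="group mean Fisher-z pupil rho (one-sample t)",
        extra={"n_subjects": n, "n_dropped": n_dropped, "mean_z": mean},
    )


@dataclass(frozen=True)
class TaskGlmResult:
    betas: np.ndarray  # conditions(+nuisance) x targets
    columns: tuple[str, ...]
    f_main: StatMap
    f_load: StatMap


def _design_on_windows(
    design: TaskDesign,
    n_frames: int,
    window_centers: np.ndarray,
    w: int,
    convolve: bool,
    conditions: Sequence[str],
) -> np.ndarray:
    cols = []
    t = np.arange(n_frames) * design.tr
    for cond in conditions:
        box = np.zeros(n_frames)
        for c, o, d in design.blocks:
            if c == cond:
                box[(t >= o) & (t < o + d)] = 1.0
        if convolve:
            h = double_gamma_hrf(design.tr)
            box = np.convolve(box, h)[:n_frames]
        # average the frame-level regressor over each MTD window
        win = np.empty(len(window_centers))
        for k, c0 in enumerate(window_centers):
            lo = c0 - w // 2
            win[k] = box[lo : lo + w + 1].mean()
        cols.append(win)
    return np.column_stack(cols)


def _contrast_f(
    x: np.ndarray, y: np.ndarray, beta: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """F test of a single linear restriction c'beta = 0 for every column of y."""
    n, k = x.shape
    dof = n - k
    resid = y - x @ beta
    sigma2 = np.sum(resid**2, axis=0) / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    denom = float(c @ xtx_inv @ c)
    num = (c @ beta) ** 2 / denom
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(sigma2 > 0, num / sigma2, 0.0)
    p = sps.f.sf(f, 1, dof)
    return f, p


def task_glm(
    topo_values: np.ndarray,
    design: TaskDesign,
    n_frames: int,
    window_centers: np.ndarray,
    w: int,
    nuisance: np.ndarray | None = None,
    load_conditions: Sequence[str] = ("0-back", "1-back", "2-back", "3-back"),
    nuisance_conditions: Sequence[str] = ("instruction",),
    convolve: bool = True,
    q: float = 0.05,
) -> TaskGlmResult:
    """Window-level GLM of topology values against the N-back block design.

    ``topo_values`` is windows x targets (targets are regions or profile
    bins).  Condition boxcars are HRF-convolved (optionally raw),
    averaged within each MTD window, and entered with an intercept,
    instruction/rest regressors and any supplied nuisance columns.  Two
    F contrasts are reported, FDR-controlled across targets:

    - main effect: mean of the 1-, 2- and 3-back betas versus 0-back;
    - load effect: linear parametric increase across the four loads.
    """
    y = np.atleast_2d(np.asarray(topo_values, dtype=float))
    n_win = len(window_centers)
    if y.shape[0] != n_win:
        raise ValueError("topo_values must have one row per window")
    conds = list(load_conditions) + [
        c for c in nuisance_conditions if c in design.conditions
    ]
    present = [c for c in load_conditions if c in design.conditions]
    if len(present) < len(load_conditions):
        raise ValueError(
            f"design lacks task blocks for conditions: "
            f"{sorted(set(load_conditions) - set(present))}"
        )
    xcond = _design_on_windows(design, n_frames, window_centers, w, convolve, conds)
    cols = list(conds) + ["intercept"]
    x = np.column_stack([xcond, np.ones(n_win)])
    if nuisance is not None:
        nuis = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuis.shape[0] != n_win:
            raise ValueError("nuisance must have one row per window")
        x = np.column_stack([x, nuis])
        cols += [f"nuisance{i}" for i in range(nuis.shape[1])]
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name a dependent column for the error message
        bad = []
        for j in range(x.shape[1]):
            keep = [i for i in range(x.shape[1]) if i != j]
            if np.linalg.matrix_rank(x[:, keep]) == rank:
                bad.append(cols[j])
        raise ValueError(f"rank-deficient design matrix; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    n_loads = len(load_conditions)
    c_main = np.zeros(x.shape[1])
    c_main[0] = -1.0
    c_main[1:n_loads] = 1.0 / (n_loads - 1)
    c_load = np.zeros(x.shape[1])
    loads = np.arange(n_loads, dtype=float)
    c_load[:n_loads] = loads - loads.mean()
    maps = []
    for cvec, name in ((c_main, "main effect"), (c_load, "load effect")):
        f, p = _contrast_f(x, y, beta, cvec)
        sig, thresh = fdr_bh(p, q=q)
        maps.append(
            StatMap(
                statistic=f,
                pvalues=p,
                significant=sig,
                q=q,
                fdr_threshold=thresh,
                name=name,
            )
        )
    return TaskGlmResult(
        betas=beta, columns=tuple(cols), f_main=maps[0], f_load=maps[1]
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def permutation_corr_test(
    x: np.ndarray, y: np.ndarray, n_perm: int = 5000, seed: int = 0
) -> tuple[float, float]:
    """Two-sided permutation test of the Pearson correlation.

    One vector is randomly permuted ``n_perm`` times; the p-value is
    (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length vectors of size >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    r_obs = _pearson(x, y)
    rng = np.random.default_rng(seed)
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    n = x.size
    perms = rng.permuted(np.tile(yc, (n_perm, 1)), axis=1)
    r_null = perms @ xc / n
    p = (1 + np.sum(np.abs(r_null) >= abs(r_obs) - 1e-12)) / (n_perm + 1)
    return r_obs, float(p)


def bootstrap_corr_ci(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 5:
        raise ValueError("x and y must be equal-length vectors of size >= 5")
    rng = np.random.default_rng(seed)
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    xs = x[idx]
    ys = y[idx]
    xs = xs - xs.mean(axis=1, keepdims=True)
    ys = ys - ys.mean(axis=1, keepdims=True)
    denom = np.sqrt((xs**2).sum(axis=1) * (ys**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (xs * ys).sum(axis=1) / denom, 0.0)
    alpha = 1 - level
    lo, hi = np.percentile(r, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def dunn_clark_z(
    r1: float,
    r2: float,
    n1: int,
    n2: int,
    r_cross: float | None = None,
) -> tuple[float, float]:
    """Fisher-z comparison of two correlations (Dunn & Clark form).

    ``r_cross`` is the correlation between the two Fisher-z estimates
    induced by shared measurement units; when omitted (or 0) the test
    reduces to the independent-samples z comparison.  Returns the z
    statistic and its two-sided p-value.
    """
    for r in (r1, r2):
        if not -1 < r < 1:
            raise ValueError("correlations must satisfy |r| < 1")
    if min(n1, n2) < 4:
        raise ValueError("need n >= 4 in both samples")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    v1, v2 = 1.0 / (n1 - 3), 1.0 / (n2 - 3)
    cov = 0.0
    if r_cross is not None:
        if not -1 <= r_cross <= 1:
            raise ValueError("r_cross must lie in [-1, 1]")
        cov = r_cross * np.sqrt(v1 * v2)
    var = v1 + v2 - 2 * cov
    if var <= 0:
        raise ValueError("degenerate variance in Dunn & Clark comparison")
    z = (z1 - z2) / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(p)
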