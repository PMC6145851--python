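"""Synthetic modular BOLD-like data with planted community structure.

The generator draws zero-mean Gaussian frames from a block-structured
correlation matrix whose between-module coupling switches with a latent
per-frame state.  That is the simplest process whose sliding-window
covariance reproduces the integration/segregation dynamics the network
pipeline measures: within-module coupling sets segregated structure,
raising between-module coupling moves occupancy toward high
participation (integration).

Default dimensions emulate the resting-state acquisition regime the
pipeline targets (375 regions, 216 frames at TR 2.2 s); tests and
examples use smaller instances of the same process.  Everything is a
pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ParcellatedTimeSeries, PupilSeries, TaskDesign
from .hrf import hrf_convolve

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_modular_bold",
    "generate_pupil",
    "generate_task_run",
    "generate_crossover_cohort",
]


def _default_module_sizes(n_regions: int, n_modules: int = 5) -> tuple[int, ...]:
    base = n_regions // n_modules
    sizes = [base] * n_modules
    for i in range(n_regions - base * n_modules):
        sizes[i] += 1
    return tuple(sizes)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the modular Gaussian generator.

    ``within_coupling`` and the values of ``between_coupling_by_state``
    are target correlations (the block correlation matrix has unit
    diagonal), so the sample correlations of a long run converge to them
    directly.  ``noise_sd`` adds optional white measurement noise on top
    of the structured signal (default 0: the unit-diagonal correlation
    model already contains unstructured variance).
    """

    n_regions: int = 375
    module_sizes: tuple[int, ...] | None = None
    tr: float = 2.2
    n_frames: int = 216
    within_coupling: float = 0.5
    between_coupling_by_state: Mapping[str, float] = field(
        default_factory=lambda: {"rest": 0.1}
    )
    state_sequence: tuple[str, ...] | None = None
    noise_sd: float = 0.0
    hrf_smoothing: bool = False
    seed: int = 0

    def __post_init__(self):
        sizes = self.module_sizes
        if sizes is None:
            sizes = _default_module_sizes(self.n_regions)
        sizes = tuple(int(s) for s in sizes)
        if sum(sizes) != self.n_regions:
            raise ValueError(
                f"module_sizes sum {sum(sizes)} != n_regions {self.n_regions}"
            )
        if not (0 <= self.within_coupling < 1):
            raise ValueError("within_coupling must lie in [0, 1)")
        object.__setattr__(self, "module_sizes", sizes)
        object.__setattr__(
            self, "between_coupling_by_state", dict(self.between_coupling_by_state)
        )
        if self.state_sequence is not None:
            seq = tuple(str(s) for s in self.state_sequence)
            if len(seq) != self.n_frames:
                raise ValueError("state_sequence length must equal n_frames")
            unknown = set(seq) - set(self.between_coupling_by_state)
            if unknown:
                raise ValueError(f"states without coupling value: {sorted(unknown)}")
            object.__setattr__(self, "state_sequence", seq)
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        # validate PSD of every state's target covariance at construction
        for state, b in self.between_coupling_by_state.items():
            cov = block_correlation(sizes, self.within_coupling, float(b))
            lo = np.linalg.eigvalsh(cov)[0]
            if lo < -1e-10:
                raise ValueError(
                    f"state {state!r}: target covariance not positive semidefinite "
                    f"(min eigenvalue {lo:.3g}); reduce |couplings|"
                )

    @property
    def planted_partition(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.module_sizes)), self.module_sizes)

    def resolved_states(self) -> tuple[str, ...]:
        if self.state_sequence is not None:
            return self.state_sequence
        state = next(iter(self.between_coupling_by_state))
        return (state,) * self.n_frames


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: module membership and the latent coupling path."""

    planted_partition: np.ndarray
    latent_integration: np.ndarray  # per-frame between-module coupling applied
    condition_labels: tuple[str, ...]  # per-frame state / block labels

    def __post_init__(self):
        part = np.asarray(self.planted_partition, dtype=int)
        lat = np.asarray(self.latent_integration, dtype=float)
        if len(self.condition_labels) != lat.shape[0]:
            raise ValueError("condition_labels and latent_integration disagree")
        object.__setattr__(self, "planted_partition", part)
        object.__setattr__(self, "latent_integration", lat)


def block_correlation(
    module_sizes: Sequence[int], within: float, between: float
) -> np.ndarray:
    """Unit-diagonal block correlation matrix for one latent state."""
    membership = np.repeat(np.arange(len(module_sizes)), module_sizes)
    same = membership[:, None] == membership[None, :]
    cov = np.where(same, within, between)
    np.fill_diagonal(cov, 1.0)
    return cov


def _region_labels(n: int) -> tuple[str, ...]:
    return tuple(f"roi{i:03d}" for i in range(n))


def psd_between_range(
    module_sizes: Sequence[int], within: float, margin: float = 0.01
) -> tuple[float, float]:
    """PSD-valid interval of the between-module coupling (by bisection).

    The block correlation model is only a valid covariance for between
    couplings in a within/size-dependent interval; couplings outside it
    have no generative meaning.  ``margin`` keeps a numerical buffer to
    the exact boundary.
    """

    def min_eig(b: float) -> float:
        return float(
            np.linalg.eigvalsh(block_correlation(module_sizes, within, b))[0]
        )

    def bisect(lo: float, hi: float) -> float:
        # invariant: min_eig(hi) >= 0 > min_eig(lo)
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            if min_eig(mid) >= 0:
                hi = mid
            else:
                lo = mid
        return hi

    lower = bisect(-1.0, 0.0) if min_eig(-1.0) < 0 else -1.0
    upper = within  # b = within removes block structure but stays PSD
    return lower + margin, upper - margin


def generate_modular_bold(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[ParcellatedTimeSeries, GroundTruth]:
    """Draw one run from the state-switching block-correlation model.

    Frames are independent draws from N(0, C_state(t)); state changes
    happen on frame boundaries.  With ``hrf_smoothing`` the series is
    additionally convolved with the canonical double-gamma kernel, which
    induces BOLD-like temporal autocorrelation but leaves the spatial
    block structure intact.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    states = spec.resolved_states()
    chols = {
        s: np.linalg.cholesky(
            block_correlation(spec.module_sizes, spec.within_coupling, float(b))
            + 1e-12 * np.eye(spec.n_regions)
        )
        for s, b in spec.between_coupling_by_state.items()
    }
    z = rng.standard_normal((spec.n_frames, spec.n_regions))
    data = np.empty_like(z)
    for s, chol in chols.items():
        idx = [t for t, st in enumerate(states) if st == s]
        if idx:
            data[idx] = z[idx] @ chol.T
    if spec.noise_sd > 0:
        data = data + spec.noise_sd * rng.standard_normal(data.shape)
    if spec.hrf_smoothing:
        data = hrf_convolve(data, spec.tr)
    ts = ParcellatedTimeSeries(
        data=data,
        tr=spec.tr,
        region_labels=_region_labels(spec.n_regions),
        run_meta={"source": "synthetic"},
    )
    latent = np.array(
        [float(spec.between_coupling_by_state[s]) for s in states]
    )
    truth = GroundTruth(
        planted_partition=spec.planted_partition,
        latent_integration=latent,
        condition_labels=states,
    )
    return ts, truth


def generate_pupil(
    latent_integration: np.ndarray,
    tr: float,
    lag: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    smooth_frames: int = 1,
) -> PupilSeries:
    """Pupil trace coupled to the latent integration path, at frame rate.

    The latent series is delayed by ``lag`` seconds (rounded to frames),
    boxcar-smoothed over ``smooth_frames`` frames (1 = no smoothing),
    perturbed with Gaussian noise of sd ``noise_sd`` (in units of the
    latent series) and z-scored.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    x = np.asarray(latent_integration, dtype=float)
    shift = int(round(lag / tr))
    lagged = np.concatenate([np.full(shift, x[0]), x])[: x.shape[0]]
    if smooth_frames > 1:
        k = np.ones(smooth_frames) / smooth_frames
        lagged = np.convolve(lagged, k, mode="same")
    rng = np.random.default_rng(seed)
    trace = lagged + noise_sd * rng.standard_normal(lagged.shape)
    sd = trace.std()
    z = (trace - trace.mean()) / sd if sd > 0 else trace - trace.mean()
    return PupilSeries(samples=z, rate=1.0 / tr, z_scored=True)


def generate_task_run(
    spec: SyntheticSpec,
    design: TaskDesign,
    load_integration_profile: Mapping[str, float],
    baseline_state: str = "rest",
    seed: int | None = None,
) -> tuple[ParcellatedTimeSeries, GroundTruth]:
    """One task run whose between-module coupling follows the block design.

    ``load_integration_profile`` maps a block condition (e.g. "2-back")
    to the between-module coupling applied during its frames; inverted-U
    load profiles are expressed directly through these values.  Frames
    outside every block use the baseline state's coupling from the spec.
    """
    if baseline_state not in spec.between_coupling_by_state:
        raise ValueError(f"baseline state {baseline_state!r} missing from spec")
    frame_cond = design.condition_per_frame(spec.n_frames, baseline=baseline_state)
    coupling_map = dict(spec.between_coupling_by_state)
    for cond, b in load_integration_profile.items():
        coupling_map[str(cond)] = float(b)
    missing = {c for c in frame_cond} - set(coupling_map)
    if missing:
        raise ValueError(f"no coupling for conditions: {sorted(missing)}")
    from dataclasses import replace

    run_spec = replace(
        spec,
        between_coupling_by_state=coupling_map,
        state_sequence=tuple(frame_cond),
    )
    return generate_modular_bold(run_spec, seed=seed)


def generate_crossover_cohort(
    n_subjects: int,
    spec: SyntheticSpec,
    drug_integration_shift: float,
    seed: int = 0,
    subject_sd: float = 0.03,
) -> tuple[list[dict], pd.DataFrame]:
    """Simulate a pre/post x drug/placebo crossover cohort.

    Each subject contributes four runs.  Subject heterogeneity is a
    Gaussian random intercept (sd ``subject_sd``) on the between-module
    coupling; the post-drug run's coupling is additionally shifted by
    ``drug_integration_shift`` (negative = segregating drug).  Couplings
    are clipped into the PSD-safe range of the block model.

    Returns the list of run records (ts, truth, labels) and a tidy run
    table.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    from dataclasses import replace

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    run_seeds = iter(int(s) % (2**31) for s in ss.generate_state(4 * n_subjects + 8))
    base_b = float(next(iter(spec.between_coupling_by_state.values())))
    lo, hi = psd_between_range(spec.module_sizes, spec.within_coupling)
    hi = min(hi, max(0.0, spec.within_coupling - 0.05))
    runs: list[dict] = []
    rows = []
    for subj in range(n_subjects):
        intercept = subject_sd * rng.standard_normal()
        for session in ("placebo", "drug"):
            for phase in ("pre", "post"):
                b = base_b + intercept
                if session == "drug" and phase == "post":
                    b += drug_integration_shift
                b = float(np.clip(b, lo, hi))
                run_spec = replace(
                    spec, between_coupling_by_state={"rest": b}, state_sequence=None
                )
                ts, truth = generate_modular_bold(run_spec, seed=next(run_seeds))
                ts = ParcellatedTimeSeries(
                    data=ts.data,
                    tr=ts.tr,
                    region_labels=ts.region_labels,
                    run_meta={
                        "subject": f"sub{subj:02d}",
                        "session": session,
                        "phase": phase,
                    },
                )
                runs.append(
                    {
                        "subject": f"sub{subj:02d}",
                        "session": session,
                        "phase": phase,
                        "between_coupling": b,
                        "ts": ts,
                        "truth": truth,
                    }
                )
                rows.append(
                    {
                        "subject": f"sub{subj:02d}",
                        "session": session,
                        "phase": phase,
                        "between_coupling": b,
                    }
                )
    return runs, pd.DataFrame(rows)
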