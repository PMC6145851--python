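"""Shared data containers for parcellated BOLD, motion, pupil and task-design data.

All containers are thin, validated wrappers around numpy arrays.  The
frames x regions orientation is used throughout: one row per acquired
volume, one column per region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ParcellatedTimeSeries:
    """Region-averaged BOLD series: ``data`` is frames x regions.

    Parameters
    ----------
    data
        Real matrix, one column per region, no missing values.
    tr
        Repetition time in seconds.
    region_labels
        Unique, ordered region names (one per column).
    run_meta
        Free-form subject/session/condition annotations.
    """

    data: np.ndarray
    tr: float
    region_labels: tuple[str, ...]
    run_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be a 2-D frames x regions matrix")
        if data.shape[1] < 2:
            raise ValueError("need at least 2 regions")
        if not np.all(np.isfinite(data)):
            raise ValueError("data contains non-finite values")
        labels = tuple(str(x) for x in self.region_labels)
        if len(labels) != data.shape[1]:
            raise ValueError(
                f"{len(labels)} labels for {data.shape[1]} regions"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("region_labels must be unique")
        if not (self.tr > 0):
            raise ValueError("tr must be positive (seconds)")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "region_labels", labels)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "ParcellatedTimeSeries":
        """Copy of this series with ``data`` replaced (same TR/labels/meta)."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass(frozen=True)
class MotionParams:
    """Rigid-body realignment parameters: frames x 6.

    Columns are three translations (mm) followed by three rotations
    (radians), the conventional realignment-parameter dialect.
    """

    params: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.params, dtype=float)
        if p.ndim != 2 or p.shape[1] != 6:
            raise ValueError("motion parameters must be frames x 6")
        if not np.all(np.isfinite(p)):
            raise ValueError("motion parameters contain non-finite values")
        object.__setattr__(self, "params", p)

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]


@dataclass(frozen=True)
class PupilSeries:
    """Pupil-diameter trace with sampling rate and interpolation mask."""

    samples: np.ndarray
    rate: float
    interpolated_mask: np.ndarray | None = None
    z_scored: bool = False

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1:
            raise ValueError("samples must be a 1-D vector")
        if self.interpolated_mask is None:
            mask = np.zeros(s.shape, dtype=bool)
        else:
            mask = np.asarray(self.interpolated_mask, dtype=bool)
        if mask.shape != s.shape:
            raise ValueError("interpolated_mask length must match samples")
        if not (self.rate > 0):
            raise ValueError("rate must be positive (Hz)")
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "interpolated_mask", mask)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class TaskDesign:
    """Block design: (condition, onset s, duration s) triples on a TR grid.

    Conditions follow the N-back vocabulary ("0-back" ... "3-back",
    "instruction", "rest") but any string is accepted; blocks must not
    overlap and must start inside the run.
    """

    blocks: tuple[tuple[str, float, float], ...]
    tr: float

    def __post_init__(self):
        blocks = tuple(
            (str(c), float(o), float(d)) for c, o, d in self.blocks
        )
        if not (self.tr > 0):
            raise ValueError("tr must be positive (seconds)")
        for c, o, d in blocks:
            if o < 0 or d <= 0:
                raise ValueError(f"block {c!r}: onset must be >= 0, duration > 0")
        ordered = sorted(blocks, key=lambda b: b[1])
        for (c1, o1, d1), (c2, o2, d2) in zip(ordered, ordered[1:]):
            if o1 + d1 > o2 + 1e-9:
                raise ValueError(
                    f"blocks {c1!r} (onset {o1}) and {c2!r} (onset {o2}) overlap"
                )
        object.__setattr__(self, "blocks", blocks)

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(sorted({c for c, _, _ in self.blocks}))

    def condition_per_frame(self, n_frames: int, baseline: str = "rest") -> np.ndarray:
        """Label each of ``n_frames`` frames with its block condition.

        Frames outside every block get ``baseline``.  A frame belongs to a
        block when its acquisition onset ``t = frame * tr`` falls in
        [onset, onset + duration).
        """
        t = np.arange(n_frames) * self.tr
        labels = np.array([baseline] * n_frames, dtype=object)
        for c, o, d in self.blocks:
            if o >= n_frames * self.tr:
                raise ValueError(f"block {c!r} at onset {o}s lies outside the run")
            labels[(t >= o) & (t < o + d)] = c
        return labels


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def check_labels_match(a: Sequence[str], b: Sequence[str]) -> None:
    if tuple(a) != tuple(b):
        raise ValueError("region label mismatch between inputs")
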