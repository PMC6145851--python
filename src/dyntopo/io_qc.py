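"""I/O and quality control for parcellated series, motion and pupil data.

Covers the temporal preprocessing applied before network analysis:
band-pass filtering (0.01-0.125 Hz), framewise-displacement / DVARS
frame flagging, and pupil preprocessing (shape-preserving interpolation,
5 Hz low-pass, z-scoring, resampling to the fMRI frame grid).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, filtfilt

from .core import MotionParams, ParcellatedTimeSeries, PupilSeries

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_motion_params",
    "read_pupil",
    "bandpass_filter",
    "compute_fd",
    "compute_dvars",
    "flag_frames",
    "preprocess_pupil",
    "qc_report",
]


def read_timeseries(path, tr: float, **meta) -> ParcellatedTimeSeries:
    """Load a TSV matrix (header row of region labels, one row per frame)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"{path}: duplicate region labels {dupes}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    labels = [str(c) for c in df.columns]
    bad = df.isna()
    if bad.any().any():
        r = int(bad.any(axis=1).idxmax())
        c = bad.columns[bad.any(axis=0)][0]
        raise ValueError(f"{path}: missing/non-numeric cell at row {r}, column {c!r}")
    for c in df.columns:
        if not np.issubdtype(df[c].dtype, np.number):
            try:
                df[c] = pd.to_numeric(df[c])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: non-numeric column {c!r}: {exc}") from exc
    return ParcellatedTimeSeries(
        data=df.to_numpy(dtype=float), tr=tr, region_labels=labels, run_meta=meta
    )


def write_timeseries(ts: ParcellatedTimeSeries, path) -> None:
    """Write to TSV at full repr precision (lossless round trip)."""
    df = pd.DataFrame(ts.data, columns=list(ts.region_labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_motion_params(path) -> MotionParams:
    """Read 6-column whitespace-delimited realignment parameters."""
    arr = np.loadtxt(path)
    return MotionParams(params=np.atleast_2d(arr))


def read_pupil(path) -> PupilSeries:
    """Read a 2/3-column (time s, diameter[, artifact]) delimited trace."""
    df = pd.read_csv(path, sep=None, engine="python")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    rate = 1.0 / float(np.median(np.diff(t)))
    mask = None
    if df.shape[1] >= 3:
        mask = df.iloc[:, 2].to_numpy(dtype=float) > 0
    return PupilSeries(
        samples=df.iloc[:, 1].to_numpy(dtype=float),
        rate=rate,
        interpolated_mask=mask,
    )


def _butter_filtfilt(x: np.ndarray, b, a) -> np.ndarray:
    return filtfilt(b, a, x, axis=0)


def bandpass_filter(
    ts: ParcellatedTimeSeries, low: float = 0.01, high: float = 0.125, order: int = 4
) -> ParcellatedTimeSeries:
    """Zero-phase Butterworth band-pass, per region.

    Defaults to the 0.01-0.125 Hz band conventionally applied before
    time-resolved connectivity.  Forward-backward filtering keeps the
    windowed statistics phase-aligned with the raw series.
    """
    nyq = 0.5 / ts.tr
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq:.4g} Hz at TR {ts.tr}")
    b, a = butter(order, [low / nyq, high / nyq], btype="band")
    return ts.with_data(_butter_filtfilt(ts.data, b, a))


def compute_fd(mp: MotionParams, head_radius: float = 50.0) -> np.ndarray:
    """Framewise displacement (mm), Power convention.

    Sum of absolute backward differences of the six parameters, with the
    three rotations converted to arc length on a sphere of
    ``head_radius`` mm.  The first frame has FD 0 by convention.
    """
    p = mp.params
    if p.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    d = np.abs(np.diff(p, axis=0))
    d[:, 3:] *= head_radius
    fd = np.concatenate([[0.0], d.sum(axis=1)])
    return fd


def compute_dvars(ts: ParcellatedTimeSeries) -> np.ndarray:
    """DVARS as percent of the run's global mean signal.

    Root-mean-square (over regions) frame-to-frame signal change,
    expressed in % of the global mean absolute signal level so the
    conventional 2.5% threshold applies.  First frame is 0.
    """
    diff = np.diff(ts.data, axis=0)
    rms = np.sqrt(np.mean(diff**2, axis=1))
    scale = np.mean(np.abs(ts.data))
    if scale == 0:
        return np.zeros(ts.n_frames)
    return np.concatenate([[0.0], 100.0 * rms / scale])


def flag_frames(
    fd: np.ndarray,
    dvars: np.ndarray,
    fd_thresh: float = 0.25,
    dvars_thresh: float = 2.5,
    exclusion_fraction: float = 0.10,
) -> tuple[np.ndarray, bool]:
    """Flag frames with FD > 0.25 mm or DVARS > 2.5%.

    Returns the boolean mask and a run-level exclusion flag that is true
    when more than ``exclusion_fraction`` of frames are flagged.
    """
    fd = np.asarray(fd, dtype=float)
    dvars = np.asarray(dvars, dtype=float)
    if fd.shape != dvars.shape:
        raise ValueError("fd and dvars must have the same length")
    mask = (fd > fd_thresh) | (dvars > dvars_thresh)
    return mask, bool(mask.mean() > exclusion_fraction)


def preprocess_pupil(
    p: PupilSeries,
    artifact_mask: np.ndarray | None = None,
    tr: float = 2.2,
    lowpass_hz: float = 5.0,
    exclusion_fraction: float = 0.5,
) -> tuple[PupilSeries, bool]:
    """Interpolate artifacts, low-pass at 5 Hz, z-score, resample to frames.

    Artifact spans are replaced with shape-preserving piecewise-cubic
    (PCHIP) interpolation, the trace is zero-phase low-pass filtered,
    z-scored, and averaged within each TR to give one value per fMRI
    frame.  The exclusion flag is true when >= ``exclusion_fraction`` of
    samples were interpolated.
    """
    if p.rate <= 10:
        raise ValueError("pupil sampling rate must exceed 10 Hz")
    x = p.samples.copy()
    mask = (
        np.asarray(artifact_mask, dtype=bool)
        if artifact_mask is not None
        else p.interpolated_mask.copy()
    )
    if mask.shape != x.shape:
        raise ValueError("artifact mask length must match samples")
    if mask.all():
        raise ValueError("artifact span covers the entire trace")
    if mask.any():
        good = ~mask
        interp = PchipInterpolator(np.flatnonzero(good), x[good], extrapolate=True)
        x[mask] = interp(np.flatnonzero(mask))
    excluded = bool(mask.mean() >= exclusion_fraction)
    nyq = 0.5 * p.rate
    b, a = butter(4, lowpass_hz / nyq, btype="low")
    x = filtfilt(b, a, x)
    sd = x.std()
    x = (x - x.mean()) / sd if sd > 0 else x - x.mean()
    # average samples within each TR bin
    samples_per_frame = p.rate * tr
    n_frames = int(np.floor(x.shape[0] / samples_per_frame))
    if n_frames < 1:
        raise ValueError("trace shorter than one TR")
    edges = (np.arange(n_frames + 1) * samples_per_frame).round().astype(int)
    frames = np.array([x[edges[i] : edges[i + 1]].mean() for i in range(n_frames)])
    out = PupilSeries(
        samples=frames,
        rate=1.0 / tr,
        interpolated_mask=None,
        z_scored=True,
    )
    return out, excluded


def qc_report(
    fd: np.ndarray, dvars: np.ndarray, mask: np.ndarray, excluded: bool, path=None
) -> dict:
    """Summarise motion QC as a JSON-serialisable report (optionally written)."""
    rep = {
        "n_frames": int(len(fd)),
        "mean_fd_mm": float(np.mean(fd)),
        "max_fd_mm": float(np.max(fd)),
        "mean_dvars_pct": float(np.mean(dvars)),
        "n_flagged": int(np.sum(mask)),
        "fraction_flagged": float(np.mean(mask)),
        "run_excluded": bool(excluded),
    }
    if path is not None:
        Path(path).write_text(json.dumps(rep, indent=2, sort_keys=True))
    return rep
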