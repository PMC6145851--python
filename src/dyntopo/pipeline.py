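"""End-to-end orchestration: simulate -> QC -> MTD -> communities -> topology -> stats.

A :class:`RunConfig` fans one master seed out to every stochastic stage
and pins every analysis parameter, so an identical config reproduces
every output byte for byte.  Intermediate artifacts (per-run topology,
partitions, profiles) are always persisted so the statistical stages can
be re-run from disk.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import consensus_partition, run_windows, SignedGraph
from .core import ParcellatedTimeSeries, TaskDesign, spawn_seeds
from .io_qc import bandpass_filter
from .mtd import mtd_coupling
from .nulls import fit_var, kurtosis_test, simulate_var
from .stats import (
    CohortProfiles,
    bin_anova_2x2,
    bootstrap_corr_ci,
    dunn_clark_z,
    permutation_corr_test,
    pupil_to_windows,
    pupil_topology_correlation,
    task_glm,
)
from .synthetic import (
    SyntheticSpec,
    generate_crossover_cohort,
    generate_pupil,
    generate_task_run,
)
from .topology import (
    cartographic_profile,
    match_labels,
    regional_flexibility,
    topology_series,
)

__all__ = [
    "RunConfig",
    "run_rest_pipeline",
    "run_task_pipeline",
    "compare_rest_task",
    "cohort_bin_profiles",
]


def cohort_bin_profiles(
    n_subjects: int,
    spec: SyntheticSpec,
    drug_integration_shift: float,
    seed: int,
    bins_b: int = 20,
    bins_w: int = 20,
    window: int = 15,
    gamma: float = 1.1,
    consensus_reps: int = 16,
    subject_sd: float = 0.03,
    bandpass: tuple[float, float] = (0.01, 0.125),
) -> tuple[CohortProfiles, "np.ndarray"]:
    """Cartographic-profile cohort via the reduced per-run pipeline.

    Every run is band-passed, MTD-windowed, and profiled against the
    consensus partition of its own time-averaged coupling matrix (rather
    than per-window consensus) — the reduced pipeline used for
    cohort-scale power and calibration simulations, where per-window
    community detection is not the quantity under test.  Returns the
    cohort profiles plus the B bin centres.
    """
    runs, _ = generate_crossover_cohort(
        n_subjects, spec, drug_integration_shift, seed=seed, subject_sd=subject_sd
    )
    session_idx = {"placebo": 0, "drug": 1}
    phase_idx = {"pre": 0, "post": 1}
    subjects = sorted({r["subject"] for r in runs})
    occ = np.full((n_subjects, 2, 2, bins_b, bins_w), np.nan)
    b_centers = None
    for rec in runs:
        filtered = bandpass_filter(rec["ts"], *bandpass)
        tensor = mtd_coupling(filtered, w=window)
        mean_graph = SignedGraph(tensor.coupling.mean(axis=2), gamma=gamma)
        part, _ = consensus_partition(
            mean_graph, n_reps=consensus_reps, seed=rec["truth"].planted_partition.size
        )
        topo = topology_series(tensor, part)
        prof = cartographic_profile(topo, n_bins_b=bins_b, n_bins_w=bins_w)
        si = subjects.index(rec["subject"])
        occ[si, session_idx[rec["session"]], phase_idx[rec["phase"]]] = prof.occupancy
        b_centers = prof.b_centers
    return CohortProfiles(occupancy=occ, subjects=tuple(subjects)), b_centers


@dataclass(frozen=True)
class RunConfig:
    """All knobs of an end-to-end run; serialises losslessly to JSON."""

    tr: float
    n_regions: int = 40
    n_frames: int = 120
    module_sizes: tuple[int, ...] | None = None
    within_coupling: float = 0.6
    between_coupling: float = 0.15
    noise_sd: float = 0.0
    n_subjects: int = 4
    drug_integration_shift: float = -0.1
    subject_sd: float = 0.03
    bandpass: tuple[float, float] = (0.01, 0.125)
    window: int = 15
    gamma: float = 1.1
    consensus_reps: int = 500
    bins_b: int = 100
    bins_w: int = 100
    w_range: tuple[float, float] = (-5.0, 5.0)
    flex_normalization: str = "switch_fraction"
    var_order: int = 6
    n_surrogates: int = 2500
    q: float = 0.05
    n_perm: int = 5000
    n_boot: int = 1000
    pupil_lag_s: float = 2.0
    pupil_noise_sd: float = 0.5
    task_blocks: tuple[tuple[str, float, float], ...] = ()
    load_profile: dict = field(default_factory=dict)
    drug_task_boost: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not isinstance(self.tr, (int, float)) or not self.tr > 0:
            raise ValueError("config requires a positive tr (seconds)")
        if self.window < 2:
            raise ValueError("window must be >= 2 frames")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        if "tr" not in payload:
            raise ValueError("config missing required field 'tr'")
        allowed = set(cls.__dataclass_fields__)
        unknown = set(payload) - allowed
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("module_sizes", "bandpass", "w_range"):
            if payload.get(key) is not None:
                payload[key] = tuple(payload[key])
        if "task_blocks" in payload:
            payload["task_blocks"] = tuple(tuple(b) for b in payload["task_blocks"])
        return cls(**payload)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def synthetic_spec(self) -> SyntheticSpec:
        return SyntheticSpec(
            n_regions=self.n_regions,
            module_sizes=self.module_sizes,
            tr=self.tr,
            n_frames=self.n_frames,
            within_coupling=self.within_coupling,
            between_coupling_by_state={"rest": self.between_coupling},
            noise_sd=self.noise_sd,
            seed=self.seed,
        )


def _write_tsv(arr: np.ndarray, path: Path, columns=None) -> None:
    df = pd.DataFrame(np.atleast_2d(arr), columns=columns)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _log(msg: str) -> None:
    print(f"[dyntopo] {msg}", file=sys.stderr)


def _analyse_run(ts: ParcellatedTimeSeries, cfg: RunConfig, outdir: Path) -> dict:
    """Single-run network analysis; writes artifacts, returns summaries."""
    outdir.mkdir(parents=True, exist_ok=True)
    filtered = bandpass_filter(ts, *cfg.bandpass)
    tensor = mtd_coupling(filtered, w=cfg.window)
    parts = run_windows(
        tensor, gamma=cfg.gamma, n_reps=cfg.consensus_reps, seed=cfg.seed
    )
    topo = topology_series(tensor, parts)
    matched = match_labels(parts)
    flex = regional_flexibility(matched, normalization=cfg.flex_normalization)
    profile = cartographic_profile(
        topo, n_bins_b=cfg.bins_b, n_bins_w=cfg.bins_w, w_range=cfg.w_range
    )
    labels = list(ts.region_labels)
    _write_tsv(parts.assignments, outdir / "partitions.tsv", columns=labels)
    _write_tsv(
        np.column_stack([parts.modularity, parts.n_modules]),
        outdir / "q_per_window.tsv",
        columns=["Q_T", "n_modules"],
    )
    _write_tsv(topo.B, outdir / "participation.tsv", columns=labels)
    _write_tsv(topo.W, outdir / "module_degree_z.tsv", columns=labels)
    _write_tsv(topo.mean_B[None, :].T, outdir / "mean_b.tsv", columns=["mean_B"])
    _write_tsv(flex.values[None, :], outdir / "flexibility.tsv", columns=labels)
    _write_tsv(profile.occupancy, outdir / "profile.tsv")
    return {
        "tensor": tensor,
        "topo": topo,
        "profile": profile,
        "flexibility": flex.values,
        "mean_n_modules": float(parts.n_modules.mean()),
        "filtered": filtered,
    }


def _provenance(cfg: RunConfig, stage_seeds: dict, outdir: Path) -> None:
    rec = {
        "config_digest": cfg.digest(),
        "software_version": __version__,
        "stage_seeds": stage_seeds,
    }
    (outdir / "provenance.json").write_text(json.dumps(rec, indent=2, sort_keys=True))


def run_rest_pipeline(cfg: RunConfig, outdir) -> Path:
    """Full resting-state analysis of a synthetic crossover cohort.

    Stages: cohort simulation, band-pass, MTD, per-window consensus
    communities, cartography, flexibility, per-bin 2x2 crossover ANOVA,
    VAR-surrogate kurtosis test, and pupil-topology correlation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = spawn_seeds(cfg.seed, 6)
    stage_seeds = {
        "cohort": seeds[0],
        "nulls": seeds[1],
        "pupil": seeds[2],
    }
    spec = cfg.synthetic_spec()
    _log("stage simulate: generating crossover cohort")
    runs, table = generate_crossover_cohort(
        cfg.n_subjects,
        spec,
        cfg.drug_integration_shift,
        seed=seeds[0],
        subject_sd=cfg.subject_sd,
    )
    table.to_csv(outdir / "runs.tsv", sep="\t", index=False)
    cfg.to_json(outdir / "config.json")

    session_idx = {"placebo": 0, "drug": 1}
    phase_idx = {"pre": 0, "post": 1}
    occ = np.full(
        (cfg.n_subjects, 2, 2, cfg.bins_b, cfg.bins_w), np.nan
    )
    subjects = sorted({r["subject"] for r in runs})
    pre_placebo_runs = []
    observed_stats = []
    pupil_windowed = []
    bin_series = []
    for rec in runs:
        tag = f"{rec['subject']}_{rec['session']}_{rec['phase']}"
        _log(f"stage analyse: {tag}")
        res = _analyse_run(rec["ts"], cfg, outdir / "runs" / tag)
        si = subjects.index(rec["subject"])
        occ[si, session_idx[rec["session"]], phase_idx[rec["phase"]]] = (
            res["profile"].occupancy
        )
        if rec["session"] == "placebo" and rec["phase"] == "pre":
            # the VAR null is fit on the unfiltered series; its surrogates are
            # band-passed like the data before re-entering the pipeline
            pre_placebo_runs.append(rec["ts"])
            observed_stats.append(res["topo"].mean_B)
        # pupil analysis on the post-drug run, where latent integration moves
        if rec["session"] == "drug" and rec["phase"] == "post":
            pup = generate_pupil(
                rec["truth"].latent_integration,
                tr=cfg.tr,
                lag=cfg.pupil_lag_s,
                noise_sd=cfg.pupil_noise_sd,
                seed=seeds[2] + si,
            )
            pw = pupil_to_windows(
                pup.samples, res["tensor"].window_centers, cfg.window
            )
            pupil_windowed.append(pw)
            bin_series.append(res["topo"].B)  # windows x regions

    _log("stage anova: per-bin 2x2 crossover interaction")
    profiles = CohortProfiles(occupancy=occ, subjects=tuple(subjects))
    amap = bin_anova_2x2(profiles, q=cfg.q)
    gdir = outdir / "group"
    gdir.mkdir(exist_ok=True)
    _write_tsv(amap.statistic, gdir / "anova_interaction_f.tsv")
    _write_tsv(amap.pvalues, gdir / "anova_interaction_p.tsv")
    _write_tsv(amap.significant.astype(int), gdir / "anova_significant.tsv")

    _log("stage nulls: VAR surrogates + kurtosis test")
    model = fit_var(pre_placebo_runs, order=cfg.var_order)
    surrogates = simulate_var(
        model, n_frames=cfg.n_frames, n_surrogates=cfg.n_surrogates, seed=seeds[1]
    )
    # reduced surrogate pipeline: per-window participation against the
    # consensus partition of the run's time-averaged coupling matrix
    ref_tensor = mtd_coupling(
        bandpass_filter(pre_placebo_runs[0], *cfg.bandpass), w=cfg.window
    )
    ref_graph = SignedGraph(ref_tensor.coupling.mean(axis=2), gamma=cfg.gamma)
    ref_part, _ = consensus_partition(
        ref_graph, n_reps=max(10, cfg.consensus_reps // 10), seed=seeds[1]
    )

    def surrogate_mean_b(arr: np.ndarray) -> np.ndarray:
        ts = ParcellatedTimeSeries(
            data=arr, tr=cfg.tr, region_labels=pre_placebo_runs[0].region_labels
        )
        tens = mtd_coupling(bandpass_filter(ts, *cfg.bandpass), w=cfg.window)
        return topology_series(tens, ref_part).mean_B

    null_series = [surrogate_mean_b(s) for s in surrogates]
    results = {}
    for variant in ("diff", "level"):
        res = kurtosis_test(
            np.mean(observed_stats, axis=0), null_series, variant=variant
        )
        results[variant] = {
            "observed_kurtosis": res.observed,
            "null_95th_percentile": res.percentile_95,
            "significant": res.significant,
        }
    (outdir / "null_kurtosis.json").write_text(
        json.dumps(results, indent=2, sort_keys=True)
    )

    _log("stage pupil: per-bin Spearman + group test")
    rho, pmap = pupil_topology_correlation(
        pupil_windowed, bin_series, tr=cfg.tr, q=cfg.q
    )
    pdir = outdir / "pupil"
    pdir.mkdir(exist_ok=True)
    _write_tsv(
        np.column_stack(pupil_windowed),
        pdir / "windowed_pupil.tsv",
        columns=subjects,
    )
    _write_tsv(rho.mean(axis=0)[None, :], pdir / "mean_rho_per_region.tsv")
    _write_tsv(pmap.pvalues[None, :], pdir / "group_p_per_region.tsv")
    _provenance(cfg, stage_seeds, outdir)
    _log("rest pipeline complete")
    return outdir


def run_task_pipeline(cfg: RunConfig, outdir) -> Path:
    """Task-based analysis: N-back cohort, topology GLM, flexibility.

    Each subject contributes a placebo and a drug session; the drug
    session's per-load integration is raised by ``drug_task_boost``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not cfg.task_blocks:
        raise ValueError("task pipeline requires a design with task blocks")
    design = TaskDesign(blocks=cfg.task_blocks, tr=cfg.tr)
    load_conditions = ("0-back", "1-back", "2-back", "3-back")
    missing = [c for c in load_conditions if c not in design.conditions]
    if missing:
        raise ValueError(f"design lacks blocks for conditions: {missing}")
    seeds = spawn_seeds(cfg.seed, 2 * cfg.n_subjects + 1)
    spec = cfg.synthetic_spec()
    cfg.to_json(outdir / "config.json")
    per_session_betas: dict[str, list[np.ndarray]] = {"placebo": [], "drug": []}
    per_session_flex: dict[str, list[np.ndarray]] = {"placebo": [], "drug": []}
    per_session_meanb: dict[str, list[np.ndarray]] = {"placebo": [], "drug": []}
    k = 0
    for si in range(cfg.n_subjects):
        for session in ("placebo", "drug"):
            boost = cfg.drug_task_boost if session == "drug" else 0.0
            profile = {
                c: float(np.clip(v + boost, 0.0, spec.within_coupling - 0.05))
                for c, v in cfg.load_profile.items()
            }
            ts, truth = generate_task_run(
                spec, design, profile, seed=seeds[k]
            )
            k += 1
            tag = f"sub{si:02d}_{session}"
            _log(f"stage analyse: {tag}")
            res = _analyse_run(ts, cfg, outdir / "runs" / tag)
            glm = task_glm(
                res["topo"].B,
                design,
                n_frames=cfg.n_frames,
                window_centers=res["tensor"].window_centers,
                w=cfg.window,
                q=cfg.q,
            )
            rdir = outdir / "runs" / tag
            _write_tsv(glm.betas, rdir / "glm_betas.tsv")
            _write_tsv(glm.f_main.statistic[None, :], rdir / "f_main.tsv")
            _write_tsv(glm.f_load.statistic[None, :], rdir / "f_load.tsv")
            per_session_betas[session].append(glm.betas[:4])
            per_session_flex[session].append(res["flexibility"])
            per_session_meanb[session].append(res["topo"].mean_B)
    gdir = outdir / "group"
    gdir.mkdir(exist_ok=True)
    summary = {}
    for session in ("placebo", "drug"):
        betas = np.mean(per_session_betas[session], axis=0)  # 4 x regions
        _write_tsv(betas, gdir / f"load_betas_{session}.tsv")
        summary[session] = {
            "mean_B_per_load": [float(b) for b in betas.mean(axis=1)]
        }
    # drug-vs-placebo contrast on the main effect of task per region
    main_effect = {
        s: np.mean(
            [b[1:].mean(axis=0) - b[0] for b in per_session_betas[s]], axis=0
        )
        for s in ("placebo", "drug")
    }
    effect_map = main_effect["drug"] - main_effect["placebo"]
    _write_tsv(effect_map[None, :], gdir / "main_effect_drug_minus_placebo.tsv")
    flex_effect = np.mean(per_session_flex["drug"], axis=0) - np.mean(
        per_session_flex["placebo"], axis=0
    )
    _write_tsv(flex_effect[None, :], gdir / "flexibility_drug_minus_placebo.tsv")
    (gdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _provenance(cfg, {"cohort": seeds[0]}, outdir)
    _log("task pipeline complete")
    return outdir


def rerun_anova(rest_dir, out_path=None) -> "np.ndarray":
    """Re-run the per-bin crossover ANOVA from persisted rest-pipeline outputs."""
    rest_dir = Path(rest_dir)
    cfg = RunConfig.from_json(rest_dir / "config.json")
    runs = pd.read_csv(rest_dir / "runs.tsv", sep="\t")
    session_idx = {"placebo": 0, "drug": 1}
    phase_idx = {"pre": 0, "post": 1}
    subjects = sorted(runs.subject.unique())
    occ = np.full((len(subjects), 2, 2, cfg.bins_b, cfg.bins_w), np.nan)
    for _, row in runs.iterrows():
        tag = f"{row.subject}_{row.session}_{row.phase}"
        prof = pd.read_csv(rest_dir / "runs" / tag / "profile.tsv", sep="\t").to_numpy()
        occ[subjects.index(row.subject), session_idx[row.session], phase_idx[row.phase]] = prof
    amap = bin_anova_2x2(
        CohortProfiles(occupancy=occ, subjects=tuple(subjects)), q=cfg.q
    )
    if out_path is not None:
        _write_tsv(amap.statistic, Path(out_path))
    return amap


def rerun_pupil(rest_dir, out_path=None):
    """Re-run the pupil-topology group test from persisted artifacts."""
    rest_dir = Path(rest_dir)
    cfg = RunConfig.from_json(rest_dir / "config.json")
    pup = pd.read_csv(rest_dir / "pupil" / "windowed_pupil.tsv", sep="\t")
    runs = pd.read_csv(rest_dir / "runs.tsv", sep="\t")
    pupils, bins = [], []
    for subject in pup.columns:
        tag = f"{subject}_drug_post"
        b = pd.read_csv(rest_dir / "runs" / tag / "participation.tsv", sep="\t")
        pupils.append(pup[subject].to_numpy())
        bins.append(b.to_numpy())
    rho, pmap = pupil_topology_correlation(pupils, bins, tr=cfg.tr, q=cfg.q)
    if out_path is not None:
        _write_tsv(pmap.pvalues[None, :], Path(out_path))
    return rho, pmap


def compare_rest_task(rest_dir, task_dir, out_path, n_perm=5000, n_boot=1000, seed=0):
    """Correlate the drug effect maps of a rest run and a task run.

    Reads the per-region drug-vs-placebo effect maps written by the two
    pipelines, reports the Pearson correlation with a permutation
    p-value and bootstrap CI, and compares the flexibility-integration
    coupling between the two states with the Dunn & Clark z.
    """
    rest_dir, task_dir = Path(rest_dir), Path(task_dir)
    task_effect = (
        pd.read_csv(task_dir / "group" / "main_effect_drug_minus_placebo.tsv", sep="\t")
        .to_numpy()
        .ravel()
    )
    # rest drug effect: interaction contrast on mean participation per region
    runs = pd.read_csv(rest_dir / "runs.tsv", sep="\t")
    eff = {}
    for _, row in runs.iterrows():
        tag = f"{row.subject}_{row.session}_{row.phase}"
        b = pd.read_csv(
            rest_dir / "runs" / tag / "participation.tsv", sep="\t"
        ).to_numpy()
        eff.setdefault(row.subject, {})[(row.session, row.phase)] = b.mean(axis=0)
    rest_effect = np.mean(
        [
            (v[("drug", "post")] - v[("drug", "pre")])
            - (v[("placebo", "post")] - v[("placebo", "pre")])
            for v in eff.values()
        ],
        axis=0,
    )
    r, p = permutation_corr_test(task_effect, rest_effect, n_perm=n_perm, seed=seed)
    lo, hi = bootstrap_corr_ci(task_effect, rest_effect, n_boot=n_boot, seed=seed)
    # flexibility-vs-integration coupling in each state
    def flex_b_corr(base: Path) -> tuple[float, int]:
        flex, bmean = [], []
        for d in sorted((base / "runs").iterdir()):
            f = pd.read_csv(d / "flexibility.tsv", sep="\t").to_numpy().ravel()
            b = pd.read_csv(d / "participation.tsv", sep="\t").to_numpy().mean(axis=0)
            flex.append(f)
            bmean.append(b)
        fl = np.mean(flex, axis=0)
        bm = np.mean(bmean, axis=0)
        return float(np.corrcoef(fl, bm)[0, 1]), fl.size

    r_rest, n_r = flex_b_corr(rest_dir)
    r_task, n_t = flex_b_corr(task_dir)
    z, pz = dunn_clark_z(r_task, r_rest, n_t, n_r)
    report = {
        "rest_task_effect_correlation": {
            "r": r,
            "p_permutation": p,
            "ci95": [lo, hi],
            "n_perm": n_perm,
            "n_boot": n_boot,
        },
        "flexibility_integration": {
            "r_rest": r_rest,
            "r_task": r_task,
            "dunn_clark_z": z,
            "p": pz,
        },
    }
    Path(out_path).write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
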