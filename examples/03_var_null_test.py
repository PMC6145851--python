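"""Stationary VAR surrogate null for network dynamism.

Fits a stationary VAR to a run, generates surrogate runs with matched
covariance and autocorrelation, pushes observed and surrogates through
the same pipeline to a mean-participation series, and compares the
kurtosis of its window-to-window change against the surrogate
distribution (one-sided, 95th percentile).

Two runs are tested: a genuinely stationary one (single latent state)
and a dynamic one with abrupt integrated bursts.  The stationary run
should land comfortably inside the null.  The dynamic run's statistic
moves toward the tail, but note that overlapping windows make the null
kurtosis distribution heavy-tailed, so single-run power is modest at
this problem size (20 regions, 300 frames) — the test is primarily a
calibrated guard against over-reading ordinary fluctuations.
"""

import numpy as np

from dyntopo import SyntheticSpec, fit_var, generate_modular_bold, kurtosis_test, simulate_var
from dyntopo.nulls import batch_mean_participation

n, t = 20, 300
part = np.repeat(np.arange(4), 5)


def run_test(state_sequence, label, seed):
    spec = SyntheticSpec(
        n_regions=n,
        module_sizes=(5, 5, 5, 5),
        n_frames=t,
        tr=2.2,
        within_coupling=0.6,
        between_coupling_by_state={"seg": 0.05, "int": 0.55},
        state_sequence=state_sequence,
        seed=seed,
    )
    ts, _ = generate_modular_bold(spec)
    model = fit_var(ts, order=2)
    surrogates = simulate_var(model, n_frames=t, n_surrogates=300, seed=seed + 1)
    null_mb = batch_mean_participation(surrogates, part, w=15, tr=2.2)
    obs_mb = batch_mean_participation(ts.data[None], part, w=15, tr=2.2)[0]
    res = kurtosis_test(obs_mb, null_mb, variant="diff")
    print(f"{label}:")
    print(f"  observed diff-kurtosis {res.observed:.2f} vs null 95th pct {res.percentile_95:.2f}")
    print(f"  null percentile of observed: {100 * res.null_percentile_of_observed:.0f}%")
    print(f"  dynamic topology flagged: {res.significant}")


stationary = ("seg",) * t
states = np.array(["seg"] * t, dtype=object)
states[150:175] = "int"
run_test(stationary, "stationary run (single state)", seed=3)
run_test(tuple(states), "dynamic run (integrated burst)", seed=4)
print("-> the percentile rule is a calibrated guard: a stationary run is not")
print("   flagged; at this problem size a single short burst rarely clears the")
print("   heavy-tailed null either, so rejections are strong evidence of dynamism")
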