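"""Per-window communities, cartographic profile and flexibility.

Runs the signed Louvain consensus in every MTD window, computes the
participation coefficient (B) and module-degree z-score (W) per region
and window, pools them into the cartographic profile, and reports
regional flexibility after Hungarian label matching.
"""

import numpy as np
from sklearn.metrics import normalized_mutual_info_score

from dyntopo import (
    SyntheticSpec,
    bandpass_filter,
    cartographic_profile,
    generate_modular_bold,
    match_labels,
    mtd_coupling,
    regional_flexibility,
    run_windows,
    topology_series,
)

spec = SyntheticSpec(
    n_regions=40,
    module_sizes=(10, 10, 10, 10),
    n_frames=216,
    tr=2.2,
    within_coupling=0.7,
    between_coupling_by_state={"rest": 0.1},
    seed=2,
)
ts, truth = generate_modular_bold(spec)
tensor = mtd_coupling(bandpass_filter(ts), w=15)
parts = run_windows(tensor, gamma=1.1, n_reps=50, seed=0)

nmis = [
    normalized_mutual_info_score(parts.assignments[t], truth.planted_partition)
    for t in range(parts.n_windows)
]
topo = topology_series(tensor, parts)
profile = cartographic_profile(topo, n_bins_b=20, n_bins_w=20)
flex = regional_flexibility(match_labels(parts))

print(f"{parts.n_windows} windows, mean Q_T = {parts.modularity.mean():.3f}")
print(f"mean modules per window: {parts.n_modules.mean():.2f}")
print(f"recovery of planted modules (mean NMI over windows): {np.mean(nmis):.3f}")
print(f"mean participation B_T: {topo.mean_B.mean():.3f}")
print(f"profile occupancy centre of mass along B: {profile.b_center_of_mass():.3f}")
print(f"median regional flexibility: {np.median(flex.values):.3f}")
print("-> mean B sits well below the 0.75 ceiling of a uniformly integrated")
print("   4-module network, and flexibility is low: segregated, stable topology")
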