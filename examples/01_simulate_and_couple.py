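"""Simulate a modular BOLD run and estimate time-resolved coupling.

Draws a 40-region run with four planted modules, band-passes it, and
computes the sliding-window MTD coupling tensor.  The printed numbers
show that windowed within-module coupling is much stronger than
between-module coupling, which is what the community detection stage
exploits.
"""

import numpy as np

from dyntopo import SyntheticSpec, bandpass_filter, generate_modular_bold, mtd_coupling

spec = SyntheticSpec(
    n_regions=40,
    module_sizes=(10, 10, 10, 10),
    n_frames=216,
    tr=2.2,
    within_coupling=0.6,
    between_coupling_by_state={"rest": 0.15},
    seed=1,
)
ts, truth = generate_modular_bold(spec)
filtered = bandpass_filter(ts)
tensor = mtd_coupling(filtered, w=15)

part = truth.planted_partition
same = part[:, None] == part[None, :]
off_diag = ~np.eye(40, dtype=bool)
mean_coupling = tensor.coupling.mean(axis=2)

print(f"run: {ts.n_frames} frames x {ts.n_regions} regions at TR {ts.tr} s")
print(f"MTD tensor: {tensor.n_windows} windows of length {tensor.window_length}")
print(f"mean within-module coupling:  {mean_coupling[same & off_diag].mean():.3f}")
print(f"mean between-module coupling: {mean_coupling[~same].mean():.3f}")
print("-> the block contrast in the coupling tensor mirrors the planted modules")
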