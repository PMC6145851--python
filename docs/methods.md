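# Methods

## The pipeline and its assumptions

The package estimates time-resolved network topology from parcellated BOLD
series in five stages: temporal preprocessing (band-pass, motion QC),
sliding-window coupling (MTD), per-window signed community detection
(Louvain + consensus), cartographic summaries (participation B_T,
module-degree z-score W_T, joint-histogram profile, flexibility), and
inference (VAR surrogate nulls, crossover ANOVA, pupil coupling, task GLM,
correlation tests).

The analysis assumes the parcellated series are stationary *within* a window,
that coupling is adequately summarised by second-order statistics, and that
community structure is meaningful per window (windows carry enough
information to partition the graph).  The last assumption is quantitatively
the weakest and drives the recovery limits discussed below.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| window `w` | 15 | frames | ≈ 33 s at TR 2.2 s; passes fluctuations near 0.1 Hz |
| band-pass | 0.01–0.125 | Hz | conventional BOLD connectivity band |
| resolution γ | 1.1 | — | most stable partitions across the 0.5–2.5 sweep |
| consensus reps | 500 | runs/window | tail estimation of the partition ensemble |
| FD / DVARS thresholds | 0.25 mm / 2.5 % | — | frame-flagging convention; run excluded above 10 % flagged |
| VAR order | 6 | lags | matches the temporal signature of the BOLD response at ~2 s TR |
| surrogates | 2500 | runs | stable tail percentiles for the dynamism test |
| FDR q | 0.05 | — | step-up control across profile bins / regions |
| permutations / bootstraps | 5000 / 1000 | — | correlation significance and CI |
| histogram geometry | 100×100, B∈[0,1], W∈[−5,5] | bins | fixed so profiles are comparable across runs; clipped samples are counted |

Numerical conventions worth knowing:

- **MTD windows** are centred on the derivative grid, valid windows only
  (`(T−1) − w + 1` windows); for even `w` the window spans `[t−w/2, t+w/2)`.
  σ is the population sd of the full-run derivative, so the normalisation sits
  outside the window mean.  Windowed means use exact cumulative sums.
- **Signed modularity** rewards positive within-module weight at scale `1/v⁺`
  and penalises negative within-module weight at the damped scale
  `1/(v⁺+v⁻)`; γ multiplies the configuration-model expected weight
  `e±_ij = s_i s_j / v` of each sign layer.  The diagonal is removed before
  community detection.  An all-negative graph has no defined objective and is
  rejected.
- **Louvain** shuffles node order per sweep (seeded xorshift), breaks gain
  ties toward the lowest community index, and aggregates sign layers
  separately.  **Consensus** thresholds the co-assignment matrix at its mean
  off-diagonal value and re-clusters until all runs agree; with unambiguous
  structure this converges in the first round.
- **W_T** uses positive weights only, for consistency with the participation
  coefficient's explicit positive-strength definition; a module with zero
  strength spread assigns W = 0 to its members.  Regions with no positive
  strength get B = 0.
- **Flexibility** defaults to the raw switch fraction (switches / (windows−1))
  after chained Hungarian matching of consecutive windows; a `per_module`
  variant additionally divides by the mean per-window module count, and the
  variant tag travels with the output.  Matching is chained forward, not
  globally optimised.
- **VAR surrogates**: coefficients are least-squares fits on demeaned runs
  (never crossing run boundaries); the model then carries an output transform
  `M = chol(Σ_data) · chol(Σ_model)⁻¹` so the surrogate stationary covariance
  equals the empirical mean covariance exactly while the companion spectral
  radius is preserved.  When `order × regions` approaches the sample count the
  fit moves to the top principal subspace (default ≤ 50 components) and
  projects back with iid residual noise; unstable fits are an error, reported
  with the spectral radius.  The model is fit to the unfiltered series;
  surrogates are band-passed like the data before re-entering the pipeline.
- **Kurtosis test**: plain (Pearson) fourth standardised moment; the default
  statistic is the kurtosis of the window-to-window *difference* of mean B_T
  (changes are what a stationary process constrains most directly), with the level-series variant also
  computed; one-sided decision at the null's 95th percentile.
- **Crossover ANOVA**: the drug-by-phase interaction in a complete
  within-subject 2×2 equals the squared paired t of
  `(post−pre)_drug − (post−pre)_placebo`, computed per bin and FDR-corrected.
- **Pupil group test**: with one Spearman ρ per subject per bin, the
  random-intercept mixed model on Fisher-z ρ is algebraically a one-sample t
  on the z values, which is what is computed.  The pupil regressor is
  convolved with the canonical double-gamma HRF (injectable kernel).
- **Task GLM**: condition boxcars, optionally HRF-convolved, averaged within
  each MTD window; contrasts are "mean(1,2,3-back) − 0-back" (main) and a
  linear trend over the four loads (load), each a one-degree F test.
- **Dunn & Clark z**: `var(z₁−z₂) = 1/(n₁−3) + 1/(n₂−3) − 2 r_x √(…)` with
  `r_x` the (user-supplied) correlation between the two Fisher-z estimates;
  `r_x = 0` reduces to the independent-samples comparison and is the default,
  since the dependency induced by shared parcels is not identifiable from the
  summary statistics alone.

## The synthetic generator

Runs are zero-mean Gaussian frames drawn from a block correlation matrix:
unit diagonal, `within_coupling` inside planted modules, and a
state-dependent `between_coupling` elsewhere; the latent state switches on
frame boundaries.  Positive semidefiniteness of every state's matrix is
validated at construction (requested couplings outside the PSD-valid range
are an error; the crossover generator clips subject-level couplings into
that range).  Optional extras: white measurement noise, double-gamma HRF
convolution, pupil traces that lag-track the latent integration path, N-back
block designs mapping load to integration (inverted-U profiles supported),
and crossover cohorts with Gaussian subject random intercepts on coupling.

Default dimensions mirror a typical resting acquisition (375 regions, 216
frames at TR 2.2 s; task 286 frames at TR 2.0 s); cohort-scale simulations
in the tests use 40 regions in four 10-region modules with within/between
couplings 0.6/0.15, a deliberately moderate modularity.  What the generator
does **not** emulate: temporal autocorrelation of real BOLD (frames are
independent unless HRF smoothing is enabled), physiological noise, scanner
artifacts, spatially heterogeneous module sizes and coupling, and
non-Gaussian tails.  Passing tests therefore demonstrate correctness of the
estimators and calibration of the inference under a known generative model,
not performance on real scanner data.

## Reduced pipelines for simulation studies

Power and calibration studies need thousands of runs, where per-window
consensus Louvain is both unaffordable and not the quantity under test.  Two
reduced paths exist and are used deliberately:

- `pipeline.cohort_bin_profiles` profiles each run against the consensus
  partition of its own *time-averaged* coupling matrix;
- `nulls.batch_mean_participation` computes mean B_T for surrogate batches
  against a fixed reference partition, fully vectorised.

Both keep the B/W/profile machinery identical to the full path (equality is
unit-tested); only the partition source changes.

## Recovery limits of windowed community detection

A windowed MTD edge estimate at `w = 15` has sampling sd
`≈ √((1+r²)/w) ≈ 0.33`, comparable to a strong within/between contrast of
0.8/0.1.  In the strong-contrast regime (40 regions, four modules, 500
frames) the per-window modularity-optimal partition therefore genuinely
differs from the planted partition in a substantial fraction of windows: the
consensus partition never scores below the planted partition's modularity,
yet typically one to three regions per window sit better (in that window's
noisy graph) in a neighbouring module.  Mean NMI against the planted
partition is ≈ 0.89 with ~40 % of windows at NMI ≥ 0.95.  This is an
information limit of 15-sample windows, not an algorithmic deficiency; exact
per-window recovery in *every* window is not attainable at these settings by
any detection method, and the test suite records that property explicitly.

## Determinism and provenance

Every stochastic stage takes a seed derived from one master seed
(`numpy` `SeedSequence` fan-out); pipeline outputs are written with fixed
float formatting and sorted JSON keys, so identical configs reproduce
byte-identical output trees (asserted in the tests).  The provenance record
stores the config hash, package version and per-stage seeds; wall-clock
timestamps go to the log stream rather than the provenance file so that
reproducibility is byte-exact.

## Known limitations

- The generator's frame-independence makes windowed estimates *optimistic*
  relative to autocorrelated real BOLD; real-data recovery will be harder.
- The multilayer (temporally coupled) Louvain variant is out of scope; label
  continuity comes only from post-hoc Hungarian matching.
- The VAR dynamism test has modest single-run power at small region/frame
  counts because overlapping windows make the null kurtosis distribution
  heavy-tailed; it is best read as a calibrated guard, and its type-I
  behaviour (not its power) is what the acceptance suite pins down.
- γ-sweep stability uses mean pairwise NMI among runs (not NMI against a
  reference partition).
- DVARS is expressed as percent of the run's global mean absolute signal and
  is only meaningful for series with a realistic baseline offset.
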