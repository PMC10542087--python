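# Methods

`dfcstates` implements a dynamic functional-connectivity (dFC) state
analysis for two-group cohorts of parcellated resting-state time series,
together with a synthetic cohort generator that gives every stage a ground
truth. This note records the models, the parameters that matter, the
numerical conventions, and what the synthetic validation does and does not
establish about real data.

## Analysis pipeline

The contract begins at the parcellated signal: one T × N matrix per subject
(N regions of an AAL-style atlas; voxel-level preprocessing is upstream and
out of scope). The stages are fixed in order:

1. **Temporal preprocessing** — discard the first `n_discard` volumes
   (default 10 of 240; TR = 2 s), subtract each region's least-squares
   linear trend, band-pass 0.01–0.08 Hz. The filter is an order-2
   Butterworth applied forward and backward (`sosfiltfilt`): zero phase, so
   state-transition timing is not displaced. The stages can be switched off
   individually but not reordered.
2. **Sliding-window connectivity** — rectangular windows of 30 volumes
   (60 s) advanced by 3 volumes (6 s): with 230 retained volumes,
   W = ⌊(230 − 30)/3⌋ + 1 = 67 windows per subject. Per window, Pearson
   correlation over all region pairs, Fisher-Z (arctanh) transformed.
   Correlations are clamped at 1 − 10⁻⁷ before the transform so duplicate
   regions cannot inject infinities; the diagonal is stored as 0 so the
   clustering vectorisation can use the strict upper triangle. A region
   with (numerically) zero variance inside a window gets zero correlations
   there, with a logged warning. The across-window standard deviation of Z
   (denominator W − 1) is the dFC variability map.
3. **Connectivity states** — K-means over all subjects' pooled
   upper-triangle Z vectors: squared-Euclidean distance, k-means++
   initialisation, best of `n_restarts` (default 50) by inertia,
   deterministic given the seed. States are renumbered by descending pooled
   occupancy so "state 1" is stable across runs. K is chosen by the elbow
   of log-inertia: the candidate with the maximal second difference, with a
   flat-curve guard (below) and a silhouette alternative. Per subject we
   compute mean dwell time (MDT; mean length of maximal runs, window
   units, with × step × TR = 6 s/window available as a seconds conversion),
   fractional windows, and the transition count. MDT of a never-visited
   state is defined as 0 and the subject is retained: dropping non-visitors
   would condition on the outcome, and the zero-inflated definition is the
   one consistent with dwell-time dispersion exceeding its mean in
   empirical cohorts.
4. **Group contrasts of temporal metrics** — linear model
   `metric ~ group + age + sex + education`, two-sided t on the group
   coefficient (patient coded 1). With no covariates this reduces exactly
   to the pooled-variance two-sample t.
5. **Per-state edgewise comparison with NBS** — per state, subjects'
   windows in that state are averaged into one matrix each (subjects never
   visiting the state are excluded and counted); each edge gets the same
   covariate-adjusted model. Family-wise control uses the network-based
   statistic: edges with two-sided p below 0.001 form a suprathreshold
   graph; its connected components are scored by edge count against a
   permutation null of the maximal component size (1000 permutations;
   component-level threshold 0.05). With covariates the permutation scheme
   is Freedman–Lane: residuals of the reduced (covariates-only) model are
   permuted and added back to the reduced fit before refitting, preserving
   the covariate structure under the null. The permutation p carries the +1
   correction, so its floor is 1/(n_perm + 1).
6. **Graph dynamics** — each windowed matrix is binarised over a sparsity
   ladder (0.10–0.40, step 0.01; 31 rungs): the top ⌊s·N(N−1)/2⌋ edges by
   |Z| are kept (ranking by signed Z available as `rank="positive"`), ties
   broken by (row, col) order for determinism. Six metrics per rung —
   degree, nodal efficiency, local efficiency, clustering coefficient,
   betweenness centrality, global efficiency — with the harmonic
   convention for unreachable pairs (1/d = 0), clustering 0 for degree < 2,
   local efficiency as the global efficiency of the neighbour-induced
   subgraph, and betweenness counting all shortest paths with multiplicity,
   normalised by (N−1)(N−2)/2. Each metric is aggregated over the ladder by
   trapezoidal AUC (threshold-free), then summarised per subject by its
   across-window sample variance; variances are contrasted between groups
   with the same covariate-adjusted model, Benjamini–Hochberg corrected
   across nodes within each nodal-metric family (global metrics are a
   family of one; q = p).
7. **Clinical statistics** — demographics via pooled t (continuous) and
   Pearson chi-squared without continuity correction (categorical; a flag
   restores Yates); metric–score correlations via Pearson's r (Spearman by
   flag), pairwise deletion of missing scores, no multiplicity correction
   but the test count is reported.

The pipeline orchestrator derives per-stage seeds by hashing the master
seed with the stage name, so re-running or appending stages never perturbs
earlier randomness; identical configs produce byte-identical output tables.

## Synthetic cohort generator

No public cohort with ground-truth connectivity states exists, so the
generator *is* the study condition. It is a hidden-Markov switching
multivariate normal:

- A latent Markov chain over K = 4 states advances one tick every
  `state_switch_step` = 3 volumes (the window step, so latent dwell times
  are commensurate with window labels). Baseline self-transition is 0.96
  per tick (mean dwell 25 ticks = 75 volumes); the planted group difference
  lowers the *controls'* self-transition in state 2 to 0.90 (mean dwell
  10 ticks = 30 volumes). Patients therefore dwell longer in state 2, and
  because the asymmetry is realised by shortening control dwells rather
  than lengthening patient dwells, patient dwell segments stay short
  relative to the 230-volume scan and are not truncated by it. The
  resulting window-level MDTs (≈ 14 vs ≈ 7 windows) sit in the range
  empirical cohorts report.
- Within a dwell segment the N-region signal is i.i.d. zero-mean
  multivariate normal with the state's covariance; AR(1) observation noise
  (stationary SD 0.5, coefficient 0.3) is added.
- State covariances are correlation matrices over 8 contiguous modules
  (stand-ins for functional networks). Two features distinguish states:
  a Hadamard-style sign pattern splits the modules into two anticorrelated
  super-communities (state 1 is the globally integrated all-positive
  pattern) with between-module coupling ±0.35, and a second, state-shifted
  sign pattern makes half the modules strongly knit (0.5 × 1.3 = 0.65) and
  half weakly knit (0.5 × 0.8 = 0.40). The sign structure is what K-means
  recovers; the within-module contrast is what makes the *binarised
  topology* genuinely switch with the state. The weak within level must
  stay above |between_r|: configurations violating this leave the PSD cone
  and the shrinkage repair (toward the identity, factor 0.95 per step)
  washes out the planted structure. The defaults need no shrinkage.
- Subject metadata (age, sex, education, symptom duration, JOA, NDI) is
  drawn to match the two-group summary moments of a published cervical
  spondylotic myelopathy cohort (88 patients, 77 controls); clinical scores
  are explicitly missing — never zero — for controls.

Every subject's latent state sequence (trimmed to retained volumes) is
exposed as a ground-truth channel for tests.

## Calibrated constants

- **Elbow tolerance 0.03** (`states.ELBOW_TOL`): a second difference of
  log-inertia below this counts as "no elbow" and triggers the flat-curve
  warning. Calibrated once against single-state (null) cohorts, whose
  maximal second differences stay below ≈ 0.013, versus planted four-state
  cohorts at default conditions, which produce ≈ 0.05–0.06 at the true K.
- **Correlation clamp 1 − 10⁻⁷**, **PSD tolerance −10⁻¹²** after
  shrinkage, **window-variance tolerance** for degenerate regions at
  relative 10⁻¹².

## What the synthetic validation shows — and does not

Passing the planted-recovery tests shows the pipeline can recover the kind
of structure it assumes: well-separated recurring covariance patterns with
geometric dwells. At the default conditions, K-selection recovers K = 4 in
≈ 90 % of reduced cohorts, window labels agree with the latent state at the
window midpoint at ARI ≈ 0.80–0.82 (the binding constraint is windows that
straddle dwell boundaries, an intrinsic limit of 60-s sliding windows, not
estimation noise — interior windows are classified essentially perfectly),
and the planted dwell asymmetry is detected with the correct direction.

Real data differ in ways the cartoon does not emulate: haemodynamic
convolution and physiological noise, spatially heterogeneous SNR,
non-Markov dwell processes, states that drift rather than switch, and
motion artefacts. Two further caveats are known from the calibration
itself. First, after band-pass filtering a 60-s window holds roughly 8
effective samples, so windowed correlations carry Z-noise of ≈ 0.4; the
between-state differences in *binarised topology* at the generator's
defaults are an order of magnitude smaller than this churn, so the
"switching inflates graph-metric variance" property is only demonstrable
with strongly re-wired states (dense communities on disjoint node sets),
which is how the test constructs it. Second, the NBS type-I calibration is
run at edge threshold p = 0.05: at the production threshold 0.001 the null
distribution of the maximal component size is concentrated on {0, 1},
making the test conservative by discreteness rather than miscalibrated —
the production setting keeps 0.001.

## Problem sizes used in the checks

The full default cohort (165 subjects × 67 windows = 11,055 windowed
networks, 90 regions) is used for the window-count, state-recovery and
dwell-contrast checks. K-recovery sweeps use 20 reduced cohorts
(20 + 20 subjects, 30 regions); NBS calibration uses 20 + 20 subjects at
30 regions with 200 permutations (500 null repetitions, 30 power
repetitions); graph-stage runs in tests subsample windows via the
pipeline's `max_windows` option. These sizes are the package's own choice
of test conditions and are recorded in each test.
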