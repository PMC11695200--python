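# Methods

This note documents the models, conventions and design choices behind
`dynconn`, in the order the pipeline runs.

## Cohort model and the synthetic generator

The package consumes per-subject channel time courses (ICA-component or
atlas-node signals) downstream of preprocessing and spatial ICA; it does
not model raw BOLD volumes, hemodynamics or head motion. The synthetic
generator exists so that every downstream stage can be validated against
planted ground truth.

Each synthetic subject follows a hidden-Markov model over covariance
states: a state sequence is drawn from a row-stochastic transition matrix
(initial state from its stationary distribution), and each time point emits
a zero-mean multivariate normal vector with the active state's covariance.
Defaults mirror the study design the package targets: two groups of 66 and
54 subjects, 234 time points at TR = 2 s, 13 channels in six networks, six
states. The default transition kernel is uniform-sticky with stay
probability 0.95 (mean dwell 20 TRs = 40 s), the dwell scale commonly
reported for resting-state connectivity states. Default state covariances
are rank-one sign-factor correlation matrices `I + λ u uᵀ` (rescaled to
unit diagonal, u a random ±1 vector), which are positive definite by
construction and give states that differ by large Fisher-z distances on
roughly half of all channel pairs.

Group effects are injected as Fisher-z shifts on selected pairs
(`r → tanh(atanh(r) + Δz)`), after which the covariance is projected back
to the positive-definite cone by eigenvalue clipping at 1e-6 and rescaled
to its original diagonal — the effect stays interpretable in the same units
as sFNC contrasts. Covariates are sampled to match the target cohort's
margins: age ~ N(58.6, 6.7) truncated to [50, 80] years, education
~ N(10.9, 1.7) years, gender ~ Bernoulli(0.525), mean framewise
displacement ~ N(0.23, 0.07) mm truncated at 0. Each subject gets an
independent random stream derived from (master seed, subject index), so
cohorts are bit-reproducible and stable under reordering.

For the multilayer stage, `make_layered_network` plants a per-layer
stochastic block model (within-module edge probability `p_in`, between
`p_out`, binary weights) in which designated switcher nodes change module
at configured layers; the planted node-by-layer partition is returned as
truth.

What the generator does **not** emulate: spatial structure and ICA mixing,
scanner noise and motion artifacts, non-Gaussian and nonstationary
marginals, autocorrelated (HRF-smoothed) noise, and site/vendor effects.
Passing recovery tests therefore demonstrates the correctness and
calibration of the algorithms under the stated statistical model, not
performance on real fMRI.

## Static FNC

Pearson correlations between channel time courses, Fisher z-transformed
with |r| clipped to 1 − 1e-7 so z stays finite (negligible bias, reached
only by numerically dependent channels). The matrix diagonal is stored as
zero because all downstream vectorization uses the strict lower triangle in
row-major order — one package-wide pair convention. An optional linear
detrend (off by default) is exposed for component time courses that were
not post-processed upstream.

## Dynamic FNC and brain states

The window is a rectangle of `width` ones convolved with a discrete
Gaussian kernel (σ in TR units, truncated at ±3σ and renormalized); the
central `width` samples of the full convolution are kept and normalized to
sum one. As σ → 0 the taper tends to the uniform window. Correlations
within a window use taper-weighted moments — this is the operational
meaning of "a rectangular window convolved with a Gaussian", rather than
slicing followed by unweighted correlation. A window in which a channel is
numerically constant gets correlation 0 on the affected pairs with a logged
warning. With T time points, width w and step s there are
`⌊(T − w)/s⌋ + 1` windows — 215 for T = 234, w = 20, s = 1.

States are found by Lloyd k-means on the pooled windows-by-pairs Fisher-z
matrix. The default distance is city-block with coordinate-wise median
centroids (the convention of the dominant dFNC toolbox); squared Euclidean
with mean centroids is available by flag. Initialization is best-of-20
random restarts from a master seed — simple and reproducible; no
subject-exemplar two-stage scheme is used. Empty clusters are re-seeded at
the point farthest from its assigned centroid. Iteration stops at an
assignment fixpoint or 500 iterations. States are renumbered in descending
order of pooled occupancy so "state 1" is always the most frequent.

Temporal metrics per subject: fraction time (window share per state), mean
dwell time (mean maximal-run length, in windows; missing for unvisited
states), and the number of adjacent-window label changes. dFNC variability
is the across-window sample SD (denominator W − 1) of each pair's windowed
correlation coefficient r — on r, not z, following the metric's standard
definition.

**Resolution limit.** A sliding window cannot resolve state excursions
shorter than itself: such excursions blur into neighboring windows and can
shift a single subject's fraction-time estimate by up to ~width/W (≈ 0.09
at the default geometry). Recovery tests therefore score per-window state
labels by the state carrying the most taper weight and assess fraction-time
accuracy as a cohort-level mean, not a per-subject worst case.

## Dynamic graph topology

Windowed correlation matrices are binarized by keeping the top
`round(s·C(C−1)/2)` edges at each sparsity s in a grid (default 0.10–0.34
in steps of 0.01, a conventional small-network range that keeps mean degree
above log C at the low end; fully configurable). Edges are ranked by
signed weight — anticorrelations drop first — with ties broken by (i, j)
lexicographic order; absolute-value ranking is available by flag. Global
efficiency is the mean inverse shortest-path length over ordered pairs
(disconnected pairs contribute 0; computed by a vectorized Floyd–Warshall);
local efficiency averages each node's neighbor-subgraph global efficiency
(0 below degree 2). Per window, each metric is integrated over the
sparsity grid by the trapezoid rule (a single grid point degenerates to the
metric itself); the subject's flexibility is the across-window sample SD of
that AUC. The alternative order — SD per sparsity, then AUC — is provided
behind a flag for sensitivity analysis. The per-window reading of
"variability of topological metrics" is implemented; building a single
graph from the variability matrix itself would be a different analysis and
is deliberately not guessed at.

## Multilayer modularity and switching

Layers are the windowed correlation matrices with negative entries set to 0
(the quality function assumes nonnegative weights; absolute value is
available by flag), sharing the tapered windowing of the dFNC stage. The
quality function is the standard multilayer modularity with uniform ordinal
coupling ω between copies of a node in adjacent layers and resolution γ
applied uniformly to all layers (defaults γ = 1.1, ω = 0.5). A layer with
zero total weight contributes no null-model term (warning logged). The
normalization 2μ is the total doubled edge weight plus total doubled
coupling; at ω = 0 the quality decomposes exactly into the per-layer
Newman–Girvan modularities weighted by their share of 2μ.

Optimization is an iterative ordinal Louvain: greedy moves over
(node, layer) units using coupling-aware gains computed from per-layer
quality blocks `B_l = A_l − γ k kᵀ/2m_l`, then aggregation of communities
and greedy moves on the aggregated quality matrix, repeated until neither
phase improves; the best of `n_repeats` randomized restarts (default 20)
is returned, with labels canonicalized by first occurrence. The returned Q
always equals the quality function re-evaluated on the returned partition.
On exhaustively enumerable instances (4 nodes × 2 layers, all 4140
partitions) the optimizer attains the global optimum in ≥ 95 % of random
instances.

A node's switching rate is `#{l : g_{i,l} ≠ g_{i,l+1}}/(L − 1)`; network
rates average member nodes. Because the optimizer is stochastic, reported
switching rates are consensus means over independent optimizer runs
(distinct seeds, one run each), with the across-run SD stored alongside.

## Inference

Group contrasts use OLS on `[1, group, age, gender, education]` with a
two-sided t test on the group coefficient (fitted column-wise over feature
matrices). Features with zero residual variance at rounding level report
β = 0, p = 1. Benjamini–Hochberg q-values use the step-up formula
`q_(i) = min_{j≥i} m p_(j)/j` clipped at 1; each feature family is
corrected separately, except temporal state properties which are reported
uncorrected (a per-family flag encodes this convention). Head-motion
validation reruns every contrast with mean framewise displacement appended
to the covariates and writes a parallel table. Partial correlations are
Pearson correlations of OLS residuals with df = n − 2 − #covariates;
subgroup contrasts reuse the GLM machinery within the patient group across
a threshold split (MoCA ≥ 26 or age ≥ 60), and error if a subgroup is
empty. Demographic tables from summary statistics use the pooled or Welch
two-sample t (as appropriate per row) and the Pearson χ² without continuity
correction. Gender is coded 0/1 as a covariate.

## Problem sizes used in tests and benchmarks

State-recovery benchmarks use cohorts of 20 subjects × 234 time points with
six strongly separated states (sign-factor correlations of magnitude 0.9,
stay probability 0.99 — the regime in which the minimum centroid separation
in windows-by-pairs space is about five times the within-state dispersion,
so window labels are well defined). Switching-rate recovery uses 20-node,
10-layer planted networks with 4 switchers (p_in = 0.9, p_out = 0.05) over
10 seeds. GLM calibration uses 200 null repeats of 10 features at
n = 60/60; power uses 20 repeats of a 0.3 z-shift on one pair at n = 30/30
in a single-state cohort (where the shift is expressed undiluted). The
demo pipeline runs 10 + 10 subjects at T = 120. These sizes make the full
validation cycle run in about a minute on one CPU while keeping every
statistical conclusion at conventional confidence.

## Known limitations

* Sliding-window state labels are undefined to within the window width at
  state boundaries (see the resolution limit above).
* The Louvain optimizer guarantees only local optimality on large
  instances; consensus averaging reduces but does not remove run-to-run
  variability.
* The generator's Gaussian, temporally white emissions understate the
  heavy tails and autocorrelation of real component time courses, so
  real-data effect sizes and variances will differ from synthetic ones.
* Group effects shift state covariances uniformly across states; per-state
  effects can be emulated by passing custom state covariance stacks.
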