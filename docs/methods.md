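# Methods

This note documents the models, conventions and numerical choices behind
`braingraph`, in the order data flow through the pipeline.

## Time-series cleaning

The pipeline operates purely at the regional-time-series level; image-space
steps (slice timing, realignment estimation, spatial normalization,
smoothing) are assumed done by an external tool that produced the ROI table
and the six rigid-body realignment parameters.

The fixed stage order is: discard initial volumes → FD/scrub mask →
nuisance regression → band-pass. Defaults: 10 of 200 volumes discarded,
TR = 2 s.

**Framewise displacement.** FD_t = Σ|Δ translation| + 50 mm · Σ|Δ rotation|,
backward differences, FD_1 = 0. The 50 mm factor converts radians to arc
length at an assumed head radius; it is the scalar-FD convention most
scrubbing pipelines use. FD is invariant to constant offsets in the motion
trace.

**Scrubbing.** A volume with FD > 0.2 mm is bad; for each bad volume b the
window {b − 1, …, b + 2} is flagged. The phrase "one forward volume and two
back volumes" admits two temporal readings; we take *forward = earlier* (1
before, 2 after), the common scrubbing practice, and expose `(n_before,
n_after)` so the opposite reading is one argument away. Each flagged volume
becomes a unit spike regressor, which exactly zeroes that volume's residual
— censoring by regression rather than deletion, keeping the time axis
intact for the band-pass.

**Nuisance design.** Intercept, linear trend, the Friston-24 motion
expansion (6 parameters, their one-volume lags, and both sets squared), the
spike indicators, and white-matter and CSF signals supplied as columns.
Exactly collinear columns are dropped greedily (intercept scanned first) and
logged; the regression is ordinary least squares per region, with residuals
orthogonal to the design to machine precision. A subject is signalled for
exclusion when fewer than 10 residual degrees of freedom remain, or when
peak-to-peak motion exceeds 1.5 mm translation / 1.5° rotation; callers
decide whether to drop the subject (the pipeline driver does).

**Band-pass.** An ideal discrete-Fourier filter: bins with 0.01 Hz ≤ f ≤
0.08 Hz are kept, everything else — including DC — is zeroed. An ideal
filter matches common rs-fMRI toolbox behaviour and is exactly testable: an
on-bin pass-band sinusoid is preserved to <1%, a stop-band one attenuated
>99%. The mean-FD covariate used later is computed after volume discarding.

## Network construction

Pearson correlation between every pair of regional series, Fisher Z
(z = arctanh r, diagonal stored as 0), then binarization at fixed sparsity
S: K = round(S · R(R−1)/2) edges (half-up rounding; at R = 116 and S = 0.05
this is round(333.5) = 334). The default grid is 0.05–0.50 inclusive in
steps of 0.01 (46 levels); the grid's stated open bounds are rounded to the
step lattice, so both endpoints are included.

Edges are the K largest positive Z values under a fixed total order (larger
Z first, ties by lexicographic node pair), from one global ranking per
subject — which guarantees nested edge sets across the grid and makes
thresholding invariant to any strictly monotone transform of positive Z
(so thresholding r or Z is equivalent). Negative correlations never become
edges under the default `positive` mode, the standard convention for binary
small-world analysis where negative-edge semantics are undefined; an
`absolute` mode is available. If fewer than K positive values exist the
graph keeps all of them and a warning is issued.

## Graph metrics

All graphs are simple, undirected, unweighted, on all R nodes.

- **Cp**: mean over nodes of C_i = 2t_i/(k_i(k_i−1)), C_i = 0 for k_i < 2.
- **Lp**: mean hop distance over *reachable* ordered pairs, with the
  unreachable fraction reported alongside. Low-sparsity graphs fragment;
  this convention keeps Lp finite across the grid instead of going infinite
  or silently restricting to the largest component. Null networks use the
  same convention, as the γ/λ normalization requires.
- **Eg / NE**: mean inverse distance with 1/∞ = 0; Eg is exactly the mean
  of the nodal efficiencies.
- **Eloc**: mean over nodes of the global efficiency of each node's
  neighbour-induced subgraph (the node excluded; k_i < 2 contributes 0).
- **DC**: edge count. **BC**: Brandes betweenness, raw (unnormalized),
  unordered-pair convention — group contrasts are invariant to the scale,
  but cross-toolbox comparisons should rescale.
- Distances come from a vectorized all-sources BFS (boolean matrix powers);
  betweenness uses networkx's Brandes implementation. Both are verified
  against exhaustive enumeration oracles in the test suite.

**Small-world normalization.** γ = Cp/⟨Cp_rand⟩, λ = Lp/⟨Lp_rand⟩,
σ = γ/λ over an ensemble of degree-preserving Maslov–Sneppen rewirings:
`swaps_per_edge × E` *attempted* double-edge swaps, rejecting any that
would create a self-loop or duplicate edge. Publication-grade runs use
1,000 nulls (the configured default); tests and the desk-scale studies
below use 8–20 nulls and 10–100 swaps per edge, which is sufficient because
AUC summaries average over 46 grid levels. With zero swaps the ensemble is
the graph itself and γ = λ = σ = 1 exactly (computed once, not averaged, so
the identity holds bitwise). All randomness is pre-drawn from a seeded
numpy Generator and fanned out per (subject, level) from a master seed, so
results are reproducible and independent of subject processing order; the
accept/reject loop is numba-compiled.

On very small graphs at very low sparsity the null ensemble can contain no
triangles, making γ undefined; such levels are recorded as NaN and the AUC
integrates the defined sub-grid. At R = 116 on the default grid this never
occurs.

**AUC.** Trapezoidal integral of each metric-versus-sparsity curve;
differences from rectangle rules are second-order at step 0.01.

## Group statistics

The subject table (one row per subject: group, age, gender, mean FD, all
AUC metrics, clinical variables) feeds a model/results pair
(`GroupComparison` → `GroupComparisonResults`):

- **Omnibus**: incremental F of the group factor — covariates-only OLS vs
  covariates + (g−1) group indicators, F(g−1, n−g−k). With no covariates
  this is exactly one-way ANOVA; the test is invariant to the reference
  level. Gender is coded 0/1 deterministically (alphabetical); constant
  covariates are dropped with a warning.
- **FDR families**: the 7 global AUC metrics form one family; each nodal
  metric type (DC, BC, NE) is corrected across its 116 nodes as its own
  family. Family structure is configurable since no single convention is
  universal.
- **Post-hoc**: two-group covariate-adjusted OLS t on the group indicator
  (sign = first-named minus second-named group mean), run only for metrics
  surviving the omnibus FDR gate, then FDR-corrected as their own family.
- **Partial correlation**: residualize metric and clinical variable on the
  covariates (with intercept), Pearson r of residuals, p from
  t = r√((n−2−k)/(1−r²)) on n−2−k df; run within each patient group and
  pooled.

## Synthetic cohort generator

The generator emulates the data structure the analysis assumes — three
groups of 37/30/41 subjects, 200 volumes at TR = 2 s, 116 regions — so the
pipeline is testable without patient data.

- **Signal model**: rows i.i.d. from N(0, Σ), Σ block-structured (8 modules
  of 14–15 regions by default): unit diagonal, r_within = 0.6 inside a
  module, r_between = 0.1 across modules, plus white observation noise
  (sd 0.2). This matrix is PSD by construction whenever
  r_within ≥ r_between ≥ 0; a nearest-PSD projection (eigenvalue clipping +
  diagonal renormalization) guards exotic parameter choices.
- **Group effect**: within-module correlation multiplied by a per-group
  factor — a pure connectivity-topology effect, no mean-signal difference,
  isolating the mechanism the group contrast measures. Each subject also
  carries a lognormal connectivity jitter (sd 0.1) providing between-subject
  metric variance.
- **Motion**: bounded random-walk drift (steps clipped so spike-free traces
  never cross the 0.2 mm FD threshold) plus one-volume translation spikes
  (rate 0.02/volume, 0.5 mm) the scrubbing stage must catch. White-noise
  WM/CSF stand-in columns are emitted alongside.
- **Clinical covariates**: a covariate targeted at partial correlation ρ
  with a named metric is built in a pilot pass: the metric AUC is computed
  on each subject's raw series, standardized across the cohort, and the
  covariate is mean + sd·(ρ·z_metric + √(1−ρ²)·ε). The pilot-pass anchor
  guarantees the target in expectation, which a latent-factor construction
  alone cannot do without calibrating the unknown latent→metric
  attenuation; the independent noise term keeps the covariate from being a
  deterministic function of the metric. Anchorable metrics are the global
  AUCs computable without null ensembles (Cp, Lp, Eg, Eloc).

What the generator does *not* emulate: hemodynamics, spatial structure,
physiological (non-white) noise, site/scanner effects, and realistic nodal
heterogeneity. Passing tests therefore demonstrate correctness of the
pipeline's computations and calibration of its statistics under the stated
generative model — not robustness to everything real fMRI contains.

## Designed study conditions for the recovery tests

The desk-scale parameter-recovery study (test suite) uses 30 regions in 6
modules, groups of 12/10/14, r_within = 0.3, r_between = 0.1, group factors
1.5 / 1.2 / 1.0, 8 nulls × 10 swaps per edge, 50 replicates. Two choices
deserve explanation:

- **Problem sizes** (R = 30, small null ensembles) keep each replicate a
  few seconds while leaving every code path identical to a full-scale run.
- **r_within = 0.3** rather than the generator default 0.6: sparsity
  thresholding is rank-based, so a uniform within-module scaling only
  changes the binary graphs where within- and between-module correlations
  intermix in rank. At r_within = 0.6 the margin over r_between = 0.1 is so
  wide (relative to the sampling noise of a 190-volume correlation) that
  the thresholded graphs are nearly invariant to the scaling; at 0.3 the
  within-module pairs sit near the noise floor and the scaling is a
  first-order topological effect — elevated Eloc, γ and σ in the scaled
  group, the qualitative pattern the pipeline is designed to detect.

The null-calibration study uses 12 regions, 3 × 5 subjects and 200
replicates (no-effect cohorts through the full cohort → Eloc-AUC → ANCOVA
chain), asserting the rejection rate inside the exact central 99.5%
binomial band around 0.05.

## Known limitations

- Binary graphs only; weighted/directed variants, modularity, rich-club and
  hub classification are out of scope.
- The ideal band-pass assumes the spike regressors have removed scrubbed
  volumes' influence; no interpolation-before-filtering is performed.
- BC's raw pair-count convention and the reachable-pairs Lp convention must
  be matched when comparing numbers across toolboxes.
- The exact original toolbox conventions for disconnected-graph Lp and for
  grid endpoint inclusion are not published; both are explicit, switchable
  choices here.
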