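# Methods

This note documents the statistical models, the synthetic-data generator,
and the numerical and design choices behind `voleconn`.

## Connectome model

Each subject-session dataset is a time × ROI matrix of cleaned BOLD
signals. Connectivity is the **partial correlation** between two regions —
the correlation of their signals after regressing out all other regions —
computed from the inverse sample covariance (precision) matrix θ as
`p_ij = −θ_ij / √(θ_ii θ_jj)` and Fisher z-transformed (`arctanh`) before
any linear modelling. The inverse-covariance route is O(p³) and
numerically stable for the regime this package targets (300 retained
volumes ≫ 16 regions), so no shrinkage is applied by default; a relative
ridge term (`PartialCorrelation(ridge=...)`) exists for p ≈ n use. The
residual-regression definition is retained as an independent oracle in the
test suite, where both routes must agree to 1e−10.

Edge order is canonical: upper triangle, row-major, in the order of the
ROI list shipped with the package (16 pair-bonding regions; a 9-region
control set). Every manifest records this ordering.

Standardizing time series before the partial correlation is unnecessary —
correlations are scale-invariant, and this invariance is tested.

## Preprocessing

The cleaning pipeline is: discard the first 5 volumes (signal
equilibrium), regress out nuisance signals, band-pass, smooth. Nuisance
signals are the top-5 left singular vectors of the centered
non-gray-matter voxel matrix (vascular/ventricle/white-matter sources)
plus six rigid-body motion parameters; an intercept is always included so
residuals are mean-centered, which the downstream correlations require.
Motion parameters are inputs, not estimated — registration and motion
correction are out of scope.

The band-pass family is unconstrained by the scientific requirement
(retain 0.01–0.1 Hz, attenuate elsewhere), so a standard choice is made: a
zero-phase forward-backward Butterworth of order 5, which passes ≥ 0.9 of
a passband sinusoid, ≤ 0.1 at twice the upper cutoff, and introduces no
phase shift. Box smoothing uses a shrinking window at the volume edges
(no zero padding), so constant volumes are preserved exactly. All steps
are linear; linearity is tested.

The voxel-level order band-pass → smoothing is fixed by convention here;
on linear operators the choice does not affect the ROI statistics used
downstream.

## NBS-GLM: edge–behavior association

Per edge, OLS of the Fisher-z values on an intercept plus the behavioral
covariate (plus optional nuisance columns); the statistic is the
covariate's T. Edges with T beyond a **fixed threshold of 1.7** in the
tested direction form a graph on the regions; each connected component is
scored by its **intensity** — the sum of |T| over its edges — matching the
"sum of statistical estimates" scoring of the network-based-statistic
framework (the extent scoring, component edge count, is available behind a
flag). Signed one-directional contrasts are run separately for positive
and negative association and both are reported by default, because the
direction of a behavioral association is a finding, not an input.

Family-wise error: the covariate vector is permuted across subjects
(exchangeable under the null of no association); with nuisance covariates
the Freedman–Lane scheme permutes reduced-model residuals. Each
permutation records the maximum component strength (0 if no edge passes);
a component's FWE p is `(1 + #{null ≥ strength}) / (1 + n_perm)`, which is
never zero and never below `1/(n_perm+1)`. Correlation matrices are never
pre-thresholded — the threshold applies to test statistics only.

Defaults: `t_thresh=1.7`, `n_perm=5000`, both chosen to match the
framework's standard operating point for this design.

## NBS-LMM: longitudinal inference

Each edge's longitudinal data (up to 3 sessions × 32 subjects, missing
cells allowed) is modelled with a linear mixed model fitted by REML:
fixed effects sex and session (interaction optional), subject-level random
effects. Two random structures are supported:

* **random intercept + per-subject session deviations** (independent,
  common variance) — the default for reported single-edge fits
  (`fit_edge_lmm`), via `statsmodels.MixedLM` with a variance component
  for the session factor; on non-convergence the fit falls back to a
  random intercept alone and the fallback is logged;
* **random intercept only** — used by the component-level permutation
  machinery (below) through a purpose-built engine.

Degrees of freedom follow the fixed **inner–outer rule** of hierarchical
models rather than Satterthwaite/Kenward–Roger: within-subject terms use
`n_obs − n_subjects − p_within` (90 − 32 − 2 = 56 for the 3-level session
factor in the additive model), between-subject terms use
`n_subjects − p_between − 1` (30 for sex). Sex and session main effects
are tested in the additive model; the interaction term in the full model,
whose within-subject df is 90 − 32 − 4 = 54.

**Permutation engine.** The component test refits every edge under
thousands of permuted designs, so it uses a profiled-REML random-intercept
engine: the single variance ratio λ = σ²_b/σ²_e reduces the model to OLS
on whitened data for any fixed λ, and a grid of 37 candidate ratios
(0 and 36 log-spaced points in [1e−3, 1e4]) is evaluated for all edges as
batched QR solves. Observed and permuted statistics always pass through
the same engine, so the permutation null is exchangeable with the
observation by construction. For reported single-edge fits the ratio is
polished by a bounded scalar search; on balanced complete data the
resulting session F equals the repeated-measures decomposition exactly
(tested to 1e−6), and the engine matches `statsmodels` REML fits to
≈1e−6 in the fixed effects.

Edge-level significance uses the term's Wald F with the inner–outer df;
suprathreshold edges (p < 0.05) form components scored by the sum of
z-equivalents √F, signed by the dominant contrast (for 1-df terms this is
|t|). Exchangeability is respected term by term: session labels are
permuted **within each subject** for session and interaction effects, sex
labels are permuted **across subjects** for the sex effect. Degenerate
(zero-variance) edges are excluded with a logged warning, never silently.
Missing sessions are handled by the likelihood — no imputation, no
casewise deletion.

Post hocs are estimated-marginal-means session contrasts. In the additive
model the sex effect cancels in every session contrast, so the EMM
difference equals the session-coefficient contrast; t uses the
within-subject df (56 in the study design) and Benjamini–Hochberg FDR is
applied across all contrasts of all edges of one significant component
(one FDR family per network). Dropping the sex term
(`include_sex=False`) reuses the identical component machinery.

The "session as a random variable" phrasing of mixed-model folklore is
ambiguous between per-level deviations and a numeric slope; the deviation
reading is implemented. The sign convention for multi-df z-equivalents is
internal and tested for self-consistency only.

## Behavioral statistics

* Partner-preference index: `time_partner / (time_partner +
  time_stranger)` (dimensionless, [0, 1]); undefined (missing, with a
  warning) when both times are zero.
* Huddling latency: minutes to the start of the first continuous
  side-to-side contact bout of ≥ 10 s; bout timestamps are seconds,
  latencies minutes, conversions explicit.
* Mann–Whitney U: midranks for ties, tie-corrected variance. The effect
  size is `r = |Z|/√N` with Z from the normal approximation **without**
  continuity correction and N the number of **unique subjects**
  contributing observations — with 32 animals providing both proportions,
  N = 32 even when the two samples hold 32 values each. This is the only
  convention that reproduces all four printed (U, r) pairs of the
  reference behavioral dataset simultaneously (378→0.32 at 32 v 32;
  121→0.05, 118→0.07, 119→0.06 at 16 v 16), which the tests assert
  jointly. The p-value uses the same Z; one- and two-tailed versions are
  exposed.
* Edge–behavior correlations: Pearson (t distribution, df = n − 2) or
  Spearman (t approximation), pairwise-complete. At the rounded
  r = −0.468 with n = 28 the two-tailed p is 0.0120; published tables
  that print 0.011 for this r computed p from the unrounded correlation.

## Synthetic cohorts

The generator emulates the study design: 32 subjects (16 F / 16 M), 3
sessions, 16 ROIs, 300 retained volumes at TR = 2 s, and an explicit
missingness list reproducing the 90-of-96 accounting (four baseline cells
and two 2-week cells lost). Missingness is configured, not random, so the
bookkeeping is exact.

Latent structure is specified on the Fisher-z partial-correlation scale —
the scale of all downstream statistics; per-session additive effects are
applied there (for the magnitudes used, ≤ 0.3, the difference from
specifying them on the correlation scale is second order). A target
partial-correlation matrix is converted to a unit-diagonal precision
matrix (`θ = 2I − P`), checked for positive definiteness, and rows are
drawn i.i.d. from N(0, θ⁻¹), so the true partial correlations equal the
target exactly. Individual differences come from a per-subject **network
factor** (sd 0.12 z-units) shared by the edges of a designated
subnetwork, which makes a behavioral value coupled to one edge correlate
with the whole subnetwork — the structure the cross-sectional network
statistic is designed to detect. Behavioral values are
`intercept + slope × true_z + N(0, noise_sd)`.

Two named scenarios fix the planted-effect conditions used throughout the
tests: `huddling_scenario` (9-edge path over 10 ROIs, 28 subjects,
latency slope −150 min per z-unit, noise sd 6 min, intercept 69.5 min)
and `session_change_scenario` (10-edge path over 11 of 12 ROIs, +0.25 z
at 24 h persisting at 2 weeks, default missingness). The slopes and
shifts are free parameters — no empirical per-edge connectivity
distributions exist to calibrate them — chosen once as "clearly present
but not trivial" effects: per-edge associations around r ≈ 0.8 and
session shifts around 4× the estimation noise of a 300-volume z value
(≈0.06).

What the generator does **not** emulate: temporal autocorrelation is off
by default (rows i.i.d.; an AR(1) knob exists because band-passed BOLD is
autocorrelated, and it preserves the marginal covariance when on), and
there is no hemodynamic model, scanner noise model, or motion. Passing
calibration/recovery tests therefore demonstrates correctness of the
statistical machinery under the declared sampling model, not robustness
to every artifact of real acquisitions.

## Dual regression

Stage 1 regresses the k group maps (inputs — ICA estimation itself is
external to this package, and the mixture-model thresholding of ICA maps
is replaced by a plain Z ≥ 2.3 cut, stated openly) onto each volume,
giving subject time series; stage 2 regresses those series onto each
voxel's time course, giving subject maps. Both stages are plain OLS
without intercepts; variance-normalization of stage-1 series is off by
default, behind a flag. Session differences use paired t-tests on
matched subjects only, with FWE from the max-|t| distribution under
random sign flips of the difference maps.

## Problem sizes in the test suite

Monte-Carlo checks are sized to give stable verdicts at desk scale: 200
null cohorts × 500 permutations for GLM type-I calibration (band
[0.02, 0.08]); 100 null longitudinal cohorts × 500 permutations for the
LMM family-wise rate (band [0.02, 0.09]; an independent 400-simulation
measurement puts the underlying rate at ≈0.04); 50 seeds per recovery
scenario (success = a significant component with planted-edge Jaccard
≥ 0.6, required in ≥ 90% of seeds); component enumeration checked
exhaustively on all graphs with ≤ 4 nodes and on 1000 random graphs with
≤ 8 nodes.

## Known limitations

* The permutation component test models a random intercept only; a
  strong subject-by-session random structure would make its edge p-values
  conservative or liberal relative to the richer model used in single-edge
  fits. The two routes agree on the study-like designs tested.
* The inner–outer df rule is a convention, not an approximation to the
  sampling distribution; it is used deliberately to match the reference
  framework (it is what yields df = 56).
* Partial correlations assume an invertible covariance; with fewer time
  points than ~p + 3 the estimator refuses rather than regularizing
  silently.
* NIfTI support is a thin optional layer; the package's native exchange
  formats are TSV/CSV/JSON.
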