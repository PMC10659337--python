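# Methods

## The model

`flmm` fits function-on-scalar mixed regression to trial-structured,
event-aligned signals such as fiber-photometry ΔF/F. Each trial's signal
is a curve sampled on a common grid of S time-points (seconds relative to
the alignment event). At every time-point s an independent Gaussian
linear mixed model is fitted,

    Y_i(s) = X_i' β(s) + Z_i' γ_i(s) + ε_i(s),

where β(s) are fixed-effect coefficient functions shared across animals
and γ_i(s) are subject- (or session-) specific random deviation curves.
Random-effect structure is declared with lme4-style formulas, including
one level of nesting (`(x | id/session)` expands to subject and
subject-by-session groups). This "massively univariate" strategy makes
the fit embarrassingly simple per column while all cross-time structure
is recovered afterwards, when the confidence bands are built.

### Per-time-point estimation

Variance components are estimated by REML (ML optional). The relative
random-effect covariances Σ_g/σ² are parameterised by their Cholesky
factors, which enforces positive semi-definiteness; boundary (zero
variance) fits are accepted. σ² and β have closed forms given the
Cholesky parameters, and the marginal covariance is inverted with the
Woodbury identity on the stacked random-effect design, so one objective
evaluation costs O(n q² + q³) for q total random-effect columns. The
optimiser is L-BFGS-B with deterministic restarts (×0.1, ×10) on
non-convergence; columns that still fail are flagged, their estimates
linearly interpolated from converged neighbours, and excluded from
covariance estimation (more than 20% failures aborts with a request to
simplify the model). Column 0 is fitted from a fixed default start and
every other column starts from its solution, so results are identical
for any worker count.

AIC/BIC are always computed from the ML criterion evaluated at the
fitted components, summed over converged columns; comparisons across
models are refused unless the converged-column sets coincide. Trial rows
are internally re-ordered to a canonical (subject, session, trial) sort
before any sufficient statistic is accumulated, making every output
invariant to the on-disk row order.

### Smoothing

Raw coefficient functions β̃_k(s) are smoothed with penalised B-splines:
cubic splines on uniform, unclamped knots, K = min(⌈S/2⌉, 30) basis
functions, second-order difference penalty. With uniform knots the
Greville abscissae are equally spaced, so the penalty null space contains
exactly constants and linear functions, which pass through unchanged for
every penalty weight. One weight per coefficient function is selected by
generalised cross-validation on a fixed logarithmic grid (10⁻⁶…10⁸, 57
points); selection is deterministic given the input. The smoother is an
explicit S×S matrix H_k, so variance propagation below is exact. GCV is
known to undersmooth occasionally under pure noise; this affects only
the roughness of a displayed curve, not validity of the bands, because
the bands propagate whatever smoother was chosen.

### Cross-time covariance (method of moments)

The joint band needs Cov(β̂_k(s₁), β̂_k(s₂)) for all pairs. It is
assembled in three steps.

1. **Moment equations on OLS-projected data.** With P₀ = I − X(X'X)⁻¹X',
   the statistics Z_g'P₀Y(s) and the residual products e₀(s₁)'e₀(s₂)
   (e₀ = P₀Y) have expectations that are exactly linear in the unknown
   random-effect cross-covariances G_g(s₁,s₂) and the residual
   cross-covariance R(s₁,s₂); working in the projected space removes the
   fixed-effect estimation from the equations, avoiding the O(1/n)
   shrinkage bias a marginal-residual construction would carry. One small
   linear system (assembled once from the projected designs, including
   all cross-level and cross-group couplings that nesting creates) is
   solved simultaneously for all S² pairs.
2. **Surface stabilisation.** The G surfaces are estimated from as many
   cross-products as there are grouping levels and are therefore noisy;
   they are smoothed bivariately with a shared P-spline sandwich whose
   penalty is selected by a pooled GCV over all surface rows. The R
   surface, estimated from all trials, is left untouched.
3. **Sandwich, smoothing and the stabilised diagonal.** The raw
   cross-covariance is H(s₁)[Σ_g Z_g G_g Z_g' + R I]H(s₂)' with H(s) the
   per-column GLS hat matrices; pre/post-multiplying by the coefficient
   smoother gives the covariance of the smoothed estimator. Because the
   pointwise moment diagonal is far noisier than the constrained
   likelihood-based variances when grouping levels are few, the diagonal
   is anchored to the model-based REML variances, scaled by a single
   global smoothing-reduction factor (the trace ratio of the surface
   before/after smoothing). The matrix is symmetrised and projected to
   the nearest PSD matrix by truncating negative eigenvalues; the final
   diagonal defines the pointwise standard errors.

### Pointwise and joint bands

Pointwise intervals are β̂_k(s) ± z_{0.975}·se_k(s). The simultaneous
band replaces z by a multiplier q obtained from the distribution of the
maximum standardised deviation: draws Z ~ N(0, Corr) from the estimated
cross-time correlation, each divided by the square root of a simulated
variance field that mimics the sampling noise of the standard errors. In
a balanced cluster design the model-based variance of a coefficient
behaves like max(between-cluster sample variance, residual floor) over
the cluster count; accordingly the variance field is a Wishart-type field
(mean of df squared Gaussian curves, df = smallest grouping-level count
minus one, correlated along the grid like the raw coefficient covariance)
truncated below at the residual-variance share — the REML zero-boundary.
The multiplier's correlation and floor use the *unsmoothed* moment
surfaces: surface smoothing biases correlation upward, and the noisier
raw correlation errs on the conservative side. q is the empirical level
quantile over 10,000 draws (seeded; numpy PCG64; seed recorded in the
output), clipped from below at the pointwise normal quantile so the
joint band always contains the pointwise band. This max-t construction
is what brings simultaneous coverage to its nominal level with as few as
seven subjects; a plain Gaussian max multiplier undercovers noticeably
there (the per-replicate variance estimate itself has only ~6 degrees of
freedom). Each coefficient gets its own band; significance is reported
as maximal time intervals over which the chosen band excludes zero.

A cluster bootstrap over subjects (resampled with replacement, all
trials carried along, duplicates relabelled as distinct grouping levels;
B ≥ 200) provides percentile pointwise bands and a max-deviation joint
band for settings where the Gaussian working likelihood is in doubt.

## Synthetic data

The generator emulates a two-condition (short/long cue-reward delay)
photometry experiment: per subject one random intercept curve and one
random condition-slope curve, drawn from S×S covariances; per trial an
error curve drawn from `eps_scale × B_{m(i)}`, with `eps_scale = 5` and
M = 7 base matrices B that differ mildly in scale and correlation length
(mimicking animal-to-animal differences in noise); errors independent
across trials. The subject-to-base-matrix map draws indices uniformly
without replacement for n ≤ M; for n > M the first M are the identity
map and the remainder are drawn without replacement (in blocks when
n − M > M). Defaults: 15 Hz sampling on a −1…+1.93 s grid (S = 45), two
sessions of 100 trials, the condition switching between sessions, and
inter-reward intervals exponential with mean 14 s.

The true covariances of real recordings are not published, so the
defaults are parametric stand-ins: squared-exponential kernels
(intercept curve sd 0.25, slope curve sd 0.15, length-scale 0.5 s;
error base scale 0.35–0.65 with length-scales 0.15–0.3 s plus a 10%
white-noise nugget). Magnitudes were chosen once so that single trials
are noisy (per-point error sd ≈ 1.6 against transients of amplitude
≈ 1.5–2), session averages across seven subjects spread visibly, and a
window-summary t-test at n = 7 sits mid-range in power — i.e. the
comparison with summary methods stays informative. The true condition
effect is biphasic (positive early lobe +0.8, smaller negative late lobe
−0.3), so a window average dilutes opposing effects the functional fit
can resolve. User-supplied covariance matrices are accepted for exact
replication when available.

What the generator does *not* emulate: photobleaching trends, isosbestic
channels, photon-count noise, trial-length variability, or behavioural
exclusion rules. Passing tests therefore demonstrate the statistical
machinery under the stated Gaussian curve model, not robustness to those
artefacts.

The nested-trend ("Simpson") template makes session intercepts rise
(+0.4 per session on the response bump) while the signal falls across
trials within a session (−0.05 per trial), so a pooled summary
regression on cumulative reward number trends positive even though the
within-session trend is negative; the two-covariate functional fit
recovers both signs.

## Simulation experiments and problem sizes

Coverage/type-I experiments regenerate the truth per replicate, refit the
full pipeline, and tally (a) whether the joint band covers the entire
true coefficient function, (b) per-point pointwise coverage averaged
over the cue-period window, and (c) whether the joint band excludes zero
anywhere. The power experiment compares the joint band's detection rate
against a paired t-test and a scalar LMM (random intercept + condition
slope per subject, fitted with the same engine at S = 1) on the
cue-window mean summary, including a ±1-grid-step window perturbation
sweep. Every rate is reported with its binomial Monte-Carlo standard
error and seed; reports are bit-reproducible given (configuration,
seed).

The packaged experiment defaults run at desk scale: 7 subjects, 2
sessions × 40 trials, S = 45, 500 replicates for coverage/type-I and
200 for power. These sizes were chosen so the whole suite completes on a
single CPU in well under half an hour while keeping Monte-Carlo error
small relative to the acceptance regions.

## Numerical choices and conventions

- Window summaries: "mean amplitude" is the composite-Simpson
  time-integral divided by the window length (stable under sampling-rate
  refinement, exact for cubics); "integral" is the trapezoid rule.
  Baseline windows are subtracted in the same mode. The mode is always
  recorded in output metadata because the convention differs between
  labs.
- Covariate centering: numeric covariates are mean-centered by default
  (so the intercept is the mean signal at average covariates), 0/1
  condition indicators never are; the same centering applies wherever a
  covariate appears. Subtracted means are recorded.
- Categorical covariates are dummy-coded against the first level in
  sorted order (recorded); sorted rather than first-observed so designs
  are invariant to row order.
- Degenerate inputs: a constant curve passes through smoothing exactly
  (with a warning from GCV); zero-variance time-points collapse the band
  to the point estimate and are flagged; a paired t-test with exactly
  zero difference variance reports t = 0, p = 1.
- Tie-breaks: GCV takes the first minimum on the fixed grid; the
  multiplier quantile is the empirical `level` quantile (numpy default
  interpolation).
- Seeds: one integer seed drives everything; per-coefficient multiplier
  seeds are derived as `(seed + 7919 k) mod (2³¹−1)`, per-replicate
  experiment seeds from a seeded generator's integer stream.

## Known limitations

- The cluster-level degrees-of-freedom model for the joint multiplier is
  exact for balanced designs with a single grouping factor and an
  approximation (df = smallest level count − 1) under nesting or strong
  imbalance, where it errs conservative.
- Per-column case deletion for missing samples zero-fills the moment
  statistics; at high missingness the covariance surface degrades.
- AIC/BIC sums across columns ignore cross-column dependence; they are
  comparative tools, not absolute fit measures, and conditional AIC is
  not provided.
- The functional GLM (count likelihood) extension, time-varying
  covariates, and spline expansions of covariate effects are out of
  scope.
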