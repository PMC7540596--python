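# Methods

This note records the statistical model behind `fairreg`, the objective
functions exactly as implemented, the numerical choices, what the synthetic
generators do and do not emulate, and the design decisions taken where more
than one reasonable formulation existed.

## Setting and notation

Person-level data consist of an outcome Y (annual health spending, dollars),
a design matrix X whose columns are an intercept (default, switchable),
a female indicator, age, and T binary condition indicators H₁…H_T, and a
binary protected-group indicator A (group g, complement g^c; n_g, n_c
members; N total; empirical prevalence P = n_g/N). All fairness measures are
functions of the residual: we use the shortfall orientation r = Y − Ŷ
internally (`fairreg.metrics.residuals`), while net compensation reports the
payment orientation Ŷ − Y so that *negative means underpaid*. Both
orientations appear in the risk-adjustment literature; keeping them explicit
in one helper avoids silent sign bugs.

### Metrics

* Net compensation: (1/n_g)∑_{i∈g}(Ŷᵢ − Yᵢ); likewise for g^c.
* Mean residual difference: NC_g − NC_gc.
* Predictive ratio: ∑_{i∈g}Ŷᵢ / ∑_{i∈g}Yᵢ.
* Fair covariance: Cov(A, Y−Ŷ) with the **population divisor N**. For binary
  A it factorizes as P(1−P)(r̄_g − r̄_c). The same divisor is used inside the
  covariance-constrained estimator, so metric and constraint share a scale.
  (With N = 100 000 the N vs N−1 distinction is far below reporting
  precision.) The scaled variant divides by a reference c\* — by convention
  the OLS fit's covariance on the same data — giving 1 for OLS itself and 0
  for full collapse; it can be *negative* when a strongly penalized fit
  overcompensates the group, which is expected behaviour at large λ, not an
  error.
* R²: 1 − SSE/SST, reported as a percent; SST around the overall mean of Y.
  Out-of-sample values can be negative.

P is always the empirical in-sample proportion, never an external prior.
Currency values are rounded to whole dollars (ratios to 3 decimals, R² to
one) only in the presentation layer.

## Estimators

All six fits minimize a convex quadratic in θ with at most one linear
constraint, so each has an exact KKT closed form, used by default. The
equality-constrained solution is
θ = θ_OLS − (XᵀX)⁻¹d · [dᵀ(XᵀX)⁻¹d]⁻¹ (dᵀθ_OLS − b).

| method | constraint / penalty |
|---|---|
| ols | — |
| avg_constrained | dᵀθ = b with d = mean design row over g, b = ȳ_g |
| wavg_constrained(α) | same d; b = (1−α)ȳ_g + α·dᵀθ_OLS |
| cov_constrained(m) | Cov(A, Y−Xθ) ≤ m·c\*, one-sided (see below) |
| mrd_penalized(λ) | SSE + λ·MRD(θ)² (augmented normal equations) |
| netcomp_penalized(λ) | (1/N)[SSE + λ·∑_{i∈g}(Yᵢ−xᵢᵀθ)] |
| netcomp_constrained(z) | (1/n_g)∑_{i∈g}(Yᵢ−xᵢᵀθ) ≤ z |

Notes on the choices that were genuinely open:

* **Intercept.** Risk-adjustment formulas are often written without an
  explicit intercept (X = {female, age, H}); we include one by default
  because the residual-orthogonality and R² identities used throughout the
  tests rely on it, and expose `fit_intercept=False` for the traditional
  parameterization.
* **Covariance constraint.** Implemented one-sided (covariance below
  m·c\*), since the policy concern is the *under*-compensated side and a
  single inequality also optimizes faster; a `two_sided` flag adds the
  symmetric lower bound, which cannot bind at the one-sided optimum when
  c\* > 0. The constraint carries the 1/N of the covariance definition so
  that c = m·c\* is dimensionally identical to the reported metric. The
  strict "<" of the mathematical statement is implemented as "≤": solvers
  work on closed sets and the distinction is measure-zero at the optimum.
  c\* and θ_OLS are always computed on the same training data as the fit,
  never on held-out data. c\* ≤ 0 (group not undercompensated under OLS) is
  an error, not a silent sign flip.
* **Net-compensation penalty scale.** The penalty is the group's **total**
  shortfall residual, normalized together with the squared error by 1/N.
  This keeps λ in dollars and makes the penalty's pull proportional to the
  group's size: the closed form is θ = (XᵀX)⁻¹(Xᵀy + (λ·n_g/2)u_g), the
  in-sample group mean residual falls linearly in λ at rate P·u′/2 with
  u′ = u_gᵀ(XᵀX/N)⁻¹u_g, and the zero-crossing
  λ\* = 2·r̄_g(θ_OLS)/(P·u′) — exposed as `netcomp_lambda_star` — is
  independent of N. At λ = λ\* the penalized fit coincides *exactly* with
  the average-constrained fit (both move along the direction (XᵀX)⁻¹u_g,
  which is the fitted linear propensity of group membership); beyond it the
  group is overcompensated and the fair covariance goes negative. Under
  this scale the λ = N/10 rule of thumb sits below λ\* on the default
  generator, i.e. it buys a partial fairness improvement at a small R²
  cost. `lam_scale="fraction"` interprets λ as a fraction of the training
  fold's λ\*, making grids portable across outcome scales.
* **MRD penalty scale.** Kept on the raw sum-of-squares scale
  (SSE + λ·MRD²): the penalty is itself quadratic, so its leverage relative
  to the SSE is λ·vᵀ(XᵀX)⁻¹v, already dimensionless-in-N for λ ∝ N; the
  N-proportional default grid {N/100, N/10, N/5, 3N/10} produces the
  intended mild-to-moderate shrinkage.
* **Rank deficiency** is refused with the offending columns named (via
  column-pivoted QR): these coefficients are policy-interpreted, so a
  pseudo-inverse's arbitrary tie-break would be silently misleading.
* **Solver paths.** `solver="slsqp"` re-solves each program with
  sequential quadratic programming in QR-whitened coordinates (objective
  scaled by ∑y², constraints by the outcome SD) and accepts the result only
  if the solver converged and any constraint residual is below
  1e-6 × SD(Y); otherwise the fit falls back to the closed form and is
  flagged `solver_inaccurate`. The property suite asserts agreement of the
  two routes to 1e-6 relative on small random instances.

## Cross-validated evaluation

Five-fold CV, folds **stratified on A** by default so every training split
contains both groups (a feasibility requirement for the constrained fits);
plain random folds are available by flag. For each configuration the
held-out predictions are pooled into a single vector covering each person
exactly once, and the metric suite is computed on that vector — matching the
convention of evaluating formulas on cross-validated predictions. OLS is
always included and its pooled residual covariance supplies the reference
c\* for the scaled fair covariance; per-fold c\* values used *inside* the
covariance-constrained fits remain training-fold quantities. Hyperparameter
selection (`select_configuration`) maximizes the group predictive ratio
subject to a relative R² loss ceiling (default 10%).

## Synthetic spending population

The generator emulates a private-claims sample: N = 100 000 enrollees, 52%
female, ages 21–63 (Beta-shaped, median 45 — the shape within the range is
otherwise unconstrained and chosen unimodal), 62 condition indicators with
log-spaced prevalences (floor 5·10⁻⁴, i.e. ≥50 expected carriers at the
default N — the analogue of retaining only conditions with enough
enrollees; the floor is capped at 2% for small fixtures), and a 13.8%
protected group.

Spending is a **two-part model**: a Bernoulli(0.88) any-spending indicator
times a lognormal whose location is a linear function of covariates on the
log scale — condition effects decline with prevalence (0.9 rarest → 0.15
commonest), small female and age effects — plus a group-specific intercept
and shape. For each group the intercept c and shape σ are solved
numerically (Brent) so that, *conditional on the realized covariates*, the
expected sample mean and the population median equal the calibration
targets: means $11 520 / $5 880 and medians $3 744 / $1 274 for group and
complement, overall mean/median $6 651 / $1 511. The printed targets are
mutually inconsistent by ≈$7 in the overall mean (0.138·11 520 +
0.862·5 880 = 6 658); the generator calibrates the per-group moments and
lets the overall mean follow. Because only the conditional expectation is
pinned, sample moments retain genuine heavy-tailed Monte-Carlo noise — the
calibration test therefore compares across-seed means within three
Monte-Carlo standard errors over 20 seeds.

**Leakage mechanism.** Three "marker" conditions (base prevalence 0.5–3%)
are boosted on the odds scale among group members so that the markers carry
a fraction `group_signal_leakage` (default 0.5) of the group/complement
log-mean ratio; the group calibration constant absorbs the remainder as a
latent shift invisible to any regression on X. Markers get a moderate cost
effect (0.4) so their signal is concentrated prevalence, not price —
mimicking common diagnosis codes that identify a clinical group. At
leakage 1 the indicators carry the whole mean shift and OLS
undercompensation nearly vanishes (not exactly: a linear dollar-scale fit
of a multiplicative model retains a small misspecification residual); at
leakage 0 it is maximal. The default produces an OLS group predictive
ratio ≈ 0.84–0.87 and a positive fair covariance — the precondition c\* > 0
of the covariance-constrained method.

**A structural limit worth knowing.** With an intercept, the
average-constraint correction satisfies the exact identity
scaled_fair_cov(avg) = 1/u′ in-sample, and u′ ≤ 1/P with equality only when
group membership is perfectly linearly identifiable from X — at which point
OLS is no longer unfair at all. A generator (or dataset) therefore cannot
combine an arbitrarily large OLS undercompensation with an arbitrarily
complete covariance collapse under the hard constraint; the defaults sit at
u′ ≈ 3.3, i.e. the constrained fits collapse the fair covariance to
roughly a quarter-to-a-third of its OLS value in cross-validation rather
than to zero. Real claims data with no intercept and sharp diagnostic
markers can do better; tests assert the collapse, not an exact zero.

What the generator does **not** emulate: longitudinal (prior-year
predictors → next-year spending) structure, partial-year enrollment,
diagnosis-code-to-condition mapping, within-group correlation of condition
indicators beyond the marker boost, and any particular R² level (the
heavy-tailed two-part model yields cross-validated R² around 3–5%, lower
than typical adult risk-adjustment formulas; orderings among estimators,
not fit levels, are what the tests assert). Passing tests on this generator
show the estimators' *relative* behaviour under a realistic
undercompensation mechanism, not that any particular published number would
be reproduced on proprietary data.

## Simulation scenarios

A population of 100 000 with covariates x1–x3 ~ N(0,1), x4 ~ B(0.30),
x5 ~ B(0.20), x6 ~ B(0.25), x7 ~ N(0,1), x8 ~ U(0,1), x9 ~ B(0.5); two
partially overlapping protected classes A1 = {x6=1} ∪ {x5=1, x1>0.5} and
A2 = {x5=1} ∪ {x6=1, x2>0.25}; outcomes

* Y1 (complex): 8 + 2x1 + 1.5x2 − x3 + 2.5x4 + 10x6 + 1.2x1x4 + 0.8x2²
  + ε(1 + 0.6x4), ε ~ N(0, 2²) — nonlinearity, interaction, strong x6
  effect, heteroscedastic noise;
* Y2 (simple): 5 + 2x1 + 1.5x2 − x3 + 2x4 + 1.5x5 + 1.2x5x1 + ε — close to
  linear with one mild interaction;
* a purely linear form with configurable noise for well-specified limit
  checks.

Scenario 1 hands the estimators only x1–x5 (omitting x6, the main driver of
both Y1 and A1); scenario 2 hands them all nine covariates, four of which
never enter Y2. Forms and class rules are config-driven so alternative
recipes can be swapped in. The scenario-1 effect sizes were chosen so the
construction exhibits the intended mechanism: A1 is nearly unidentifiable
from the included covariates, so the hard group-mean/covariance constraints
can only raise the group's predictions by shifting *everyone's* predictions
— a cross-validated R² catastrophe (relative losses of hundreds of percent)
— while a small linear net-compensation penalty (fractions 0.05–0.1 of λ\*)
buys a proportional fairness gain at a quadratically small R² cost and
stays within a 10% relative-R²-loss frontier. Replicates (default 500 of
n = 1 000 or 10 000; the test suite runs 50 × 1 000 to keep the default run
in seconds-to-minutes) are drawn without replacement with per-replicate
seeds spawned from (seed, r), so any replicate is reproducible in
isolation. The scenario summary reports per-configuration across-replicate
means and SDs, and the frontier filter keeps OLS plus every configuration
that improved mean |NC_g| with a relative mean R² loss ≤ 10%.

## Numerical details and degenerate inputs

* Normal equations via Cholesky; OLS via LAPACK `gelsd`; equality
  constraints via the explicit KKT formula (single constraint — no need for
  a bordered system).
* Brent root-solving for the generator's (c, σ) calibration (σ bracketed in
  [0.05, 6]; an unbracketable target pair raises a calibration error) and
  for the marker odds boost γ.
* Empty group, constant group indicator, zero group outcome sum, zero
  outcome variance, zero reference covariance, negative penalty weights,
  α or m outside [0,1], non-positive z, and rank-deficient designs all
  raise informative errors rather than returning sentinel values.
* Determinism: every stochastic component takes an explicit seed;
  cross-validation results serialize byte-identically for identical inputs.

## Known limitations

* One protected group per fit; simultaneous multi-group constraints are out
  of scope.
* No standard errors or inference on the fairness metrics.
* The individual-level residual-comparison metric variant is not
  implemented (impractical at risk-adjustment scale).
* The SLSQP path is a cross-check, not a scalability claim; at N ≫ 10⁶ the
  closed forms remain exact but XᵀX assembly dominates.
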