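# Methods

This note records the statistical content of `tlagseq`: the model and
estimators, the conventions and numerical choices that a reimplementation
would need to match, and the limitations of the synthetic study conditions
used in the tests.

## Data structure

Full data per subject: entry calendar time E, arm A ∈ {0, 1}, baseline
covariates X, outcome Y, ascertainment lag T ∈ (0, T_F] in subject time, and
a time-dependent covariate path L(u) observed up to T. T_F is the maximum
follow-up; pr(T ≤ T_F) = 1 by design. At an interim analysis at calendar
time t the observed data for an enrolled subject (E ≤ t) are
C(t) = t − E, U(t) = min{T, C(t)}, Δ(t) = I{T ≤ C(t)}, Δ(t)·Y, and the path
truncated at U(t). Entry is assumed independent of everything else
(completely random staggered enrollment), which makes C(t) independent of
(X, A, T, Y, L̄) — the key identifying assumption. The first analysis must
come at least T_F after the trial starts so that pr{C(t) > T_F} > 0;
`build_interim_dataset` warns, and the estimators fail, otherwise.

## Outcome models and influence machinery

Treatment effects are marginal: difference of means E(Y|A=a) = α + βa, log
relative risk E(Y|A=a) = exp(α + βa), or proportional odds
logit pr(Y ≤ j | A=a) = α_j + βa. Each model is estimated through a
p-dimensional estimating function M(Y, A; α, β) with mean zero at the truth;
β is always the last parameter. The influence function of the β estimator is
m = G·M with G the last row of [−E ∂M/∂θ]⁻¹.

For the ordinal model the default weighting is "working independence":
with residuals r_j = I(Y ≤ j) − expit(α_j + βA), the estimating function
Dᵀ V_ind⁻¹ r collapses algebraically to −(r₁, …, r_{c−1}, A Σ_j r_j). This
form is exact, so its analytic Jacobian is the exact derivative of M; the
numeric-differentiation path exists only as a cross-check. The full
multinomial covariance (the ML score) is available behind
`full_covariance=True`; it is used in tests as an oracle against an
off-the-shelf ordered-logit fit, and the efficiency difference between the
two weightings is negligible in the settings studied here.

Solving: closed forms for the two 2-parameter models (weighted arm means),
Newton with analytic Jacobian and step halving for proportional odds,
convergence at ‖equation‖∞ ≤ 1e−9·n, initialization from pooled weighted
cumulative logits with β = 0. Degenerate cumulative probabilities (an empty
category among complete cases at an early look) raise an error suggesting a
later analysis time rather than returning a pinned estimate.

## Censoring model conventions

K̂_t(u, a) estimates pr{C(t) ≥ u | A = a} by the product limit over
censoring events (observations with Δ = 0), fitted per arm by default.
Two conventions are fixed deliberately:

- **Left-continuous evaluation.** Because the definition is "≥ u", the
  estimate at a subject's own U includes only jumps strictly before U. This
  is what makes the binary-outcome IPWCC estimator *algebraically identical*
  to the log-ratio of treatment-specific Kaplan–Meier event probabilities
  (verified to 1e−10 against an independent survival-curve fit), and it
  makes the inverse weights Δ/K̂ sum exactly to the arm size whenever the
  largest observation in the arm is an ascertainment.
- **Ascertainment before censoring at ties.** A complete case observed at
  the same time as a censoring event stays in the censoring risk set. Ties
  have probability zero under the continuous enrollment distributions used
  here but the convention matters for real data.

The cumulative hazard is exposed as Λ̂_c(u) = −log K̂_t(u) exactly. The
**martingale compensator**, however, uses Nelson–Aalen increments
dΛ̂_j = d_j/Y_j at the censoring jump times: with these increments the
counting-process identities hold exactly in finite samples — the sum of
dM̂ over an at-risk set vanishes at every jump, so the arm-sum of any
martingale integral with constant integrand is zero to machine precision,
and the step-2 "dependent variable" averages to zero exactly at the step-1
solution. Increments defined as differences of −log K̂ would violate these
identities at O(1/Y) per jump and blow up when K̂ reaches zero at a
trailing censoring event. The two choices are asymptotically equivalent;
all integrals are exact finite sums over jump times (no quadrature grid).

## The two-step augmented estimator

Step 1 solves the inverse-weighted estimating equation
Σ Δ_i M_i / K̂_t{U_i, A_i} = 0 for (α̂(t), β̂_init(t)), estimates G from the
weighted average Jacobian normalized by n(t), and forms m_i = G·M_i for
complete cases. Step 2 builds, per enrolled subject,

- Ŷ_i = Δ_i m_i / K̂ + ∫ dM̂_i(u, A_i)·q(u, A_i), where q(u, a) is the
  at-risk average within arm a of the inverse-weighted influence values;
- covariates (A_i − π̂_t) f_m(X_i) for m = 0..M (f₀ ≡ 1), and for each arm a
  and each h_ℓ a column I(A_i = a)·∫ dM̂_i(u, a)·[h_ℓ{u, X_i, L̄_i(u)} −
  μ̂(h_ℓ, u, a)] with μ̂ the at-risk arm average of h_ℓ;

regresses Ŷ on the covariates by one ordinary least squares pass (the
one-step update is not iterated), sets β̂(t) = β̂_init(t) − mean(Pred_i) and
SE{β̂(t)} = n(t)⁻¹{Σ(Ŷ_i − Pred_i)²}^½. AIPW1 uses the baseline columns
only; AIPW2 adds the martingale columns. m_i is evaluated at
(α̂(t), β̂_init(t)) in step 2, exactly as the update is defined. Collinear
columns (e.g. all-zero martingale columns when nothing is censored) are
handled by minimum-norm least squares with a warning; this is what makes
AIPW1 ≡ AIPW2 automatic at the final analysis.

Default bases — f = {1} ∪ components of X, h = components of X ∪ components
of L(u) — approximate the (unknown) optimal augmentation functions linearly
and are fully configurable through `BasisSpec`, including arbitrary
callables of (u, X, L̄(u)). Because the centering of each martingale column
uses the at-risk mean, the compensator part of each column sums to zero
exactly within its arm; the remaining dN part is mean-zero but random
(order √J per arm, J the number of censoring events), which the tests check
across replicates rather than within one sample.

## Information and monitoring

Inf(t) = SE{β̂(t)}⁻². Under fixed-sample monitoring the information fraction
is n_ESS(t)/n_max for the weighted estimators, with
n_ESS(t) = var̂{m}/SE{β̂(t)}²; var̂ is the inverse-weighted mean of m²
(IPWCC) or of (m − Pred*)² (both AIPW estimators), where Pred* comes from a
*weighted* least squares of m on the baseline columns — one formula serves
AIPW1 and AIPW2. m here is re-evaluated at the updated β̂(t) with the
step-1 G row. For the T_F-only comparator the fraction is nA(t)/n_max.
Because the re-evaluation at β̂(t) can move the ratio a fraction of a
percent off n at the final analysis, the fraction is pinned to exactly 1
when every planned subject is enrolled and fully followed; elsewhere
fractions above 1 (estimator noise at late looks) are clipped with a
warning, and the monitoring layer nudges non-increasing fraction paths up
by ε = 1e−6. Information-based monitoring against a prespecified maximum
information MI = {(z_{α/2} + z_γ)/β_A}²·IF is also supported; the inflation
factor IF is a user input (≈1.03 for O'Brien–Fleming boundaries).

Boundaries use Lan–DeMets spending: O'Brien–Fleming-type
α*(s) = 2{1 − Φ(z_{α/2}/√s)} and Pocock-type α*(s) = α ln(1 + (e−1)s), the
forms that reproduce the published boundary tables; one-sided designs spend
the whole α on one side, two-sided designs split it symmetrically. The
group-sequential recursion propagates the continuation-region subdensity of
the score S_j = Z_j √p_j on a trapezoidal grid (4000 points by default,
spanning 8.5 SDs; each stage's boundary solved by Brent's method to 1e−6).
Stage boundaries depend only on earlier fractions, so unplanned analysis
schedules are handled by construction, and an incremental spend below 1e−12
yields an infinite sentinel boundary. The recursion is validated in the
tests against direct Monte Carlo of the canonical correlated-normal joint
law. The Monte Carlo experiments pass a 400-point grid to the same
recursion; the induced boundary error (< 1e−4) is negligible against
simulation noise, and the deterministic results reported by the acceptance
script always use the full grid.

## Synthetic study conditions

- **Ordinal scenario** (n_max = 602, enrollment uniform on [0, 240] days,
  T_F = 90, looks at 150/195/240/285 and final at 330): a latent uniform Υ
  is warped in the treated arm to Γ = Υe^{−β}/(1 − Υ + Υe^{−β}), the unique
  reading of the generative transform under which
  logit pr(Γ ≤ u | A=1) = logit(u) + β exactly; categories from cutpoints
  (0, .12, .35, .52, .62, .67, 1) give control probabilities
  (.12, .23, .17, .10, .05, .33). Death (category 6) is ascertained at
  T ~ U(0, 30) (control) or U(20, 50) (treated); all other categories at
  T_F. X ~ N{1.5(Υ − .5), 1}; discharge time W = T_F Γ/0.52 for Γ < 0.52,
  else T_F; L₁(u) = I(W < u) and L₂(u) = (T_F − W) L₁(u). L₁ follows the
  indicator formula literally (despite reading as "has left hospital"
  rather than "still in hospital"); paths are right-continuous step
  functions, so the value *at* W is the post-change one — a
  probability-zero distinction for continuous C.
- **Binary scenario** (n_max = 900): same latent machinery with
  Y = I(Γ ≥ 0.67); at latent odds ratio 1.5 the treated event probability
  is 0.247 against 0.33, a log relative risk of −0.290, monitored with a
  lower-tailed alternative.
- **Continuous scenario** (n_max = 300, enrollment over 156 weeks,
  T_F = 52, looks at 104/130/156/182, final 208): longitudinal measurements
  at weeks (0, 4, 12, 24, 52) from a linear mixed model with categorical
  intercepts (65, 60, 55, 49) at probabilities (.4, .3, .2, .1), random
  intercept/slope covariance vech(D) = (80, −0.5, 0.08), residual SD 4.5,
  and arm-specific slopes ξ; the outcome is the week-52 value, the baseline
  covariate the week-0 value (the group label is deliberately withheld),
  and L(u) the last observed measurement. ξ = (−0.3, −0.18) implies a mean
  difference of 6.24.

Randomness is drawn as one row-per-subject uniform matrix per trial, so a
fixed seed yields bitwise-identical data and enlarging n_max preserves
earlier subjects. Replicates of the Monte Carlo driver are keyed by
(master seed, replicate index) and are independent of execution order;
failed replicates are logged, counted, and skipped.

These generators emulate the structure that matters for the estimators —
outcome-correlated lags, staggered entry, prognostic baseline and
time-dependent covariates — but idealize much of real trial conduct:
enrollment is exactly uniform and independent of covariates (no calendar
drift in case mix), censoring is purely administrative, there is no
missingness, no administrative reporting delay on top of T, and
randomization is exactly 1:1 Bernoulli. Passing tests therefore demonstrate
correctness of the estimators and boundary machinery under the stated
assumptions, not robustness to their violation (covariate-dependent entry
would call for the conditional-inference extension, which is out of scope).

## Simulation sizes used in tests

The acceptance checks run 2000 Monte Carlo replicates per scenario — enough
to pin estimator SDs to ~1.6% relative and rejection probabilities to ~0.004
absolute, which is the package's chosen verification scale for its
operating-characteristic claims; published reference values were computed
at larger replicate counts, and the test tolerances account for both
sampling errors. Deterministic quantities (boundaries, closed-form
identities) are checked to the precision printed in the reference tables.

## Known limitations

- Only two arms; no futility boundaries (efficacy-only monitoring); no
  sample-size re-estimation.
- Censoring must not depend on covariates (no Cox model for C); interval
  censoring of T is not supported.
- The optimal augmentation functions are approximated by linear bases; the
  conditional-expectation versions are not modeled.
- Proportional-odds inference conditional on X (logit = α_j + βa + ξᵀx) is
  an extension point, not implemented.
- The independent-increments structure of the sequential statistics is
  relied on (and checked empirically in the tests), not re-derived here.
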