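# Methods

## Model and scope

`relse` estimates standard errors for the statistics of a classical
reliability analysis under **multinomial sampling**: the N respondents'
response patterns on the variables entering a coefficient are treated as N
independent draws from a discrete distribution over patterns, so the
frequency vector **n** of the C *observed* patterns is one multinomial
draw. This assumes complete data (no imputation is attempted; missing
values are an error), independent respondents, and discrete scores — real
values are allowed and keyed on exact equality, but data in which nearly
every respondent has a distinct score make the pattern table as large as
the sample and the method is then not recommended.

Coefficients covered: mean, unbiased covariance/variance/SD, product-moment
correlation, split-half reliability (Spearman–Brown-stepped correlation of
two half sums, 2r/(1+r)), Guttman's λ₁ = 1 − Σs_j²/s_X², λ₂ = λ₁ +
√(k/(k−1)·C₂)/s_X² (C₂ = Σ_{i≠j} s_ij², ordered pairs), and
λ₃ = k/(k−1)·λ₁ (Cronbach's alpha), item-deleted variants, and the full
covariance matrix W of vec(S), the stacked inter-item variances and
covariances. Coefficients that involve sample maxima/minima (the rest of
Guttman's lambda series, optimal split halves) have no first-order
derivatives and are out of scope.

## The two-step procedure

Step 1 writes the coefficient as g(**n**) and obtains the Jacobian
G = ∂g/∂**n**. Step 2 applies the delta method with the estimated
multinomial covariance V(**n**) = diag(**n**) − **n n**ᵀ/N:
Var(θ̂) = G V Gᵀ, reducing to G diag(**n**) Gᵀ when g is homogeneous of
order 0. Only observed patterns are carried: unobserved patterns would
receive zero rows/columns in V and zero frequency, contributing nothing.

Two independent implementations of G are shipped and cross-checked:

* **Closed forms.** Exact derivatives in moment form. Notable identities:
  the ML-variance mean SE is √(σ̂²_ML/N) (the conventional s/√N, which is
  preferable in practice, is also exposed and used by default in the CLI);
  Var(s_xy) = N(m̂₂₂ − ĉ²)/(N−1)² exactly, with the large-sample option
  (m̂₂₂ − ĉ²)/N; SE(s) = SE(s²)/(2s); Var(r) = Σ_c n_c g_c² with
  g = (x̃ỹ − r(x̃² + ỹ²)/2)/N in ML-standardised scores;
  SE(SH) = 2/(1+r)²·SE(r); the lambda SEs compose the analytic gradient
  with respect to vec(S) with the pattern-level gradients of each s_ij
  (equivalently gᵀWg with W = Ĝ V Ĝᵀ); SE(λ₃) = k/(k−1)·SE(λ₁) exactly.
* **Generic exp-log engine.** Each coefficient is a chain of steps
  x ↦ φ(Ax + b) with φ ∈ {identity, log, exp, sqrt, reciprocal, square};
  the Jacobian is the product of per-step Jacobians. The affine offset b
  (constant, so it vanishes under differentiation) serves two purposes:
  pattern values are shifted per variable so every aggregate entering a
  log is positive (shifts leave variances, covariances, correlations and
  lambdas unchanged; the mean chain undoes its shift in a final affine
  step), and N−1 — needed by unbiased estimators — becomes expressible as
  a linear map of **n** plus a constant. Coefficients that are differences
  of ratios of positive aggregates are assembled by dividing each positive
  term separately in log space and differencing with a final linear step,
  so no log or sqrt ever sees a non-positive argument away from genuine
  boundaries. λ₂'s sum of squared covariances uses the square transform,
  which is sign-safe.

The suite verifies: closed form ≡ engine to relative 1e−8 (observed
~1e−13) on ≥50 random dichotomous/polytomous fixtures; chain-rule ≡
central-difference Jacobians to relative 1e−6 (step h = max(1e−6·n_c,
1e−8)); the homogeneity detector (scale constants {0.5, 2, 10}, relative
tolerance 1e−9) additionally asserts G·n = 0 and the equality of the full
and simplified variance forms; and Monte-Carlo calibration (below).

## Boundary cases and the ε-device

A coefficient on the boundary of its parameter space has no delta-method
SE. Tolerances: *at* boundary within 1e−12 (relative to the bound's
scale), *near* boundary within 1e−3 (flag only).

* Constant variable: covariance/variance SE is exactly 0 (flagged);
  correlations and SDs are undefined (error).
* Covariance at the Fréchet bound of its margins (comonotone or
  antimonotone coupling of the empirical marginals): no SE, error.
* Variance of a non-constant variable with vanishing delta variance —
  for a dichotomous item this occurs exactly at sample proportion ½,
  where the variance attains its upper bound: no SE, error. The
  simulation harness counts and omits such replications.
* |r| = 1: SE reported as 0 with an `at-boundary` flag; split-half at
  r_AB = −1 is undefined.
* λ₂ with all inter-item covariances zero: the gradient of
  √(k/(k−1)·C₂) is 0/0. The SE is computed by a descending-ε limit
  (the sqrt term replaced by √(k/(k−1))·ε·s̄², ε ∈ 1e−4…1e−10, stopping
  when successive SEs agree to 1e−6 relative); the limit equals the λ₁
  SE and the estimate is flagged `epsilon-device`.
* N = 2 is computed but flagged `low-N`; no small-sample corrections are
  invented.

## Confidence intervals

Wald intervals θ̂ ± z·SE; the mean alone uses a t quantile with N−1
degrees of freedom. Wald intervals are deliberately not clipped to the
coefficient's theoretical range (they are reported raw; near boundaries
they can overshoot, which is precisely the undercoverage phenomenon the
evaluation harness measures). Benchmarks: Feldt's F-interval for alpha
(df N−1 and (N−1)(k−1), applied to 1−α̂), the Fisher-Z interval
tanh(atanh r ± z/√(N−3)), normal-theory SEs (SE(s²) = s²√(2/(N−1)),
SE(s) = s/√(2(N−1)), SE(s_xy) = √((s_x²s_y² + s_xy²)/(N−1)) under
bivariate normality), and the Agresti–Coull interval for proportions,
used to judge simulated coverage: for a nominal 95% level observed over
2,000 replications it is [93.9%, 95.8%] (endpoints floored at one
decimal in percent).

## Data simulator

The population model is a two-dimensional five-parameter acceleration
model: P(score 1 | θ) = γ + (1 − γ − δ)·F(z)^ξ with
z = Σ_d w_d a_d (θ_d − b_d) and F the logistic function. γ is the lower
asymptote, 1 − δ the upper, ξ > 0 skews the response curve, a and b are
discrimination and location per dimension, and the fixed design weights w
set the loading structure. γ = δ = 0, ξ = 1 recovers the 2PL model, and
the generator reproduces 2PLM output bit-for-bit when handed neutral 5PAM
parameters at the same seed. Latent pairs are bivariate standard normal
with correlation ρ; a score is 1 when an independent uniform draw falls
below P.

Defaults (all configurable): ρ = 0.5; discriminations lognormal(0, 0.1);
locations evenly spaced on [−2, 2]; for the 5PAM γ, δ ~ U(0, 0.2) and
ξ ~ U(0.5, 2); one-dimensional cells set w = (1, 0); two-dimensional
cells give odd items w = (1, 0.5) and even items w = (0, 1). γ + δ = 1 is
admitted as the degenerate coin-flip case. Population coefficient values
are computed from a large generated sample (default 10⁶ respondents,
generated in 5·10⁵ chunks; Monte-Carlo error ∝ 1/√m).

What the simulator emulates: dichotomous educational/questionnaire item
scores with a unidimensional or two-dimensional trait, items spanning easy
to hard, and the boundary phenomena (an extreme-mean first item, a
maximum-variance middle item). What it does not emulate: polytomous
items, missing data, local dependence beyond the latent trait(s), or
respondent populations with non-normal traits — so passing tests support
the SEs' behaviour for well-behaved discrete data, not those settings.

## Evaluation harness

Per design cell: item parameters fixed once (deterministic child seed),
population values fixed once, then R replications (deterministic per-
replication seeds, order-independent). Per replication and coefficient:
estimate, SE, Wald CI; boundary replications are omitted and counted (the
denominators of coverage use post-omission counts). Reported: true SE
(SD of estimates across replications), mean SE, scaled bias
100·(mean SE − true SE)/true SE, coverage, and the Agresti–Coull band at
the used replication count. Flag rules mirror standard practice: coverage
outside the band, |scaled bias| > 10%.

The scaled-down reference study (one-dimensional 2PLM, k = 10, N = 2,000,
500 replications, master seed 1, population sample 10⁶) shows: scaled bias
within ±5% and coverage inside the Agresti–Coull band for the sum-score
mean and SD, the item-A/item-B covariance and correlation, the split-half
coefficient and the lambdas; expected undercoverage (~92%) for the
middle item's variance/SD, whose population value sits near the 0.25/0.5
bound; and much larger bias for the normal-theory benchmark SEs on
dichotomous data (≈ +16% for the sum-score SD, several hundred percent
for the near-boundary item SD). These numbers are recomputed, not stored,
by `scripts/acceptance.py` and the acceptance tests.

## Known limitations

* The SEs are first-order. At N = 100 the plug-in SE of the intricate
  coefficients (λ₁, λ₂, λ₃, split-half) underestimates the true sampling
  SD by ≈2.5–4% across every fixture family we examined (dichotomous and
  polytomous, k = 2…10, weak to very strong reliability); a 10,000-draw
  resampling experiment resolves this bias at more than 3 Monte-Carlo
  standard errors, and the corresponding calibration tests document it as
  expected failures at that sample size. At N = 500 and above all
  coefficients calibrate within Monte-Carlo error. The calibration
  fixtures for the well-behaved coefficients use tables with healthy cell
  expectations (a 9-level score for mean/variance/SD, 4-level pairs),
  since highly discrete two-point tables add curvature error of their own.
* Wald intervals near parameter-space boundaries undercover; the
  asymmetric Fisher-Z interval is preferable for correlations in small
  samples.
* Quasi-continuous scores make the pattern representation (and W
  especially) expensive; for such data a continuous-model SE is the
  better tool.
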