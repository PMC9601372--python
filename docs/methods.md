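# Methods

## Model

`simplexmm` fits Bayesian mixed-effects models for longitudinal proportions
y_ij ∈ (0, 1) observed on subjects i = 1..n at visits j = 1..n_i.  The
response follows the simplex distribution S⁻(μ_ij, σ²),

    p(y; μ, σ²) = [2π σ² {y(1−y)}³]^(−1/2) exp{−d(y; μ) / (2σ²)},
    d(y; μ)     = (y − μ)² / [y(1−y) μ²(1−μ)²],

a dispersion model on the open unit interval whose mean parameter μ equals
the distribution mean.  The conditional mean is linked to covariates through
the logit,

    logit(μ_ij) = x_ij′β + z_ij′b_i,

with fixed effects β (intercept included) and subject random effects b_i.

Two departures from the classical Gaussian mixed model define the package:

1. **Random effects — centered Dirichlet process mixture (CDPMM).**
   b_i ~ Σ_g π_g N_q(μ_g, Ω_g), truncated at G components, with
   stick-breaking weights π_g = ϑ_g Π_{ι<g}(1−ϑ_ι), ϑ_g ~ Beta(1, τ),
   τ ~ Γ(a₁, a₂); raw locations μ*_g ~ N_q(ξ, Ψ) with conjugate hyperpriors
   on (ξ, Ψ); diagonal component variances ω_gj with Gamma priors on the
   precisions, ω_gj⁻¹ ~ Γ(ω_a, ϖ_j), ϖ_j ~ Γ(ϖ_a, ϖ_b).  The component
   means are re-centered, μ_g = μ*_g − Σ_h π_h μ*_h, so the mixture mean is
   exactly zero and the fixed-effect intercept stays identifiable while the
   random-effect law remains absolutely continuous (it can be skewed,
   heavy-tailed or multimodal).  Setting `prior_kind="discrete_dp"` drops
   the centering; `prior_kind="gaussian"` collapses to a single zero-mean
   normal component.

2. **Fixed effects — Bayesian Lasso.**  β carries a Laplace shrinkage prior
   expressed as a normal scale mixture: β | H ~ N(0, diag(h²_k)),
   h²_k ~ Exp(ν²/2), ν² ~ Γ(ν²_a, ν²_b).  All conditionals are conjugate
   (inverse-Gaussian for the local precisions h⁻², Gamma for ν²), and
   variable selection uses the 95% credible-interval rule: a coefficient is
   declared null when its equal-tailed interval contains zero.  Every
   coefficient, including the intercept, is shrunk.

The dispersion has the conjugate prior σ⁻² ~ Γ(σ²_a, σ²_b).

## Default hyperparameters

G = 25; a₁ = 25, a₂ = 5 (concentration ≈ 5, favouring many distinct
clusters); ξ₀ = 0, Ψ₀ = I, c₁ = 11, c₂ = 2.5; ω_a = 3, ϖ_a = n (the subject
count), ϖ_b = 10; σ²_a = 1, σ²_b = 0.01; ν²_a = 1, ν²_b = 0.1.  These are
deliberately diffuse except where a structural constraint appears, noted
next.

**The ϖ conditional.**  Conjugacy of the rate parameters ϖ_j with the G
Gamma-distributed precisions ω_gj⁻¹ ~ Γ(ω_a, ϖ_j) gives

    ϖ_j | Ω ~ Γ(ϖ_a + G·ω_a, ϖ_b + Σ_g ω_gj⁻¹);

the shape term G·ω_a (each precision's Gamma likelihood contributes ω_a)
is essential: dropping it — a tempting simplification since it leaves the
update "looking conjugate" — makes the ϖ/ω feedback loop mean-unstable
whenever G·ω_a > ϖ_a, allowing a self-reinforcing collapse of cluster
variances toward zero; with the full shape, the loop's mean map has slope
G·ω_a/(ϖ_a + G·ω_a) < 1 and is unconditionally stable.  The prior-only
joint-distribution test detects the truncated-shape variant immediately
(E[ω] biased by ~30%).  As a pure safety net the sampler also floors
variances and rate parameters at 1e−12.

## Posterior computation

One sweep of the Metropolis-within-Gibbs sampler updates, in order: the β
block (MH), the Lasso scales h² and ν² (conjugate), σ⁻² (conjugate Gamma),
then the mixture blocks ξ, Ψ, ϖ, (π, ϑ), τ, μ*, Ω, labels L, and finally
each b_i (MH).  The scan order is fixed for reproducibility.

**Information-based MH proposals with exact Hastings correction.**  The β
proposal is N(β, s²Σ_β) with
Σ_β = [Σ_ij w_ij x_ij x_ij′ + H⁻¹]⁻¹, where
w_ij = E[d̈(y; μ_ij)] (dμ/dη)² / (2σ²) is the expected-information weight of
the simplex likelihood under the logit link.  Each b_i uses the analogous
N_q(b_i, s_i²Σ_bi) with Σ_bi = (Ω_{L_i}⁻¹ + Ξ_i)⁻¹ and Ξ_i the per-subject
expected information (an observed-Hessian variant is available behind
`bi_proposal="observed"`, with an automatic fall-back to the expected form
when indefinite).  Because these covariances depend on the current state
(through μ(β) and μ(b_i)), the proposals are *not* symmetric; the
acceptance ratio therefore includes the forward/reverse proposal densities.
Joint-distribution validation (below) showed that omitting this correction
— i.e. accepting on the plain target ratio — leaves a measurable bias in
the invariant distribution whenever the likelihood is weak, so the
corrected kernel is the only one implemented.

**Expected curvature table.**  E[d̈(y; μ)] has no closed form used here; it
is computed by adaptive quadrature on the logit scale (with subdivision
points seeded at ± a few spike widths √(σ²μ(1−μ)) around logit μ, where the
density concentrates) and, inside the sampler, served from a bilinear
lookup table of the log value over (logit μ, log σ²) ∈ [−8, 8] × [−6, 6],
accurate to about 1e−4 relative error at microseconds per point; queries
outside are clamped to the table edge.  Any deterministic approximation
here affects only proposal efficiency, never correctness, because the
Hastings ratio uses the same table on both sides.

**Likelihood-invariant translation move.**  When a random-effect design
column coincides with a fixed-effect column (here the intercept and the
observation time), the linear predictor is invariant under
β_k → β_k + δ, b_im → b_im − δ (all i).  The one-at-a-time scan mixes this
direction extremely slowly (integrated autocorrelation times in the
thousands), which at reduced chain lengths occasionally leaves an entire
replication with a large intercept error.  The sweep therefore appends a
joint translation Metropolis move along each such direction; because the
likelihood cancels exactly, its acceptance ratio involves only the β
shrinkage prior and the mixture prior of b, making the move essentially
free.  Its step size is tuned toward the scalar-optimal 0.44 acceptance.

**Step-size adaptation.**  s and the per-subject s_i are tuned by
Robbins–Monro on the log scale every 100 burn-in iterations toward
acceptance 0.25 and frozen afterwards, so the kept draws come from a fixed,
valid kernel.

**Centering in the conditionals.**  The label probabilities and the b_i
prior use the centered means μ_g (the model definition).  For the component
locations, the default update (`mu_star_mode="joint"`) draws all G
locations per coordinate as one G-variate normal — the exact full
conditional under centering, where every component enters every likelihood
term through the centering sum (a G×G Cholesky per coordinate, negligible
cost).  The per-component conjugate updates that ignore this coupling are
retained as `"offset"` (centered residual target) and `"literal"` (raw
target); they are exact for the uncentered `discrete_dp` prior, where all
three modes coincide.  The weight update π | L, τ (generalized Dirichlet)
ignores the dependence of the b-likelihood on π through the centering sum;
this is the one knowingly approximate conditional of the centered sampler,
kept because an exact update would lose conjugacy entirely.  Its effect is
quantified by the joint-distribution test below.

**Random variate generation** for S⁻(μ, σ²) inverts a tabulated CDF
(cumulative trapezoid of the density on a dense logit-spaced grid, refined
around the density spike), vectorized over distinct μ.  Accuracy: KS
distance ~5e−3 at n = 5·10⁴ against an adaptively integrated CDF, moment
errors below 0.3%.

## Validation strategy

* Conjugate updates are unit-tested against their closed-form moments by
  Monte Carlo from frozen states; the inverse-Gaussian sampler
  (Michael–Schucany–Haas) is cross-checked against an independent
  implementation and its analytic moments.
* The full sweep is validated by a joint-distribution ("getting it right")
  test on a tiny configuration (n = 5, n_i = 2, p = 1, q = 1, G = 3):
  forward prior/likelihood simulation versus alternating posterior sweeps
  with data regeneration must agree in distribution.  The test uses
  hyperparameters with finite fourth moments (shape-3 Gamma priors), and
  composes several MH kernel applications per sweep because the random-walk
  blocks are the mixing bottleneck at this scale.  The successive side runs
  16 independent chains each started from an exact joint prior draw, so
  per-chain averages are unbiased under the null regardless of
  autocorrelation and the across-chain spread gives an honest standard
  error; single-chain batch-mean errors are badly anti-conservative here.
* End-to-end behaviour is checked by a scaled-down Monte-Carlo replication
  study of the benchmark design (below).

## Benchmark simulation designs

The generator reproduces a standard benchmark: n = 100 subjects, n_i = 6
visits at t_j = 0.2j (j = 0..5), x_ij = (1, x1, x2, x3, t) with x1 = ±1
equiprobable and x2, x3 ~ N(0,1), z_ij = (1, t), β = (−0.45, 0, 0.45, 0,
0.45), σ² = 1.  Random-effects laws (both mean zero):

* `normal_gamma`: b_1 ~ N(0, 0.8) (variance 0.8, SD 0.894) and
  b_2 = g − 2, g ~ Γ(shape 4, rate 2) (SD 1.000, skewness 1);
* `normal_mixture`: b_1 ~ 0.6 N(−0.8, 0.5²) + 0.4 N(1.2, 0.5²) and b_2 its
  sign-flipped counterpart (SD 1.100, bimodal).

The second-argument conventions (variance 0.8 vs SD 0.5) are fixed by the
population-SD targets 0.894/1.000/1.100 and asserted in tests.  Designs 1–4
pair these laws with fitting priors: (1) normal_gamma + CDPMM, (2)
normal_mixture + CDPMM, (3) normal_gamma + discrete DP, (4) normal_mixture
+ Gaussian.

The replication driver reports, per coefficient, Bias (mean estimate −
truth), RMS (root mean squared error across replications) and F0 (the
percentage of replications whose 95% CI contains zero — high is good for
truly null coefficients, low for nonzero ones), plus estimated
random-effects means/SDs and quantiles of the density-recovery RMSE
(root-mean-square gap between the true b density and a Gaussian-KDE of the
posterior-mean b̂_i on an n_grid = 100 quantile grid; Silverman bandwidth).
The `est_sd` column is the cross-subject SD of the posterior means b̂_i
averaged over replications; the average posterior SD is reported separately
as `post_sd` since the two summarize different things (spread of point
estimates vs within-subject uncertainty).

**What the generator does not emulate:** missingness, unbalanced designs
driven by dropout, covariate measurement error, and dispersion that varies
with covariates.  Passing the benchmark therefore demonstrates correct
recovery under the stated sampling model, not robustness to those
violations.

## Problem sizes used in the shipped checks

Full-fidelity chains for this model run 7000 burn-in + 5000 kept draws with
three chains (EPSR < 1.2 is the working convergence rule, typically reached
well before 7000 iterations).  The package's own test battery uses reduced
budgets chosen to keep the whole suite desk-scale: the replication check
runs R = 50 replications of design 1 at 3000 burn-in + 2000 kept with one
chain per replication, which is sufficient for the qualitative pattern
(|Bias| < 0.10, RMS < 0.16, F0 high only for the null coefficients); the
joint-distribution test uses 1.5·10⁴ forward draws against 3·10⁴ sweeps
split over 16 equilibrium-start chains.  The acceptance script defaults to
R = 30 replications at 2000/1500 and accepts
`--replications/--burnin/--keep` to reproduce the full-scale study.

## Known limitations

* The intercept and the time slope are identified only jointly with the
  finite-sample means of the random effects; at n = 100 the sampling SD of
  mean(b_i1) is ≈ 0.09, which is the dominant contribution to the RMS of
  β0 and β4 in the benchmark (the translation move keeps the sampler
  mixing across this direction, but the information limit is intrinsic to
  the design).
* The π | L, τ update is approximate under centering (see above).
* G is fixed (default 25), not learned; slice/retrospective samplers for
  the untruncated process are out of scope.
* Responses exactly 0 or 1 are rejected, not squeezed, by default (the
  simplex support is open); `--squeeze` on the CLI opts into the
  (y(N−1)+0.5)/N transform.
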