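# Methods

This note documents the statistical model implemented in `zicopula`, the
numerical choices behind the fitter and simulator, what the built-in
fixture communities do and do not emulate, and the package's known
limitations.

## Generative model

A community of `p` microbial features is parameterised by per-feature
marginals `(π_j, μ_j, σ_j)`, a copula correlation structure, and a depth
model:

- **Marginals.** Absolute abundance `A_j` is zero-inflated log-normal:
  `P(A_j = 0) = π_j` (biological absence) and
  `log A_j | A_j > 0 ~ N(μ_j, σ_j²)`. `μ` is in (unitless) log-abundance
  units; since only relative abundances are observed, `μ` is identified
  only up to a shared additive constant and the fitter pins `Σ_j μ_j = 0`.
- **Copula.** A latent Gaussian vector `g ~ MVN(0, R)`, `R = Ω⁻¹` with
  unit diagonal, couples the features: `A_j = F_j⁻¹(Φ(g_j))`, which is
  zero exactly when `g_j < Φ⁻¹(π_j)`. `Ω` is stored as the precision
  matrix; `R` is obtained by inversion followed by symmetric rescaling to
  unit diagonal (symmetrising with `(M + Mᵀ)/2` against round-off).
- **Observation layers.** `X = A / ΣA` (compositional), integer depth
  `D = max(1, round(LogNormal(μ_D, σ_D²)))`, and
  `C ~ Multinomial(D, X)`, which adds technical zeros at low depth.

A sample whose `A` is entirely zero has no defined composition; the
simulator redraws such samples (up to 100 attempts) — an event with
negligible probability under realistic parameters.

## Likelihood and its approximations

The density of an abundance vector with zero coordinates multiplies the
copula density over the non-zero block (copula × Jacobian of the marginal
quantile map) by the probability of the latent orthant
`{g_j ≤ Φ⁻¹(π_j)}` for the zero block, conditional on the non-zero
scores. The likelihood of an observed composition `x` further integrates
over the latent total `t = log A^Σ` (the counts enter through the plug-in
`x̂ = C / ΣC`, accurate at modern sequencing depths).

Numerical choices, in decreasing order of consequence:

- **Orthant probability.** `log_density_absolute` evaluates the
  conditional-Gaussian orthant probability by quasi-Monte Carlo
  (scipy's Genz algorithm; `n_mc` points, default 4096, seeded and
  reproducible). Inside the EM and cross-validation loops this would be
  evaluated tens of thousands of times per iteration, so there the
  orthant factor is replaced by a one-pass conditional-independence
  surrogate: the product of univariate normal CDFs with means conditioned
  on the non-zero scores and variances from the conditional covariance
  diagonal. The surrogate is exact when zero features are conditionally
  uncorrelated and was measured within ~1 natural-log unit of the QMC
  value under strong conditional correlation; because the same surrogate
  is used for every candidate λ, the bias largely cancels in
  cross-validation comparisons.
- **Quadrature over the latent total.** The conditional density of `t`
  given `x` is integrated by Gauss–Legendre quadrature (default 64
  nodes) on a window of ±8 SD around an independence (Laplace-style)
  Gaussian approximation with precision `Σ_j σ_j⁻²`; if the posterior
  mass touches the window edge the window is re-centred once and widened.
  With π = 0 this is exact to quadrature accuracy (verified against a
  10⁴-node dense grid to 1e-4).
- **Latent scores.** For the M-step moment matrix, non-zero entries get
  the deterministic score `g_j = Φ⁻¹(F̂_j(A_j))` evaluated at the
  posterior-mean total; zero entries get the mean and variance of a
  normal truncated above at `Φ⁻¹(π_j)`, conditioned on the non-zero
  scores in one pass (no joint truncated-MVN sampling). Scores are
  clipped at ±8 to keep the linear algebra finite.

## Penalized EM

- **Initialisation.** Moments of the log non-zero relative abundances
  give `μ⁰, σ⁰` (σ floored at 1e-3 against degenerate quantile maps);
  `π` is the empirical zero fraction — exact, and never updated, because
  `X_j = 0 ⇔ A_j = 0`. The initial correlation is the latent-score
  correlation shrunk 10% toward the identity and eigenvalue-clipped to
  stay positive definite.
- **E-step.** Per-sample log-likelihood and posterior moments
  `E[t], E[t²]` as above.
- **M-step.** `μ, σ` have closed-form weighted Gaussian maximizers over
  non-zero entries using `E[t], E[t²]`; `μ` is re-centred to sum to zero.
  `Ω` is re-estimated by graphical lasso (scikit-learn) on the expected
  latent second-moment matrix, penalising off-diagonals only.
- **Convergence.** Relative change of the penalized objective below 1e-4
  (default) or 100 iterations. Non-convergence flags the result rather
  than raising.
- **Monotonicity caveat.** The penalized objective is monotone (to
  quadrature noise) once EM is underway in the π = 0 regime, where the
  E-step is exact. Two deliberate exceptions: (i) the moment-based
  initialiser sits on the compositional non-identifiability ridge — a
  common log-normal factor added to all features trades `σ²` inflation
  against equicorrelation while leaving the distribution of `X`
  unchanged — and the first penalized M-step steps off that ridge, which
  can raise the objective once; (ii) with zero inflation the truncation
  surrogates leave ~1e-3-relative non-monotone drift. The fitter
  therefore monitors settling, not strict descent.
- **λ selection.** K-fold cross-validation (5 folds by default) on mean
  held-out log-likelihood over a grid defaulting to 10 log-spaced values
  on `[0.01, 1] × sqrt(log p / n)`; fold assignment is a seeded
  permutation. CV-fold fits run with a reduced iteration cap (default
  25) — λ ranking stabilises long before full convergence.
- **Depth.** `(μ_D, σ_D)` are the ML mean and population SD of log
  column totals, fitted independently of the EM. Relative-abundance
  input carries no depth information; a placeholder of
  `LogNormal(log 10⁴, 0)` is used unless the caller supplies one.

## Simulation and new features

Simulation draws each layer with an independent child stream of one root
seed, so enlarging `n` or adding layers never perturbs earlier draws, and
a null spike-in is bit-identical to plain simulation at equal seed.

"New" features are drawn from a 3-D Gaussian kernel density estimate over
the fitted per-feature triplets, on the transformed scale
`(logit π, μ, log σ)` so that every sampled triplet back-transforms to a
valid parameter set. (Modelling `log σ` rather than `σ²` is this
package's choice; the logit transform for π follows the same rationale.)
Bandwidths use the per-dimension normal-reference rule; sampling picks a
training triplet uniformly and adds kernel noise. Boundary π values are
clamped to `[1/(2 n_fit), 1 − 1/(2 n_fit)]` (with a warning) before the
logit.

## Association spike-in

Effects are specified on the *absolute* scale, so spiked and null
features stay cleanly defined: `μ_ij = μ_j + Z_i'β_abundance` (log fold
changes) and presence log-odds shifted by `Z_i'β_prevalence` (log odds
ratios). Effects compose additively across covariates; interactions are
out of scope. Feature pairs are correlated through a hidden standard-
normal covariate with matched abundance and prevalence effects (sign
flipped on one feature for negative association); hidden covariates are
independent across pairs. A prevalence effect on a feature with `π = 0`
is an error (its presence log-odds are infinite).

Feature selection for spike-in protocols ranks by prevalence (descending)
or by distance of prevalence from 0.5 (ascending), taking
`ceil(fraction · p)` features by default (`floor` is available); ties
break deterministically by mean non-zero abundance, then feature ID.

Compositional leakage is real and intended: a +1 log fold change on
absolute abundances recovers as slightly less than +1 on relative
abundances (and −1 as slightly more negative), because spiked features
shift the totals. With a balanced ±1 design on 16 of 320 fixture features
the systematic gap stays below 0.1 log-units.

## Evaluation statistics

Bray–Curtis `Σ|x−y| / Σ(x+y)`; PERMANOVA R² from the classical
distance partition `(SS_T − SS_W)/SS_T` (deterministic; permutation
p-values optional and seeded; single-group input returns 0); two-sample
Kolmogorov–Smirnov with zeros counted as values. Effect recovery uses
OLS on log non-zero relative abundances and logistic regression on
presence, both with normal-theory 95% CIs. The benchmarking grid spikes,
simulates, tests and adjusts per replicate — Bonferroni by default,
Benjamini–Hochberg by flag — reporting mean and standard error of power
and FDR per (effect size, sample size) cell; its built-in test is a
per-feature linear model on log(relative abundance + half the minimum
positive value), so the harness is self-contained; external tools plug in
as `test(counts, covariate) -> p-values` adapters.

## Fixture regimes

`gut_like` (moderate π in 0.2–0.8, μ uniform over ~3 log-units, σ in
0.5–1.5, sparse weak precision off-diagonals), `vaginal_like` (2–3
dominant near-always-present features with mutual negative correlation
over a sparse background) and `dense_small` (p ≤ 10 with two known strong
correlations, +0.6 and −0.5, for oracle and sign-recovery tests). Depth
defaults: `μ_D = log 2·10⁴`, `σ_D = 0.3`. These are qualitative
engineering stand-ins for real community archetypes: passing tests show
the machinery is self-consistent (fit inverts simulate, spiked effects
are recovered, same-law controls are indistinguishable), not that any
real dataset is matched. Real data additionally exhibit population
substructure, non-log-normal rare-taxon tails and depth–composition
dependence, none of which the fixtures emulate.

Test and acceptance problem sizes (p up to 320 features, n up to 10⁴
samples for simulation checks, n = 500–1000 for fitting checks, 50
replicates for the harness grid) were chosen so the full suite exercises
every code path at statistically meaningful scale.

## Known limitations

- The count-level likelihood is the plug-in approximation; exact
  integration over the multinomial layer is out of scope, so fits to
  very shallow sequencing (depths ≪ 10³) inherit plug-in bias.
- No standard errors or confidence intervals on fitted parameters.
- `Ω` (and hence `σ`) is only regularisation-identified: models on the
  common-factor ridge described above are observationally equivalent, and
  the L1 penalty, not the data, picks the sparse representative.
- Features never present must be dropped before fitting (`π = 1` has no
  quantile branch); features present in fewer than two samples are
  rejected.
- No longitudinal correlation structure; subject-level random-effect
  covariates via the spike-in are the available workaround.
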