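# Methods

This note documents the models, numerical choices and limitations of the
`thcdea` pipeline in the order the stages run.

## Slacks-based efficiency measurement

Each province-year is a decision-making unit (DMU) with m = 5 inputs and
s = 4 outputs, all required strictly positive (the SBM objective divides
by every evaluated input and output; zeros are rejected at load time
rather than imputed). The non-oriented SBM under variable returns to
scale (VRS, convexity constraint Σλ = 1) is a linear-fractional program;
we solve it exactly after the Charnes–Cooper transformation — every
variable is scaled by t > 0 chosen so the denominator equals one — with
scipy's HiGHS solver (dual feasibility tolerance well below 1e-8), then
divide the optimal variables by t to recover λ and the slacks.

Units whose SBM score reaches 1 − 1e-6 (`EFFICIENT_TOL`, chosen at LP
tolerance scale) are re-scored with the super-efficiency SBM, which
removes the evaluated unit from the reference set and searches for the
cheapest enveloped projection with x̄ ≥ x₀ and ȳ ≤ y₀; its optimum is ≥ 1,
which is how efficient provinces are ranked among themselves. Under VRS
the super program can in principle be infeasible; such cells are recorded
with score 1 and an `infeasible` stage tag so the score table stays total.
Each year is scored against its own frontier, matching the year-by-year
columns of the published score table.

The score-panel output reproduces the published convention: values below
one are plain SBM inefficiencies, values at or above one come from the
super model. Certificates (λ, slacks, targets) are returned with every
score and are verified in tests to satisfy the envelopment constraints at
1e-6 and to reproduce the reported objective.

## Global Malmquist index

Productivity change between adjacent years is measured against the pooled
all-period reference set, which makes the index transitive:
MI = E^g(t+1)/E^g(t). The catch-up term EC compares each year's score
against its own contemporaneous frontier, and TC is defined as MI / EC,
so the decomposition identity holds to machine precision by construction.
Inside the Malmquist computation we use the *plain* (non-super) SBM:
every evaluated point belongs to its reference set — pooled or
contemporaneous — so all sub-scores are feasible and lie in (0, 1];
super-efficiency is reserved for the score table. If a point is evaluated
against a reference set it does not belong to (the general
`efficiency_vs_reference` entry point), an infeasible plain program falls
back to super-efficiency semantics.

Per-unit summaries are geometric means over the T − 1 adjacent pairs
(geometric averaging is the index-number convention and preserves
MI = EC × TC at the unit level); the national summary is the arithmetic
mean across units, which matches the published summary row. Note that the
published per-province means do **not** satisfy the product identity
beyond rounding (discrepancies up to 0.028), so their averaging was
evidently not geometric in all three columns; our tables are internally
consistent instead.

## Spatial autocorrelation

The weight matrix is first-order rook contiguity over the 29 study
provinces, with Hainan linked to Guangdong so that no row is empty; the
edge list ships as a fixture and is the declared reference for all Moran
computations (it reproduces the published Moran values to three decimals,
which is strong evidence it matches the unprinted original matrix). The
default standardization is row-stochastic; binary weights are exposed for
sensitivity analysis.

Global Moran's I uses the Cliff–Ord moments: expectation −1/(n−1) and,
by default, the randomization-assumption variance (which involves the
sample kurtosis), with a two-sided normal p-value; a Monte-Carlo
permutation p-value (pseudo-p convention, (count+1)/(perms+1)) is
available. Moran-scatter quadrants classify each unit by the sign of its
demeaned value and of the row-standardized lag of demeaned values; exact
zeros are assigned to the positive side (they cannot occur with 3-dp
data). The agglomeration share is (|HH| + |LL|)/n.

## Spatial panel econometrics

The spatial Durbin model with two-way fixed effects is estimated by
quasi-ML with the likelihood concentrated in the scalar spatial
parameter. Three numerical points matter:

- **Lag-then-demean.** Cross-section demeaning does not commute with a
  row-standardized W (row sums are one, column sums are not), so spatial
  lags are computed on the raw data and then within-transformed. The
  demean-then-lag order produces a severely biased ρ̂ (bias ≈ 0.12 at
  n = 29, T = 10 in our simulations).
- **Transformation likelihood.** Demeaning the time dimension removes one
  period; demeaning the unit dimension removes the constant eigenvector
  of W, whose eigenvalue is exactly 1. The default likelihood therefore
  uses effective dimensions (n−1) and/or (T−1) and drops the unit
  eigenvalue from the log-Jacobian T·Σ ln(1 − ρωᵢ); this keeps the
  two-way fixed-effects QMLE consistent at moderate n. The naive demeaned
  likelihood is available via `transform=False`.
- **Optimizer.** Bounded scalar minimization over
  (1/ω_min + 1e-6, 1 − 1e-6) with tolerance 1e-10; an optimum within
  1e-5 of the boundary raises with diagnostics. σ² is the transformed
  residual variance; standard errors come from the analytic information
  matrix with trace terms evaluated on the within-projected lag operator.
  R² is reported as the squared correlation of reduced-form fitted values
  with the (demeaned) response.

Under the default study-condition DGP (n = 29, T = 10, ρ = −0.155,
published coefficient vector, σ = 0.07), 200-replication simulations give
|mean ρ̂ − ρ| < 0.005 and ≈ 92% empirical coverage of nominal-95% Wald
intervals for β.

**Specification tests.** The LM lag/error scores on within-transformed
pooled OLS residuals have nonzero null means because the within projector
does not commute with W; instead of the classic trace formulas we center
each score at its exact normal-theory null mean and scale by its exact
null variance under the combined demeaning-and-residual projection
(n·T-dimensional matrices; trivial at this size). The robust variants
partial one centered score out of the other with their analytic
covariance — the textbook robust LM is the special case with zero means
and the classic traces. Likelihood-ratio tests apply the Bartlett-type
factor (N − K)/N (N = effective sample size, K = full-model slope count):
for Gaussian likelihoods LR = N·ln(RSS₀/RSS₁) has null mean ≈ qN/(N−K),
and the scaling restores χ²(q) calibration (simulated size 0.04–0.06 at
nominal 5%). The SDM→SEM degradation is tested through the common-factor
restriction θ = −ρβ by the delta method.

**Random effects and Hausman.** The random-effects fit (needed only by
the Hausman test) keeps time effects fixed, estimates the variance
components from within and between residuals (Swamy–Arora-type moment
estimators), quasi-demeans by 1 − √(σ_ν²/(Tσ_μ² + σ_ν²)), and maximizes
the same concentrated likelihood. The Hausman contrast uses the slope
coefficients; when V_FE − V_RE is not positive definite (common in finite
samples) the statistic is computed on the positive-eigenvalue subspace
with df = its dimension, and the fallback is noted in the result.

**Effects.** For regressor k, S_k(W) = (I − ρW)⁻¹(β_k I + θ_k W); the
direct effect is the mean diagonal, the total effect the mean row sum,
and the indirect effect their difference (total = direct + indirect holds
exactly). Inference simulates 1000 multivariate-normal parameter draws
(default seed 20240816) from the fit's covariance and reports the
draw mean/sd normal p-values.

## Synthetic data generators

Both generators are pure functions of (config, seed).

The DEA generator drives each unit by a latent activity level a: outputs
are proportional (y_r = d_r·a) and the efficient input requirement is
x_i = c_i·a^γ with γ = 1.4 > 1, i.e. a convex input requirement and hence
a strictly concave VRS frontier on which every zero-inefficiency unit
lies by construction. Inefficiency inflates inputs by exp(u) with u
half-normal of scale 0.3 (input-side only — the simplest DGP consistent
with a non-oriented measure), and a drift parameter shifts the frontier
over time. The technology directions c, d are shared across units, which
is what guarantees frontier membership at zero inefficiency; real panels
have heterogeneous input mixes, so passing recovery tests here says
nothing about mix-driven allocative effects.

The covariate generator draws 13 independent series at the published
descriptive moments — lognormal for positively skewed levels (population
density, GDP per capita, incomes, traffic volume), normal clipped to the
observed ranges for bounded shares. The published maximum of the urban-
population share (5042%) is physically impossible, so that series is
clipped to [0, 100] with a plausible spread; no cross-covariate
correlation is imposed (none is published). The spatial-Durbin generator
builds the response through the reduced form
y_t = (I − ρW)⁻¹(X_tβ + WX_tθ + μ + γ_t + ε_t) with defaults at the
study conditions: the 29-province contiguity matrix, T = 10, ρ = −0.155,
the published SDM coefficient vector, σ = 0.07, and N(0, 0.1²) unit and
time effects. Because the covariates are independent of the effects, the
exogeneity assumptions of the estimators hold by construction; the
generators do not emulate endogeneity, measurement error, or serial
correlation, and results on them certify the estimators, not the
substantive findings.

## Problem sizes and determinism

The default test-suite problem sizes are the study dimensions (29 × 10)
for single fits and 100–500 replications for calibration checks; DEA
property tests use 2–8 units, where the independent simplex-grid oracle
(resolution 1/50 with four shrinking refinement stages; valid because the
SBM objective is quasiconvex over the feasible region) is sharp. The
pipeline is deterministic given (config, seed): identical runs produce
byte-identical artifacts, and every emitted table carries the seed in a
header comment.

## Known limitations

- Undesirable outputs (e.g. medical expense burdens) are outside the SBM
  model; no bad-output extension is provided.
- The published coefficient tables cannot be reproduced without the
  original yearbook covariate panel, which has no public deposit; the
  estimators are instead validated by parameter-recovery simulation at
  the published operating point.
- Random-effects estimation is the feasible-GLS approximation described
  above, not full joint ML over variance components.
- The printed per-province Malmquist means violate MI = EC × TC beyond
  rounding for several provinces (up to 0.028); this package's own tables
  preserve the identity exactly and therefore cannot match those rows.
- No distance-based or k-nearest-neighbor weights; the contiguity fixture
  is the single supported geography.
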