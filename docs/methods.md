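# Methods

## Model

The package implements a factor-augmented vector autoregression with
time-varying parameters and stochastic volatility (SV-TVP-FAVAR) for
studying how economic-policy-uncertainty (EPU) shocks transmit to fiscal
healthcare expenditure.

A high-dimensional quarterly panel of n macro indicators x_it is compressed
into k latent common factors f_t.  The augmented vector
y_t = [f_t', z_t', m_t]' (factors, core observables z_t with the
expenditure series ordered last among them, and the EPU index m_t) follows
a VAR(p) whose coefficients drift as random walks:

    y_t = b_1t y_{t-1} + ... + b_pt y_{t-p} + nu_t,   nu_t ~ N(0, Omega_t)
    B_t = B_{t-1} + eta_t^B,                          eta^B ~ N(0, Q_B)

with B_t the column-major stacking of the b_jt.  The reduced-form
covariance is identified recursively through the triangular decomposition

    Omega_t = A_t^{-1} Sigma_t Sigma_t' A_t^{-1}',

where A_t is unit-diagonal lower triangular (free elements alpha_t, a
random walk with covariance Q_alpha) and
Sigma_t = diag(sigma_1t, ..., sigma_mt) with log sigma_t a random walk
(covariance Q_sigma).  With variables ordered [f, z, m], the EPU
innovation is the last orthogonalized shock: it may affect every variable
contemporaneously only through its own column, and the expenditure
response to it starts at horizon 1 — which is where the pro-/counter-
cyclicality question lives.

The panel links to the augmented vector through the factor equation

    x_it = lf_i' f_t + lz_i' z_t + lm_i m_t + u_it,

with idiosyncratic AR(q) errors u_it whose innovations carry their own
stochastic volatility, eps_it ~ N(0, exp(2 h_it)).  Throughout the code
h denotes a log *standard deviation* (so variances are exp(2h)).

## Estimation

Bayesian, by block Gibbs sampling:

1. (joint mode only) latent factors, via the Durbin–Koopman
   mean-correction simulation smoother on the companion state
   xi_t = [y_t', ..., y_{t-p+1}']' — the transition noise covariance is
   singular, which the mean-correction construction handles exactly;
2. loadings: per-series conjugate Gaussian regressions after
   quasi-differencing by the idiosyncratic AR polynomial and weighting by
   exp(-2 h_it);
3. idiosyncratic AR coefficients: conjugate draws, rejection-sampled to
   the stationary region;
4. idiosyncratic and VAR volatilities: the Kim–Shephard–Chib (KSC)
   7-component normal mixture approximation to log chi-squared(1), turning
   log(resid^2 + 1e-4) into a conditionally linear-Gaussian model;
5. B_t and alpha_t paths: Carter–Kohn forward-filter / backward-sampler;
6. Q_B, Q_alpha (blocked by equation row), Q_sigma: conjugate
   inverse-Wishart updates.

A block's time-variation indicator set to false pins its innovation
covariance to exactly zero; the Carter–Kohn wrapper special-cases Q = 0 and
returns a constant path drawn once from the final filtered distribution, so
the fixed-coefficient VAR is recovered to machine exactness rather than up
to numerical noise.

Priors follow common Bayesian-VAR practice: B_0 ~ N(Bhat, Vhat) with 0.9 on
each own first lag and Minnesota-form variances (overall tightness 0.05,
cross-equation 0.5, lag decay 1/lag^2, scaled by per-equation AR(p)
residual variances); alpha_0 ~ N(0, 4I); log sigma_0 ~ N(0, 4I); and

    Q_B     ~ IW(0.005 (dim B + 1) Vhat, dim B + 1)
    Q_alpha ~ IW(0.01  (dim_j + 1) I,    dim_j + 1)   per row block j
    Q_sigma ~ IW(0.0001 (m + 1) I,       m + 1).

Sampler defaults are 10,000 sweeps, 2,000 burn-in, thinning 5; tests and
the bundled studies use much shorter, explicitly stated chains.  All
randomness flows through one seeded `numpy.random.Generator`; identical
seed and configuration reproduce every retained draw bit-for-bit.

### Two-step versus joint mode

The default `two_step` mode fixes the factors at their principal-component
estimates and runs the VAR blocks (fast, and standard FAVAR practice).  In
`joint` mode the factors are re-drawn each sweep as latent states.  The
likelihood is then flat along two orbits: any invertible k x k transform of
(factors, loadings), and adding multiples of the *observed* variables to
the factors with loadings compensating.  Left alone, the chain
random-walks along these flat directions and draw averages become
meaningless.  Each factor draw is therefore canonicalized — projected
orthogonal to the observed block, whitened to identity sample covariance,
rotated by orthogonal Procrustes onto the PCA basis, and sign-matched.
This moves each draw along directions the likelihood cannot distinguish,
so fit is untouched.  Joint mode additionally requires q <= p - 1 (the
quasi-differenced panel observation must be expressible in the companion
state) and remains the more fragile mode at small n and T: with loose
idiosyncratic SV the volatility paths can slowly absorb common variation.
It is exercised in tests at reduced size; two-step is the recommended
default.

## Factor extraction and factor count

Factors are initialized (and in two-step mode fixed) as the first k
principal components of the standardized panel, unit-variance normalized,
with the sign convention that each factor's largest-magnitude loading is
positive.  The number of factors is chosen by the Bai–Ng ICp2 criterion,

    ICp2(k) = log V(k) + k (n+T)/(nT) log min(n, T),

minimized over 1..k_max (default 8), with one numerical guard: when the
residual variance after k factors falls below 1e-10 of the panel scale the
panel is numerically rank-k and k is returned directly (the log term would
otherwise dominate the penalty on exactly low-rank input).

## Preprocessing

Mixed-frequency series are aggregated to quarters (mean, sum, or last;
default mean).  Seasonal adjustment is by quarter-of-year dummy regression
— deterministic, dependency-free, and exactly mean-preserving; it removes
stable calendar patterns but not moving seasonality, which is acceptable
for the stationarized, standardized inputs the model consumes.  Each series
is screened with an augmented Dickey–Fuller test (intercept, no trend, lag
order 4 — one year of quarterly lags; level 0.05) and differenced until the
unit-root null is rejected, up to max_d (default 2); failure raises an
error naming the series.  Columns are then standardized (mean 0, sample
std 1), and the whole transformation is recorded per series so it can be
reported and, where invertible, undone.

## Impulse-response surfaces

Responses to the EPU shock are computed per posterior draw and per shock
date with coefficients and impact matrix frozen at that date (the standard
TVP-VAR convention), propagated through the companion matrix:
response_h = J C_t^h J' (A_t^{-1} Sigma_t) e_m.  The default shock is one
standard deviation (sigma_mt at each date, so surfaces inherit the
stochastic volatility); a unit-shock mode normalizes the impact on the
shock variable to one.  Horizon default H = 12 quarters.  Surfaces are
summarized by pointwise 5/50/95 percent quantiles over draws — the 90%
bands — and exported as long-format CSV (quarter, horizon, variable, q05,
q50, q95).  Plotting is a convenience layer over the exported data, not a
normative output.

## Synthetic-data generator

The generator stands in for the proprietary commercial-database inputs
such an analysis would normally require:
it simulates the exact structure the model assumes, with full ground truth
retained.  All three latent blocks are drawn as random walks (innovation
stds: coefficients 0.005, triangular elements 0.02, log-volatilities 0.05
per quarter), the augmented VAR is simulated with a 20-quarter burn-in, and
the panel is built from the factor equation with AR(q) + SV idiosyncratic
errors.  Design choices that matter:

- Coefficient paths are rejection-sampled until every companion eigenvalue
  stays below 0.999 (at most 100 tries); explosive configurations raise a
  stability error.  The random-walk law itself does not enforce
  stationarity, but unstable paths make impulse responses meaningless.
- Factor loadings are standard normal, scaled by each factor's realized
  standard deviation so every factor carries a unit-variance common
  component regardless of the dynamics a particular seed draws.  A
  random quarter of the series also load (std 0.3) on the core observables
  and on the EPU index.
- The idiosyncratic noise scale defaults to 1.0, giving a common-factor
  variance share around 0.6 on the national preset — large enough that the
  three factors dominate the panel (the analysis' premise), small enough to
  be a realistic macro panel.
- Crisis windows multiply all shock standard deviations inside the window
  (national preset: 2008Q3–2009Q2 x3, 2015Q3–2016Q2 x2, 2020Q1–2020Q4 x4
  at the calendar-analogue positions).
- The uncertainty -> expenditure coefficient starts negative (-0.25,
  contractionary transmission) and, in scenarios with a sign switch, ramps
  linearly to +0.25 over 4 quarters at the switch date (2020Q1-analogue in
  the national preset).  The ramp is deterministic and added to the random
  walk: the historical finding it emulates is an emergent data property,
  and a deterministic ramp makes the ground truth unambiguous for
  recovery tests.
- The idiosyncratic log-volatilities follow the same random-walk law (and
  innovation scale) as the VAR block's log sigma — the model itself states
  no law of motion for them, so the generator mirrors the nearest stated
  one.
- Presets: national (T=74 quarters from 2007Q1, n=98, k=3, l=2, p=2, q=1),
  provincial (T=44 from 2009Q1, n=30, no 2020-analogue window, no sign
  switch), plus small three-variable scenarios (m=3, p=1) for recovery
  studies.

What the generator does not emulate: mixed frequencies, missing values,
outliers and data revisions, moving seasonality, cross-sectionally
correlated idiosyncratic errors, and any real calendar correlation between
the EPU index and the factors beyond what the VAR induces.  Passing
recovery tests therefore demonstrates internal correctness of the
estimator under the model's own assumptions, not robustness to the ways
real macro data violate them.

## Problem sizes in the bundled studies

The test-suite and acceptance studies use deliberately small problems: the
band-calibration study fits m=3, p=1, T=80 with 2,000 sweeps (500 burn-in,
1,500 retained) per replicate, 10 replicates; the sign-switch study uses
T=200 with 3,000 sweeps over 5 seeds; factor-count recovery uses the full
98-series panel over 20 seeds.  These sizes give stable Monte-Carlo
behavior for the properties checked while keeping the whole suite
desk-scale.

## Numerical choices

- Covariances are symmetrized at every filter step; a 1e-10 ridge is added
  before Cholesky factorizations and inversions; likelihoods accumulate in
  log space.
- log(resid^2 + c) uses offset c = 1e-4.
- The KSC mixture constants are the standard published 7-component table;
  component means are stored for log chi2(1) + 1.2704 and the offset is
  subtracted when forming the observation equation.  A unit test checks
  the mixture mean against psi(1/2) + log 2.
- Inverse-Wishart sampling delegates to scipy; draws are symmetrized and
  their positive definiteness is asserted in tests.
- Convergence diagnostics: Geweke difference-of-means z (first 10% vs last
  50%, spectral variances) and inefficiency factors with a Parzen window
  of bandwidth 4 (len/100)^0.25.  At that bandwidth the estimator targets
  the *windowed* autocorrelation sum; for very persistent chains
  (autocorrelation ~0.9) this sits well below the untruncated asymptote —
  the unit tests check against the windowed closed form.

## Known limitations

- Band calibration: in the bundled recovery study the 90% IRF bands cover
  the truth at ~96% pooled — conservative rather than nominal.  The
  inverse-Wishart prior on Q_B admits more coefficient drift than the
  generator's truth, and at T=80 the likelihood only partially overrides
  it (Q_B is weakly identified in short TVP-VARs).  The direction and size
  of this conservatism depend on the truth's drift scale, which real data
  do not reveal.
- The recursive identification makes the EPU shock definitionally the last
  innovation; reordering changes the shock and is exposed as
  configuration, not inferred.
- Joint mode: see above; small-sample fragility with loose idiosyncratic
  SV is documented rather than hidden.
- Response magnitudes are in standardized-data units; only signs, shapes
  and relative comparisons are interpretable across datasets.
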