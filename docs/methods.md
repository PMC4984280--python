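# Methods

## Model

The package analyses glucose-limited continuous cultures of yeast in
two operating modes: the **chemostat**, where the dilution rate
D = phi_V/V fixes the specific growth rate mu at steady state, and the
**retentostat**, a chemostat whose effluent passes through a 0.22 um
filter so biomass is fully retained and accumulates while mu decays
towards zero.

Substrate use is partitioned by the Herbert–Pirt relation

    q_S = mu / Y_X/S^max + m_S

with q_S the biomass-specific glucose uptake rate (g glucose per g dry
biomass per hour), Y_X/S^max the maximum biomass yield on glucose
(g/g) and m_S the maintenance coefficient (g/g/h) — the
growth-independent consumption that sustains turnover and homeostasis.

The retentostat feed glucose concentration declines because the
reservoir upstream of a level-controlled mixing vessel (working volume
V_S) is swapped at t = 0 from concentration C_S,MC to C_S,MR:

    C_S,in(t) = (C_S,MC − C_S,MR) exp(−phi_V t / V_S) + C_S,MR

The culture balances are

    dC_Xv/dt = mu C_Xv − k_d C_Xv
    dC_Xd/dt = k_d C_Xv
    dC_S/dt  = D (C_S,in − C_S) − q_S C_Xv

where C_Xv/C_Xd are viable/dead biomass (g/L) and k_d a first-order
death rate; dead biomass keeps its dry weight but consumes no
substrate. Viability is C_Xv/(C_Xv + C_Xd).

### Pseudo-steady substrate mode (default)

Under glucose limitation the residual concentration is mg/L-scale
while the feed is g/L-scale, so dC_S/dt ≈ 0 and consumption equals
supply: q_S C_Xv = D C_S,in(t). Inverting the Pirt relation gives
mu = Y_X/S^max (q_S − m_S). With constant parameters the viable-biomass
balance is then a *linear* ODE,

    dC_Xv/dt = Y D C_S,in(t) − (Y m_S + k_d) C_Xv,

whose closed form (a sum of exponentials, with the degenerate
equal-rate case handled by its limit) serves three roles: an
independent oracle for the numeric integrator, the fast model solution
inside the least-squares fitter, and the source of the long-time
asymptote C_X(∞) = D C_S,MR / m_S that makes the identifiability of
m_S from biomass trajectories obvious.

### Full-ODE mode

When the residual substrate is integrated explicitly, an uptake law is
required; the balances alone do not provide one. The package uses
Monod saturation q_S = q_S_max C_S/(K_S + C_S) with defaults
q_S_max = 0.36 g/g/h (uptake at fast growth) and K_S = 0.005 g/L
(high-affinity glucose transport). Whenever uptake capacity exceeds
supply — the whole operating regime here — residual glucose settles at
mg/L values and the mode agrees with the pseudo-steady solution to
within 1% at 600 h. The mode exists to verify the pseudo-steady
assumption and the substrate budget, not as an independent kinetic
claim.

### Growth-rate-dependent maintenance

Windowed regression (below) indicates that m_S is not constant but
drops roughly 3-fold between mu = 0.06 and 0.03 h^-1. Only windowed
point estimates are observable, so the continuous shape is a modelling
choice: a logistic interpolation

    m_S(mu) = m_S_low + (m_S_high − m_S_low) · logistic((mu − mu_mid)·s)

with defaults m_S_high = 0.0100, m_S_low = 0.0031 g/g/h,
mu_mid = 0.045 h^-1 and steepness s = 200 (placing ~95% of the
transition inside 0.03–0.06 h^-1). The logistic was chosen because it
is the simplest smooth monotone curve with two plateaus and a single
midpoint parameter; any monotone interpolant consistent with the
windowed estimates would serve. With a profile, the Pirt inversion
solves the fixed point mu = Y (q_S − m_S(mu)) by bracketed root
finding (the solution is unique because m_S(mu) is monotone
non-decreasing); the profile is evaluated for negative trial mu too,
where the low plateau simply continues. The simulator supports both
constant-m_S and mu-dependent modes because the data cannot
distinguish whether maintenance tracks instantaneous mu; the constant
mode is used for fitting, the profile as synthetic truth.

## Default operating point

All defaults reproduce one operating configuration: V = 1.4 L,
phi_V = 0.035 L/h (D = 0.025 h^-1), V_S = 1.2 L, 10 → 5 g/L reservoir
swap, Y_X/S^max = 0.584 g/g, fast-growth m_S = 0.0100 g/g/h,
near-zero-growth m_S = 0.0031 g/g/h, k_d = 6e-5 h^-1, 600 h (25 d) of
retentostat operation. The initial retentostat biomass is taken as the
chemostat steady state at D = 0.025 h^-1 with the fast-growth
parameters (4.734 g/L), which makes runs reproducible from printed
constants alone. Residual glucose defaults to zero in all yield
algebra (measured residuals are ~3 orders of magnitude below the
feed).

## Estimators

**Chemostat regression.** q_S per reactor follows from the
steady-state balances, q_S = D (C_S,in − C_S)/C_X; OLS of q_S on
mu (= D) gives m_S as the intercept and Y_X/S^max as the reciprocal
slope, with classical OLS standard errors and R². A negative fitted
intercept is returned with a warning, never clipped. Requires ≥ 3
observations at ≥ 2 distinct dilution rates.

**Retentostat fit.** For each experiment separately, the constant-m_S
pseudo-steady solution is fitted to the observed total-biomass series
(and the viable-biomass series when viability was measured) by
minimising the unweighted joint SSE over bounded parameters
m_S ∈ [1e-5, 0.05] g/g/h and, when viability data allow it,
k_d ∈ [0, 1e-2] h^-1 (otherwise k_d is fixed; default 0). A relative
(log-residual-like) objective is available but off by default: the
measurement error is a few-percent CV over a ~6-fold biomass range, so
weighting changes little. The optimiser is bounded trust-region least
squares with a 3-point log-spaced multistart in m_S; the objective is
smooth and unimodal in practice, the multistart guards against edge
starts. C_X0 is fixed to the first observation (initial dead biomass
from the first viability sample); it can be supplied explicitly. mu(t),
q_S(t) and doubling times ln2/mu are derived from the fitted model.

**Interval balances and moving windows.** Between consecutive
retentostat sampling points, mu = ln(C_X2/C_X1)/(t2 − t1); the glucose
supplied follows from the closed-form feed integral times phi_V; the
apparent yield is Y_X/S = ΔC_X·V/ΔS and q_S = mu/Y_X/S. In the
zero-growth limit q_S degenerates to supply per unit biomass
(maintenance-only consumption) instead of 0/0. Chemostat and
retentostat (mu, q_S) points are pooled, ordered by descending mu, and
OLS is run on moving windows of four consecutive mu levels (all
replicates included, so typically 8 points per window), advancing one
level at a time. A window is *accepted* — and only then interpreted as
(m_S, Y_max) over its mu range — iff R² > 0.99; the flag is a pure
function of the window's R². Replicate experiments at nominally equal
conditions produce near- but not exactly-equal mu values, so an
explicit level label can group them; by default each distinct mu value
is its own level. Single-replicate levels are allowed with a warning.

**Storage accounting.** The fraction of supplied glucose diverted to
reserves over an interval is Δ(stored glucose equivalents)/ΔS, with
glycogen measured directly in glucose equivalents and trehalose
converted by hydrolysis stoichiometry (2 × 180.16/342.30 ≈ 1.053 g
glucose per g trehalose; configurable). Negative fractions (stores
mobilised) are reported as such. The supplied-glucose denominator uses
the feed integral, which coincides with integrated consumption under
the full-consumption assumption.

## Synthetic data

The generator emulates the study conditions so estimator behaviour can
be quantified against known truth:

- chemostats: duplicate reactors at D ∈ {0.025, 0.05, 0.075, 0.10}
  h^-1, 10 g/L feed, biomass from the steady-state balances;
- retentostat: forward simulation from the mu-dependent maintenance
  truth (0.0100 → 0.0031 g/g/h) with k_d = 6e-5 h^-1, sampled at 12
  sparse time points over 600 h (including days 1, 3, 5, 16 and 23 —
  sampling is sparse because each sample removes biomass from a
  closed system);
- noise: mean-preserving lognormal factors of CV 3% on biomass and
  feed-glucose measurements (positivity-preserving; the 3% scale
  mirrors the steady-state criterion that biomass drift be below 3%),
  additive Gaussian noise (sd 0.005, clipped to [0, 1]) on viability;
- storage contents: log-mu Gaussian bumps peaking at mu = 0.0013 h^-1
  with maxima 0.12 g/g (trehalose, log-width 1.28) and 0.07 g/g
  (glycogen, log-width 0.667); the widths are calibrated so contents at
  mu = 0.0007 h^-1 sit ~11% and ~35% below their maxima. The curve is
  an empirical shape for generating plausible data, not a kinetic
  model of reserve turnover.

All randomness derives from one explicit integer seed through a single
`numpy.random.default_rng` (PCG64) stream with fixed draw order, so a
given seed reproduces identical bytes.

What the generator does **not** emulate: sampling-volume losses,
slow drifts in reactor volume or flow, biomass attachment to surfaces,
correlated (batch) measurement errors, and any biological deviation
from the Pirt relation other than the m_S transition. Passing recovery
tests therefore demonstrate estimator correctness under the assumed
error model, not robustness to every failure mode of real
cultivations.

## Numerical choices

- Integration: LSODA with rtol 1e-8 / atol 1e-10; trajectories span
  600 h of slow exponentials and results are tolerance-independent to
  at least 4 significant figures. The integrator must agree with the
  analytic pseudo-steady solution to rel. err < 1e-6 before its output
  is used.
- Pirt inversion with a maintenance profile: Brent root finding,
  xtol/rtol 1e-14, bracketed by the two plateaus.
- Least squares: `scipy.optimize.least_squares` (trf), xtol/ftol 1e-14.
- Negative-mu states (supply below maintenance) are simulated and
  fitted, never clipped; they are flagged with a warning.
- Zero-growth intervals switch to the maintenance-only q_S formula at
  relative biomass change ≤ 1e-12.
- OLS (estimates, SEs, R²) via statsmodels.

## Problem sizes

Default trajectories use 601 grid points over 600 h. The statistical
test batteries use 1000 seeded chemostat tables for the bias check of
the chemostat estimator (its single-table relative SE is ~25%, so the
median over 1000 replicates carries ~1% Monte Carlo error, well inside
the 3% bias bound being verified) and 100 seeded retentostat series
for the sparse-noise recovery check (that estimator's per-series
spread is a few percent, so 100 replicates suffice). The whole suite
runs in well under a minute on one CPU.

## Known limitations

- The constant-m_S retentostat fit is a working approximation when the
  truth has mu-dependent maintenance; it recovers the low-growth
  plateau because the culture spends nearly the whole 25 days below
  the transition, but the first ~2 days are systematically mis-fitted
  by a small amount.
- Y_X/S^max is treated as a fixed external input to the retentostat
  fit; its own (mild) growth-rate dependence is resolved only by the
  windowed analysis.
- Confidence intervals for the retentostat fit (profile likelihood or
  bootstrap) are not implemented.
- Washout (D exceeding the achievable growth rate) is deliberately not
  checked in the chemostat algebra.
- Interval mu estimates at near-zero growth are noise-dominated (the
  biomass increment falls below the measurement CV), which is why
  noisy low-mu windows usually fail the R² > 0.99 acceptance rule —
  the rule exists precisely to screen these out.
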