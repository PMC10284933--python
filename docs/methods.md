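# Methods

## Rate law and state convention

The package models the degradation of a stability-indicating attribute as a
normalized extent of conversion α ∈ [0, 1] evolving under a competitive
two-step rate law: each step *i* contributes
kᵢ(T)·(1−αᵢ)^nᵢ·αᵢ^mᵢ·C^pᵢ with Arrhenius kᵢ(T) = exp(lnAᵢ − Eaᵢ/RT), and
the observed rate is the v-weighted sum of the two step rates. The combined
expression is ambiguous about whether the two terms share one extent or
carry their own; `stabkin` evolves two coupled-but-independent sub-extents
(dαᵢ/dt = rᵢ) and reports α = v·α₁ + (1−v)·α₂. This is the only reading
under which the observed rate equals the stated sum at all times, and it
makes v = 1 reduce exactly to the one-step law. The convention is a
documented choice, not a claim about any particular reference software.

Autocatalytic steps (m > 0) have α^m = 0 at α = 0 and would never start;
sub-extents are initialized at α(0) = 1e−8, the usual regularization in
thermokinetic software, and the value is an explicit argument everywhere.

Units: time in days, temperature in Kelvin, Ea in J/mol internally;
files carry °C and days/months (1 month = 30.4375 days), converted at the
I/O boundary. The protein concentration C is a per-dataset covariate
(initial concentration), constant during integration.

## Integration: reference route and superposition route

`integrate_extent` is the contract integrator: per-segment LSODA
(`scipy.integrate.solve_ivp`) over the piecewise-linear temperature
profile, rtol 1e−8 / atol 1e−10, state clipped to [0, 1] with a 1e−6
tolerance check. Near full conversion the rate law can reach α = 1 with a
kink (e.g. zero-order); the RHS tapers linearly over the last 1e−9 of
conversion so the solver neither overshoots nor stalls — a perturbation far
below the solver tolerances.

Because every step separates as kᵢ(T)·f(αᵢ), the sub-extent depends on the
temperature program only through the reduced time
θᵢ(t) = C^pᵢ·∫kᵢ(T(s))ds. The package exploits this with a second,
numerically identical route: θ is accumulated by 8-point Gauss–Legendre
quadrature per profile segment (sub-divided to ≤2 K spans), and the
autonomous problem dα/dθ = (1−α)^n·α^m is solved in closed form for m = 0
(m < 1e−6 is treated as 0; the induced error is < 2e−5 relative) and by a
compiled RK4 otherwise. The RK4 step adapts to the *relative* motion of α
and 1−α (~0.04 per step), which bounds the work through autocatalytic
induction and saturation regardless of how large θ grows; the two routes
agree to ~1e−7 in the test suite. Fitting and bootstrapping use the fast
route; reported trajectories can use either.

## Fitting

The objective is unweighted least squares in extent units (optional
per-observation weights are available): attribute values are mapped to
α = direction·(y − y0)/span and residuals are taken there, so arms with
different spans are on a common scale. y0 defaults to the mean of the
time-zero records; the span comes from assay theory (100 for % scales, the
full titer range for log-titer) and is a user input.

Optimization uses `scipy.optimize.least_squares` (TRF, box constraints)
from a deterministic 8-start grid: Ea ∈ {50, 80, 110, 140} kJ/mol crossed
with k(40 °C) ∈ {1e−3, 3e−2}/day; order/autocatalysis/weight parameters
start at the midpoints of their bounds (n = 1.5, m = 1, v = 0.5, p = 0.5).
Two-step starts split the rate grid into a fast step (20×) and slow step
(1/20) with Ea₂ = Ea₁ + 30 kJ/mol. Default bounds: Ea ∈ [10, 300] kJ/mol,
n ∈ [0, 3], m ∈ [0, 2], v ∈ [0, 1], p ∈ [−2, 3], lnA ∈ [−40, 140].
Internally the optimizer works in (ln k(298.15 K), Ea) coordinates rather
than (lnA, Ea): over a 5–40 °C window lnA and Ea are correlated at ~0.999
and TRF crawls; anchoring the rate constant mid-window decorrelates them.
lnA is recovered exactly for reporting. Ties across starts break on lowest
RSS, then fewest function evaluations; with a fixed seed the fit is
bit-reproducible. Function evaluations are capped at 200 per start.

Information criteria use the least-squares forms with the error variance
counted as a parameter: AIC = N·ln(RSS/N) + 2(K+1),
AICc = AIC + 2(K+1)(K+2)/(N−K−2), BIC = N·ln(RSS/N) + (K+1)·ln N. These
definitions vary across software, so they are fixed here explicitly; fits
with N ≤ K + 2 are refused because AICc is undefined.

During catalog screening, each more complex model additionally receives the
best simpler solution as a warm start (first-order → nth-order →
autocatalytic; best one-step seeds the two-step with v = 0.95 and a slow
second step). This both speeds convergence and guarantees the nested-model
property RSS(general) ≤ RSS(special case) up to optimizer tolerance.

## Model selection and the multiple-model bootstrap

Akaike weights are computed on AICc (the designs of interest have
N ≈ 20–30, where the small-sample correction matters) and on BIC, then
combined as the arithmetic mean; how the two weight sets should be combined
is not prescribed anywhere authoritative, so the mean is the package's
choice and both ingredients are reported. Ranking sorts by combined weight,
ties toward fewer free parameters.

The bootstrap resamples centered residuals with replacement (a parametric
Gaussian variant is a flag), adds them to the fitted values of the loop's
assigned model, and refits from a warm start. Loops are allocated across
models by largest-remainder rounding of B·wCombined — with a decisive
winner this collapses to an ordinary single-model bootstrap. Loops failing
to refit are counted; more than 20 % failures aborts the band as
unreliable.

**Band semantics.** The default band is a *confidence* band on the mean
trajectory: pointwise quantiles of the re-fitted central curves. The term
"prediction interval" is often used loosely for such bands;
`mode="prediction"` adds resampled residual noise to each loop's curve,
widening it into a band for future single observations. Batch comparison
uses prediction mode (raw observations are compared against the band);
shelf-life uses the confidence band by default. Both are available
everywhere.

## Downstream predictions

*Shelf-life*: first crossing of the specification limit by the central
curve and by the conservative band edge (upper edge for attributes that
grow with degradation, lower for those that fall), found by exact
interpolation on the band grid (piecewise-linear, well below the 0.01-day
reporting resolution). A limit already violated at t₀ is flagged as zero
shelf-life; no crossing within the simulated span reports "beyond horizon".

*ICH Q1E baseline*: single-batch, single-arm OLS of attribute vs time with
the one-sided 95 % confidence limit on the regression mean; the crossing is
bracketed on a dense grid and polished with Brent's method. No poolability
testing across batches is implemented — the baseline exists for
like-for-like comparison against the kinetic route on one batch.

*Excursion monitor*: each ensemble parameter set is integrated over the
recorded logger profile (linear interpolation between samples by default;
step-hold available for chamber programs); the band is the pointwise
quantile. The report adds the consumed thermal budget
∫k₁(T(s))ds / k₁(T_ref) in equivalent days at the reference storage
temperature, using the top model's step-1 rate constant — exact for
one-step separable models, advisory for two-step fits — plus the profile
checksum and warnings for logger gaps. The same code path produces storage
bands and excursion bands, so a constant profile reproduces the standard
band bit for bit.

*Batch comparison*: fraction of batch-B observations inside batch A's
level-0.99 prediction-mode band at matching time/temperature, plus Ea and
rate-constant (25 °C) deltas from an independent fit of B; "comparable"
requires an inclusion fraction ≥ 0.95 by default. The band ensemble is
fixed (fit once on A), not refit per comparison.

## Synthetic scenarios

Real stability tables for marketed products are proprietary; the
`synthetic` module generates studies with the statistical structure the
method assumes: arms {5, 25, 40} °C, 7–10 time points per arm over 6 months
(21–30 points), additive Gaussian noise in attribute units with sd
defaulting to 0.005 of the conversion span (≈ assay precision for SEC/ELISA
readouts), and ground truth returned for recovery testing. Presets cover
the canonical cases: nth-order acidic-variant growth (Ea 100 kJ/mol),
slow zero-order HMW aggregation tuned to 0.0046 %HMW/day at 25 °C
(Ea 80 kJ/mol, within the typical aggregation range), a biphasic
"decelerating vaccine" (v = 0.3 fast step at Ea 40 kJ/mol plus a slow
Ea 110 kJ/mol step, 30 points), concentration-dependent dimerization with
p = 1 across 50 and 150 mg/mL, and first-order titer loss in log10 units
(Ea 65 kJ/mol), where the additive log-scale noise corresponds to
proportional noise on the raw titer. Excursion profiles use 1-hour ramps
between levels so the program stays physical.

What generated data do **not** emulate: assay drift and plate effects,
batch-to-batch random effects, heteroscedastic noise, non-Arrhenius
behavior outside what the two-step sum can express, and freeze-thaw or
container effects. Passing recovery/coverage tests therefore demonstrates
the estimator works under its stated assumptions, not that any particular
real product follows them.

## Problem sizes and numerical tolerances in the shipped studies

The simulation studies in `stabkin.studies` (used by the test suite and
`scripts/acceptance.py`) run 50 seeded replicates per scenario for
structure/Ea recovery (30 in the acceptance script) and two-step
selection, and 200 replicate datasets with B = 300 loops for band
coverage — enough replication to estimate the rates to a few percent
while keeping a full run to minutes on one CPU.
Crossing searches resolve to better than 0.01 day; route-equivalence checks
use 1e−6 absolute tolerance on α.

## Known limitations

- Two-step fits with all nine parameters free are weakly identified on
  21-point designs; AICc duly punishes them, but users fitting two-step
  models deliberately should collect ≥30 points (the decelerating preset
  shows the intended design).
- The design validator's "20 % degradation" rule is applied to the extent
  scale after the transform — if the span is mis-specified, the rule checks
  the wrong thing (garbage in, garbage out).
- Bootstrap bands are percentile intervals; no BCa correction is applied,
  and extrapolation error beyond the hottest-arm-constrained region is
  reflected only through parameter uncertainty, not model inadequacy.
- Logger temperature is taken as product temperature (no thermal-mass
  model of the package).
- Random batch effects (hierarchical lot-to-lot modeling) are out of
  scope; batch comparison is a fixed-reference band test.
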