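# Methods

## The decision problem

`clipcea` models the cost-effectiveness, from the French health-system
perspective, of percutaneous edge-to-edge mitral-valve repair (PR, the clip
device) added to guideline-directed medical treatment (GDMT) versus GDMT
alone, in heart-failure patients with severe secondary mitral regurgitation.
Two randomized trials of this comparison reached conflicting conclusions, so
the model can be parameterised from either evidence base ("mitra_fr" or
"coapt" presets) and the two parameterisations yield radically different
incremental cost-effectiveness ratios (ICERs): millions of EUR/QALY versus
roughly 22,000 EUR/QALY.

## Cohort model

A three-state cohort model runs in monthly cycles over a 30-year horizon
(360 cycles, chosen so that fewer than 1 % of the cohort survives the
horizon). States: *alive without heart-failure hospitalisation (HFH)*,
*alive with HFH*, and *dead*. Hospitalisation is a one-cycle state — a
hospitalised patient accrues one month of extra disutility and one
hospitalisation tariff, then returns to the stable state. Death in and out
of hospital is not distinguished.

State occupancy is read off two independently parameterised curves rather
than a transition matrix:

* overall survival S(t) from a parametric survival model;
* per-cycle per-patient new hospitalisations from a parametric cohort
  cumulative-hospitalisation curve (below), clamped to the surviving
  fraction.

Accruals per cycle t (midpoint convention, m = t + 0.5 months, discount
factor D(m) = (1 + r)^(−m/12), r = 2.5 %/yr):

* life-years: S(m) / 12 · D(m)
* QALYs: [S(m)·u_stable − h(t)·d_hfh] / 12 · D(m), with u_stable = 0.6575
  and hospitalisation disutility d_hfh = 0.1063 per year
* costs: [S(m)·c_routine + h(t)·c_hfh] · D(m), with c_routine = 23.89
  (medication) + 25.00 (GP) + 50/12 (cardiologist twice yearly)
  = 53.0567 EUR per alive patient-month and c_hfh = 3,462.80 EUR per
  hospitalisation; the intervention arm additionally pays the device
  (21,100 EUR) plus index stay (5,398 EUR) at t = 0, undiscounted.

Undiscounted twins of all quantities are computed with D ≡ 1. There is no
additional half-cycle correction: evaluating occupancy and discounting at
cycle midpoints reproduces the published discounted/undiscounted
life-expectancy pairs (4.38 → 3.95–3.96; 3.38 → 3.12) to under 1 %, which is
what fixed this convention. Engine output is cross-checked in the tests
against the closed-form restricted-mean integral for constant hazards
(agreement to < 0.005 LY over the hazard range of interest).

## Survival models

Five families are fitted by maximum likelihood on the monthly time scale
(exponential, Weibull, Gompertz, loglogistic, lognormal), ranked by
AIC = 2k − 2·loglik, with ties broken toward fewer parameters. Optimisation
is quasi-Newton (L-BFGS-B) on log-transformed parameters with three starts;
the exponential MLE uses its closed form events/exposure. Fits are
cross-checked against lifelines' univariate fitters in the test suite.
The generalised gamma family is deliberately omitted; no spline or cure
models and no covariates.

A hazard ratio is applied generically as S(t)^hr. For the exponential
family this is exactly a rescaled rate; for the accelerated-failure-time
families it imposes proportional hazards on the survival function, which is
how between-arm hazard ratios are used in this analysis. Hazard ratios
compose multiplicatively.

**Calibration from printed anchors.** The fitted survival parameters behind
the published analysis live in supplementary material that the package does
not assume; instead `calibrate_exponential_to_life_expectancy` solves (by
bracketing root search, tolerance below 1e-8 on the target) for the
exponential monthly hazard at which the engine's own (dis)counted life
expectancy over the horizon equals a published value. Anchors used by the
presets: both arms at 4.38 undiscounted LY (Mitra-Fr, hazard ratio 1
between arms, giving monthly hazard ≈ 0.0190); control at 3.38 undiscounted
LY and intervention at 4.93 *discounted* LY (Coapt, arms modelled
independently). The Coapt intervention arm is anchored on its discounted
value because the printed undiscounted life expectancy (5.96 LY) is
mutually inconsistent with the printed undiscounted QALY (3.67 implies
≈ 5.6 LY at utility 0.6575); the discounted anchor reproduces the QALY,
LY-gain and cost figures simultaneously, the undiscounted one cannot.

## Hospitalisation model

The cohort's cumulative HFH count follows `cum(t) = max · (1 − exp(−Λ(t)))`
with Λ a parametric cumulative hazard and `max` the plateau the count
approaches as survivors run out. The loglogistic form gives the closed
curve `max·(t/α)^β / (1 + (t/α)^β)`; the exponential-hazard special case
`max·(1 − e^{−kt})` admits a closed-form two-point calibration from a
24-month count and a lifetime plateau: `k = −ln(1 − count/plateau)/24`.
The presets use the two-point exponential calibration (Mitra-Fr: 159→252
and 186→328 events for 152 patients per arm; Coapt: 160→215 for 302 and
283→345 for 312). Fitting to digitized cumulative curves uses bounded
least squares on log parameters with three starts; the plateau is
constrained to at least the last observed count (a package decision — an
unconstrained fit could undercut the data on noisy curves). Monthly
differencing divided by the randomized arm size converts the cohort curve
to per-cycle per-patient increments; the increments telescope exactly.

The hospitalisation process is modelled independently of survival, mirroring
the separate curve fits; the plateau itself encodes the clinical coupling
(fewer survivors ⇒ bounded lifetime counts). No per-patient recurrent-event
likelihood is attempted — the cohort-level curve is the estimand.

## IPD reconstruction

`reconstruct_ipd` inverts a digitized Kaplan-Meier curve plus a
numbers-at-risk table into approximate individual patient data, interval by
interval: censorings are spread uniformly within each inter-risk-time
interval, event counts at the digitized drop times are solved from the
product-limit recursion, and the censoring count is iteratively adjusted
until the implied number at risk matches the table at the interval end.
Ties place events before censorings (the KM convention); a negative implied
censoring count is clamped to zero and the interval replayed; inconsistent
inputs yield a reconciliation warning, never a silent failure. In the last
interval (no closing risk number) the earlier censoring rate is assumed;
if a total event count is supplied it is reconciled there. On zero-jitter
dense digitizations of simulated trials (n = 300, ~20 % censoring) the
round-trip error max|ΔS| is below 0.002 — an order of magnitude inside the
0.02 the validation tests require — and refits on reconstructed IPD recover
the generating hazard within sampling error.

## Synthetic trial generator

The generator exists so every pipeline stage is testable with known ground
truth; its defaults describe a plausible two-arm trial of this population:
150–300 patients per arm, exponential death hazard 0.02/month (≈ 2-year
mortality of 38 %, between the two trials' control arms), exponential
censoring at 0.005–0.012/month plus administrative cut-off at 24 months of
follow-up, and a recurrent-hospitalisation process in which each patient
draws a lifetime target count Poisson(plateau ≈ 1–2) with i.i.d.
loglogistic event times (scale 12 months, shape 1.5) truncated at the
patient's death/censor time — which produces exactly the plateauing cohort
curve the hospitalisation model assumes. Digitization is emulated by
sampling the KM step function on a uniform grid with additive Gaussian
jitter clipped to [0,1], and a risk table at 6-month intervals (typical of
published figures). Time is months from randomization throughout; no
calendar dates, no crossover, no covariates or NYHA dynamics.

What passing round-trip tests show is that the reconstruction and fitting
machinery is faithful *given* data generated under these mechanisms; real
digitized figures add reader error, plot-resolution quantisation and
non-exponential censoring that the zero-jitter tests deliberately exclude
(the jittered variants cover the first of these).

## Sensitivity analyses

**One-way (tornado).** Each scenario re-runs the full model with exactly one
input varied (costs ±20 %, monthly hospitalisations ±20 %, utility ±10 %,
survival at its CI bounds), rows sorted by ICER range; dominance is flagged
rather than reported as a ratio.

**Scenario grid.** Per arm, the Cartesian product of binary factors —
device cost (intervention arm only), hospitalisation tariff, the arm's
monthly hospitalisation increments, stable-state utility, and a survival
factor — is run through the engine, yielding up to 2^5 = 32 and 2^4 = 16
(cost, QALY) pairs. The survival factor multiplies each arm's own monthly
hazard by CI-equivalent bounds: the published equivalent hazard-ratio
bounds (0.76, 1.31) for the Mitra-Fr parameterisation, and ±20 % as a
documented stand-in where per-arm CIs are not printed (Coapt).

**Bootstrap.** 500 iterations draw one pair per arm with replacement.
Two schemes are provided. The plain scheme draws the arms independently.
The default, stratified scheme draws the intervention pair uniformly and
then the control pair uniformly *among the rows sharing the same levels of
the model-level factors* (utility, hospitalisation tariff, survival-CI
direction). The stratification matters: utility weights and tariffs are
properties of the model, not of an arm, and survival-parameter uncertainty
shifts the whole cohort rather than manufacturing a treatment effect — a
fully independent draw lets one arm's replicate value a QALY differently
from the other's, creating spurious negative-ΔQALY replicates. Under the
stratified scheme the Coapt-calibrated cloud is cost-effective at 50,000
EUR/QALY in every replicate for every seed, while the Mitra-Fr cloud has
probability 0 there with its bootstrap-mean ICER equal to the base case —
both patterns collapse under the independent scheme, which is why the
stratified draw is the default. All draws run through one seeded NumPy
generator; a fixed seed reproduces the replicate sequence bit for bit.

**CE plane and CEAC.** The acceptability curve reports, per
willingness-to-pay w, the fraction of replicates with positive net monetary
benefit w·ΔQALY − Δcost. The 95 % ellipse comes from the replicate mean and
covariance at the chi-square(2) quantile; an exactly degenerate covariance
is flagged. Quadrant shares assign exact zeros to the positive side (a tie
rule that is immaterial at floating-point resolution but documented).

**Effect duration.** Curtailment reverts the intervention arm's death
hazard and monthly hospitalisation increments to the control arm's values
after a cut-off year (≥ 2, the observed window); survival stays continuous
because the reversion acts on the hazard. Waning interpolates the hazards
linearly between year 2 and a chosen end year — interpolating hazards, not
survival probabilities, keeps survival monotone by construction. The
blended cumulative hazard is integrated trapezoidally on a 0.01-month grid
(exact for the constant-hazard models used in the presets); within the
trial window the base model is used unchanged, exactly.

## Numerical conventions and edge cases

* Currency is EUR; rounding to two decimals happens only at presentation.
* Discounting uses (1 + r)^(−t/12) at cycle midpoints; upfront items at
  t = 0 are undiscounted by definition.
* ICER is undefined when ΔQALY ≤ 0 or Δcost < 0; results carry a status
  flag (dominant / dominated / indifferent / infinite) instead of a number.
* Degenerate inputs: an all-zero hospitalisation curve fits plateau 0 with
  an arbitrary scale (warned); increments exceeding survival are clamped
  with a warning; a risk table inconsistent with the digitized drops is
  reconciled with a warning.
* Calibration root searches use Brent's method with 1e-14 tolerances;
  likelihood and least-squares optimisations use log-scale parameters and
  three starts.

## Problem sizes

Simulation-based tests use arms of 300–5,000 patients, 10–50 seeded
replicates, and 200-point digitizations; the bootstrap uses the published
500 iterations (50,000 only in a convergence property test). These sizes
give comfortable separation between pass and fail margins for every check
while keeping the full suite and the acceptance script fast.

## Known limitations

* Three health states oversimplify the disease course; no NYHA-class
  transitions (the public trial data cannot support them), no
  age-dependent utilities, no adverse-event or downstream LVAD/transplant
  costs.
* The exponential two-point hospitalisation calibration is a documented
  stand-in for the loglogistic fits behind the published curves; the
  incremental-QALY figure is timing-shape sensitive at the third decimal.
* Extrapolation from 24 months of follow-up to 30 years is inherently
  unverifiable; the effect-duration scenarios quantify, not remove, that
  uncertainty.
* The reconstruction assumes non-informative censoring spread uniformly
  within risk intervals; the trials' true censoring processes are unknown.
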