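# Methods

## Models

Both models describe a cancer by onset of screen-detectability *Z*,
sojourn time *Y* (duration of the preclinical detectable phase) and
clinical-diagnosis time *X* = *Z* + *Y*, with a single screen at time
*t* (study entry, *t* = 0, throughout). Background clinical incidence is
the linear hazard `I(x) = β₁ + β₂x` (quadratic cumulative incidence
`C(x) = β₁x + (β₂/2)x²`), a local approximation valid on a configured
window `[x_min, x_max)`; evaluation outside the window raises rather than
clamps. Sojourn times are exponential with mean μ in every closed form
and in the likelihood; the Volterra solver and the simulator accept any
density through a minimal distribution interface.

**Catch-up model** (*Y* ⟂ *X*): surfacing cancers have joint density
`I(x)f(y)`. Prevalence is `p(t) = E[C(t+Y) − C(t)] = I(t)μ + β₂μ²`.
Post-screen incidence with episode sensitivity *s* is
`I(t+x)·(1 − s·e^(−x/μ))`.

**Classic model** (*Y* ⟂ *Z*): onset incidence `I_o` satisfies the
first-kind Volterra equation `I(x) = ∫ I_o(x−y) f(y) dy`; for
exponential sojourn `I_o(x) = I(x) + μI′(x) = β₁ + β₂(x+μ)`, prevalence
is `p(t) = I(t)μ`, and post-screen incidence is
`I(t+x) − s·I(t)·e^(−x/μ)` (derived by splitting surfacing cancers into
escaped pre-screen onsets, weight 1−s, and post-screen onsets; the
quadrature route evaluates the two convolution integrals directly and is
tested against the closed form to 1e−6 relative).

A deliberate modelling caveat: the classic closed forms integrate the
*signed* linear onset rate over the entire past. `I_o` is negative below
its positivity bound `−β₁/β₂ − μ`, so when that bound lies close to the
screen (large μ, strong trend — exactly the prostate parameterization)
the classic model is not a globally consistent probability model. The
quadrature routes therefore default to the unclamped (signed) integrand,
which matches the closed forms; `clamp_onset=True` floors onset at zero
to quantify the inconsistency (at the prostate coefficients with
μ = 11.6 the clamped prevalence is ≈ 0.048 instead of 0.040).

## Direct estimators and intervals

The three direct estimators are monotone maps from prevalence
*P* = *R*/*s* (sensitivity defaults to 1): positive quadratic roots for
the catch-up time and the moment estimator, the ratio `P/I(t)` for the
classic model; negative roots are discarded explicitly, and a prevalence
exceeding the attainable cumulative incidence on the model window raises
an error naming the maximum. Applying the catch-up rule to onset
incidence reproduces the clinical-incidence catch-up time exactly (the
self-consistent integral collapses algebraically); both routes are
implemented and tested to 1e−10.

Confidence intervals propagate a normal-approximation Poisson interval on
the detected count, `count ± z√count`, through the estimator; endpoint
mapping is exact by monotonicity. This choice reproduces the published
endpoints (7.72–8.59 for the catch-up time at 804/20 100); an exact
gamma interval does not. The published classic-model lower bound (10.64)
back-calculates to 10.84 under the same propagation and is treated as a
probable erratum: the tests assert 10.84 and document the discrepancy.
Background-incidence uncertainty is ignored in these intervals (it is
carried by the ML fit instead).

## Likelihood

All counts are independent Poissons: control bins with expectation
`py × mean rate over bin` (exact for the linear hazard via the midpoint
value), the screen-detected count with expectation `n·s·p(0)` (persons,
not person-years), and interval bins with the model's post-screen
incidence integrated in closed form over each bin. `log k!` constants
are dropped inside the optimizer but included in the reported
log-likelihood, so values compare across model kinds on identical data.

Optimization: L-BFGS-B on `log β₁, log β₂, log μ` with *s* boxed in
[0, 1], restarted deterministically from three sojourn-time starting
values around the direct prevalence/incidence ratio (starting β's come
from a weighted line fit to the control rates). Out-of-bounds parameters
return +∞, never NaN. Wald intervals use the inverse observed information
(finite-difference Hessian on the natural scale); a sensitivity estimate
on the upper boundary is flagged (`s_at_boundary`) and excluded from the
Hessian rather than treated as an error. Symmetric Wald intervals match
the symmetric published ML intervals.

### Trial fixtures and their reconstruction

The packaged HIP and ERSPC-Rotterdam tables are rebuilt from published
aggregate numbers; person-years are back-derived as `cases / printed
rate` (detection uses persons: 1078/0.054 ≈ 19 963 and 55/0.00273 ≈
20 147). Two reconstructions are assumptions, stated here once:

* **ERSPC control arm** — only the aggregate (1067 cases, 5.26/1000
  person-years, years 1–12) is published, while the original fit used
  yearly bins. The fixture splits person-years evenly over twelve yearly
  bins and allocates the 1067 cases proportionally to the published
  quadratic at bin midpoints (largest-remainder rounding to integers).
* **HIP control arm** — a single bin over years 0–5 at 1.87/1000
  person-years; the trend is fixed at β₂ = 0.021/1000 per year as in the
  published fits.

Consequence: the fits reproduce the published prostate catch-up estimate
to ≈ 3% (9.67 vs 9.36 years) but the published classic estimate only to
≈ 13% (18.0 vs 15.89) and the mammography estimates to ≈ 5% (1.83/1.87
vs 1.93/1.98). The driver is that the printed aggregate control rate
(5.26/1000) sits below the published quadratic's implied 12-year mean
(5.59/1000), pulling the reconstructed β₁ down and — because the classic
screen equation ties μ to `R/(s·β₁)` — the classic μ up. The qualitative
findings are insensitive to the reconstruction and are asserted exactly:
the catch-up model fits the prostate table better (higher
log-likelihood), and the two models differ by < 0.1 years on the
mammography table.

## Lead time

Among cases prevalent at the screen, sojourn times are length-biased with
weight `w(y) = C(t+y) − C(t)`; the conditional mean is the moment ratio
`(I(t)E(Y²) + (β₂/2)E(Y³)) / (I(t)E(Y) + (β₂/2)E(Y²))`, implemented both
via exponential moments (`E(Yᵏ) = k!μᵏ`) and as the algebraic closed form
`μ(2I(t)+3β₂μ)/(I(t)+β₂μ)`, with an equivalence test guarding against
transcription error. In the catch-up model the time already spent in the
preclinical phase at the screen has mean μ, so mean lead time is the
conditional mean sojourn minus μ; with no trend this is the familiar
length-biased exponential result 2μ − μ = μ. In the classic exponential
model, memorylessness makes lead time exponential with mean μ outright.

## Simulator

The simulator realizes each model's event process exactly: clinical times
(catch-up kind) or onset times (classic kind) are drawn from the
appropriate inhomogeneous Poisson process by inverting the quadratic
cumulative rate (exact inverse-CDF sampling; no thinning loop), sojourn
times independently, and prevalent cases (`Z ≤ t < X`) are detected with
probability *s*. Event totals are Poisson at the population level and
events are counted per event, not per subject, so binned counts are
*exactly* Poisson with the likelihood's expectations and `n_subjects`
only sets the process scale; empirical rates divide counts by
`n_subjects × bin width` accordingly.

Two oracle-use caveats, both asserted or warned about in code:

* catch-up kind: clinical times are generated only to the follow-up
  horizon, so prevalence-type summaries need `follow_up ≳ 10μ` past the
  screen (the acceptance checks use 60–100 years);
* classic kind: onset starts at its positivity bound, which only
  reproduces the closed forms when that bound lies ≥ 5μ before the
  screen — the simulator warns otherwise. Closed-form and
  parameter-recovery oracles for the classic kind therefore run at
  parameter sets with a distant bound (e.g. β₁ = 0.005, β₂ = 1e−4,
  μ = 3); at the prostate pairing only truncation-robust identities
  (the exponential lead-time law) are asserted.

What the generator does not emulate: competing mortality and
overdiagnosis, repeated screening rounds, age structure, covariates, or
non-exponential sojourn families in the likelihood. Passing recovery
tests therefore show correctness of the estimators under the models' own
assumptions, not robustness to real-data violations of them.

## Numerical choices

* **Volterra solver** — midpoint product integration with forward
  substitution on a uniform grid (default step 0.01 years). Midpoint
  rather than trapezoid because the trapezoid rule is weakly unstable
  (oscillating error) for first-kind Volterra equations; midpoint is
  stable and O(h²), and recovers the exponential closed form to ~1e−7
  relative at h = 0.01. Truncation of onset at the grid start is exact
  when incidence vanishes there (start the grid at the hazard positivity
  bound); a kernel with no mass within one step of zero raises an
  ill-conditioning error. Box-like kernels remain outside the scheme's
  comfort zone; the near-degenerate-kernel test uses a short-mean
  exponential.
* **Quadrature oracles** — `scipy.integrate.quad` with default
  tolerances; infinite tails integrated directly.
* **Model-comparison curves** — the two predicted post-screen
  incidence curves are compared relative to background incidence (both
  vanish at x → 0, making pointwise ratios of the curves themselves
  uninformative); at the paired prostate estimates they stay within ≈ 6%
  of background for x ∈ [0.5, 10].
* **Problem sizes** — simulator oracles use 10⁶-subject cohorts for
  distribution identities and recovery (seeded, a few seconds each);
  repeated-fit bias/coverage checks use 200 cohorts of 20 000 subjects
  per model kind. The full test suite runs in well under a minute.

## Known limitations

Single screen only; exponential sojourn in all estimators and fits;
episode (not test-level) sensitivity; quadratic incidence with an
explicit validity window; ERSPC control-arm reconstruction as described
above. The general joint density of (X, Y) beyond the two independence
structures is out of scope.
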