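# Methods

## The model

`sessiondose` treats mental-healthcare sessions as unit "doses" into a
latent therapeutic space and models depressive symptom severity with an
indirect-response structure borrowed from pharmacodynamics.

Severity is the average of the two DSM-5 Level 1 depression items
(anhedonia, depressed mood; each 0–4) divided by 4, giving a value in
[0, 1] on a 0.125 grid. Every modelled patient enters treatment severe,
so Dep(0) = 1 by construction.

Each session of service type c ∈ {coaching, therapy, psychiatry} at time
t_e deposits a unit bolus into compartment c, which eliminates with a
first-order rate constant k_out,c (1/day). The combined latent mass is the
superposition

    TRT(t) = Σ_events exp(−k_out,c(e) · (t − t_e)),   t ≥ t_e.

Treatment inhibits the production of symptoms through a capacity-limited
(Hill-type) term with the maximum effect fixed at 1:

    I(t) = TRT(t) / (TRT(t) + S50),

so S50 is the latent mass giving half-maximal inhibition. Symptoms follow
zero-order production and first-order elimination with a common turnover
rate r (1/day):

    dDep/dt = r · (1 − I(t)) − r · Dep,    Dep(0) = 1.

Setting production = elimination rate caps severity at the severe level:
with no treatment, Dep ≡ 1 is a steady state, and after treatment stops
severity relaxes back toward 1 at rate r. The five individual constants
are (k_out,coaching, k_out,therapy, k_out,psychiatry, S50, r), all
strictly positive and dimensionally latent — only comparative
interpretation is meaningful.

The alternative parameterisation in which treatment stimulates symptom
elimination requires an unbounded maximum-stimulation parameter and is
deliberately not implemented.

## Numerics

Because TRT(t) is available in closed form, the system reduces to a single
linear ODE in Dep. Two integration routes are provided and cross-checked:

- `method="rk45"` (default of `simulate_trajectory`): adaptive explicit
  Runge–Kutta (scipy `solve_ivp`, rtol = atol = 1e−8) with mandatory
  restarts at every session time, where TRT has derivative
  discontinuities.
- `method="exact"`: the integrating-factor update
  Dep(b) = Dep(a)·e^{−rΔ} + r∫ₐᵇ e^{−r(b−s)}(1 − I(s)) ds applied per
  inter-event segment, with the integral computed by 12-node
  Gauss–Legendre quadrature on panels no longer than 6 / max-rate days
  (spectral accuracy; agreement with an independent adaptive-quadrature
  oracle is at the 1e−13 level). Mass-free segments use the closed form.
  This compiled route is what estimation uses; it is ~10³× faster than
  the RK route and the two agree to better than 1e−7.

Severity stays in (0, 1] for any event history and positive parameters;
the integrator never clamps, and solver failures raise rather than
returning silently truncated values.

## Hierarchical estimation

Random effects are log-normal on all five parameters with a diagonal
between-subject covariance: log θ_i = log θ_pop + η_i,
η_i ~ N(0, diag(ω²)). No correlation structure is estimated. The residual
model is a single additive Gaussian SD σ on the severity scale, shared
across patients and times and estimated with the rest.

Fitting uses stochastic-approximation EM (SAEM):

- E-step: per patient, 3 Metropolis–Hastings chains and 5 transitions per
  iteration; each transition applies an independent proposal from the
  current population prior, a joint random walk, and a single-component
  random walk on a cycling coordinate. Random-walk scales adapt toward
  ~35% acceptance during exploration, per kernel and per component.
- M-step: closed-form updates of log θ_pop, ω² and σ² from
  stochastic-approximation-smoothed sufficient statistics (sampled
  log-parameters, their squares, and the residual sum of squares).
- Schedule: 100 exploration iterations at step size 1, then 300 smoothing
  iterations with step size m^−0.6. A polynomial decay is used instead of
  the textbook 1/m because the (k_out, S50) likelihood surface has a
  nearly flat ridge (faster elimination trades off against higher
  sensitivity); step-1 exploration diffuses along that ridge and 1/m decay
  freezes before averaging the excursion away, whereas m^−0.6 keeps enough
  drive to re-centre. During exploration, ω² and σ² may shrink by at most
  3% per iteration (simulated-annealing guard against premature collapse);
  floors of 0.01 (ω) and 1e−3 (σ) prevent degenerate variances.
- Determinism: one root seed fans out to per-patient streams keyed by a
  CRC32 of the patient id, and patients are processed in id order, so
  estimates are independent of cohort ordering and bit-reproducible.

Initial values default to k_out = (0.05, 0.1, 0.2)/day for
coaching/therapy/psychiatry — reflecting the clinical triaging hierarchy —
with S50 = 1, r = 0.05/day, ω = 0.5 and σ = 0.2. These are engineering
starting points, not estimates from any dataset. Convergence from far-off
initial values (several-fold away) is not guaranteed on sparse cohorts;
start from plausible values, inspect the iteration trace, and lengthen the
schedule if it has not flattened.

A patient with no sessions of a given type carries no information about
that k_out; their deviation shrinks to the population prior mode without
special-casing.

Empirical-Bayes individual estimates are MAP values of η obtained by
multi-start L-BFGS-B (prior mode plus two seeded prior draws) on the
penalised least-squares objective; parameters with ω_p = 0 are held at
their typical values.

## Support triage

Individual weighted residuals IWRES = (observed − individual-predicted)/σ
are computed per observation; baseline (time-0) observations are excluded
because the model is initialised at the observed severe level, making
their residuals identically zero. A patient with fewer than two
post-baseline reports is *unclassifiable*. Otherwise |mean(IWRES)| and the
sample SD (n−1 denominator) are graded separately —

| grade | \|mean\| | SD |
|---|---|---|
| supported | ≤ 1 | ≤ 1.5 |
| semi-supported | (1, 1.5] | (1.5, 2] |
| unsupported | > 1.5 | > 2 |

— and the worse grade wins. Thresholds are inclusive: a value equal to a
boundary takes the better class. The worse-of-two combination is a
deliberate, conservative choice (an offset fit *or* an erratic fit is
enough to flag a patient for review); it is isolated inside
`classify_support` so alternative combinations are a one-line change.

## Treatment planning

Future schedules use the clinical qNd notation (q7d = weekly). Expansion
is endpoint-exclusive and includes the start day. Plans are simulated from
Dep(0) = 1 on a 0.25-day grid (fine enough to resolve threshold-crossing
times) over a horizon, typically 180 days of treatment plus 180 untreated
days. Metrics: minimum severity, days spent strictly below a response
threshold, relapse time (first grid time after the final session at or
above the threshold; time 0 for an untreated severe patient), and final
severity. The default response threshold is 0.625 — the midpoint of the
item-average band between "mild" (2 → 0.5) and "moderate" (3 → 0.75),
i.e. the top of the sub-moderate range — and is user-overridable. Ranking
prefers no relapse, then later relapse, then more time in response, with
ties broken by fewer sessions. Planning uses a patient's empirical-Bayes
parameters; population typical values are available behind an explicit
flag for unclassifiable patients.

## Synthetic cohorts

No real cohort ships with the package; `synth` generates cohorts with the
structural features the model targets, and every generated patient's true
parameters are recorded in a ground-truth ledger so estimation can be
validated by round-trip recovery.

- Reports: baseline at day 0 (severity exactly 1), then every 30 days
  (70%) or 60 days (30%) with 3-day Gaussian jitter and 55% adherence,
  over a follow-up drawn uniformly from 180–720 days. These settings give
  ~7 reports/patient (observed cohort mean: 6.2, range 2–22).
- Sessions: gamma-distributed gaps per service with participation
  probabilities and mean gaps calibrated to ~1.7 coaching, ~16 therapy
  and ~3.5 psychiatry sessions per patient. A shared log-normal
  per-patient engagement factor (SD 0.35) scales all cadences, inducing a
  therapy–psychiatry utilisation correlation of ~0.4, matching the
  observed correlation structure without modelling it explicitly.
- Archetypes (mix 42/21/16/16/5%): *response* and *saturated* keep a
  sustained cadence (saturated 1.67× denser); *rebound* stops all
  sessions at least 90 days before follow-up end; *multiphasic* has an
  active block, a ≥60-day lapse, then re-engagement; *poor_fit* has
  sparse, irregular sessions and an independent random walk (step SD
  0.08) added to the latent severity, so the schedule cannot explain the
  symptoms. The poor_fit share and step size are kept small: the
  generator must remain a cohort whose population parameters are
  recoverable, mirroring real triage outcomes where only ~1 in 8
  classifiable fits is semi- or unsupported.
- True population for generation: the estimation defaults above with
  ω = (0.3, 0.4, 0.5, 0.6, 0.2) — variability increasing across the
  coaching→therapy→psychiatry hierarchy, S50 spread over roughly an order
  of magnitude, r tightly distributed — and σ = 0.08. Severities are
  snapped to the 0.125 item grid and clamped to [0, 1] by default,
  emulating the two-item score construction.
- Every emitted record satisfies the inclusion rule (≥2 reports with ≥1
  session strictly in between); non-conforming draws are resampled with
  the resample count logged.

What the generator does **not** emulate: demographic covariates, secular
changes in care delivery, informative observation times (reports are
missed at random, not in relation to symptom state), floor effects in
self-report near remission, and multivariate symptom dynamics. Passing
recovery and triage checks on these cohorts therefore demonstrates
correctness of the machinery under the model's own assumptions, not
clinical validity on real data.

## Problem sizes used in checks

Recovery checks fit 300-patient cohorts (the smallest size at which all
five typical values are reliably identified on this design) across 10
seeds in the test suite and 3 in the acceptance script; oracle agreement
uses 100 random parameter/schedule draws; the support-rule check covers
the full 61×61 threshold grid including boundaries.

## Known limitations

- Observed severities are clamped to [0, 1]; the Gaussian residual model
  ignores this censoring, which biases σ slightly downward and the fit
  near the severe boundary (the analogous bias near the floor is a known
  behaviour of this model family on real data).
- The (k_out, S50) ridge limits per-parameter precision on sparse
  schedules; k_out,coaching is the softest because most patients have no
  coaching sessions.
- Diagonal ω cannot capture correlated individual deviations.
- Standard errors are not computed; the iteration trace is the
  convergence diagnostic.
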