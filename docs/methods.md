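# Methods

## The accrual model

Recruitment at a site is modelled as a homogeneous Poisson process observed
in discrete periods: the number of recruitments in period *t* is
N_t ~ iid Poisson(λ), with λ the site's recruitment rate per period. The
three assumptions this encodes — independence across periods, events one at
a time, a constant rate — are reasonable for routine clinic-based
recruitment but are assumptions; the goodness-of-fit test below exists to
check them against the observed log, and the main known failure mode is a
non-constant rate (site shutdowns, seasonal effects), which the test has
high power against (see calibration results computed by the test suite).

The recruitment duration for goal *g* is D = min{t ≥ 1 : Σ_{u≤t} N_u ≥ g}.
Because Σ_{u≤t} N_u ~ Poisson(λt), D has the exact tail representation
P(D > t) = P(Poisson(λt) ≤ g−1) and

E[D] = Σ_{t≥0} P(Poisson(λt) ≤ g−1).

`expected_duration_analytic` evaluates this sum directly (scipy's Poisson
CDF, 256-term blocks, truncation when a summand drops below `tol`, default
1e-12; summands are non-increasing so the truncation error is negligible).
It is deliberately kept as a second, independent route to the same quantity
the simulator estimates: the test suite compares the two across a grid of
goals and rates at three batch standard errors.

## Simulation and the batch-means interval

`sample_site_duration` draws Poisson(λ) period counts and returns the first
goal-crossing period; the vectorised path draws counts in period blocks
sized ~1.5·g/λ so one block usually suffices, with a hard `max_periods` cap
(default 10,000) so a pathological rate fails loudly instead of looping. A
positive goal with a zero rate raises an infeasible-plan error immediately.

`simulate_site` runs R replications (default 10,000) and reports the grand
mean. Uncertainty uses batch means: the replications are split in order into
B = 50 batches, and a Student-t interval at the configured confidence
(default 0.95) is taken over the B batch means. Batch means are
approximately normal even though D itself is discrete and skewed, which is
why the interval is built on them rather than on the raw samples. When
every replication returns the same integer (effectively deterministic
regimes, e.g. goal 1 at rate 10) the batch variance estimate is zero and
the interval degenerates to a point; this is a limitation of any empirical
SE estimate, and the acceptance suite allows a 1e-3-period absolute floor
in exactly that case.

R, B and the confidence level are configuration (`SimulationConfig`), with
R divisible by B enforced.

## Multi-site trials

Sites differ in rate, goal and start period, so per-site forecasts cannot
be pooled; each site is simulated independently on an RNG substream spawned
from the master seed (`numpy.random.SeedSequence.spawn`), which makes the
per-site draws independent and insensitive to adding or removing other
sites. The trial recruitment duration is the latest per-site end period,
end = delay + mean simulated duration, and the site attaining the maximum
is the determinative site (ties broken by plan order). The point estimate
is deterministic post-processing of the per-site means. For a trial-level
interval, replication r is paired across sites and the batch-means interval
is applied to max_i(delay_i + D_{i,r}); note E[max] ≥ max E[·], so this
interval is centred slightly above the headline point estimate — it bounds
the distribution of the latest finish, not the maximum of the means.

## Rate estimation and goodness of fit

The rate MLE is the sample mean count over the site's *active window*:
from the site's recorded start (baseline `start_date` if provided, else its
first period with an event) through the current period, zero-count periods
inside the window included. Starting the window at first activity avoids
penalising a site for its initiation delay; the trade-off is that a site
whose "delay" was actually a stretch of failed recruiting will look faster
than it is.

`poisson_gof` tests the Poisson fit: observed frequencies of per-period
counts k = 0, 1, 2, … are compared with n·pmf(k; λ̂), the final category
open-ended (≥ k_max) via the survival function so expected frequencies sum
to exactly n. Adjacent categories are merged from both tails (then, if
needed, interior categories into their left neighbour) until every expected
frequency is at least `min_expected` (default 5, the textbook validity
rule). The statistic Σ(obs−exp)²/exp is referred to chi-squared with
df = bins − 2 — one degree for the fixed total, one for the estimated mean.
With the mean estimated from ungrouped data the true null distribution lies
between χ²(bins−2) and χ²(bins−1) (Chernoff–Lehmann); at the sizes tested
the empirical type-I rate stays inside the binomial band around the nominal
α, which the acceptance suite verifies. Fewer than three surviving bins is
reported as insufficient data rather than a p-value.

## Monitoring semantics

- `current_period` defaults to the latest period present in the log, so
  monitoring needs no clock; `--as-of` restricts the log to events on or
  before a date and sets the period accordingly.
- A site with outstanding recruitments and a zero estimated rate (or a
  start date after the as-of period) is *stalled*: its forecast is
  undefined, it is surfaced as a warning and excluded from the
  determinant-site comparison rather than crashing the overview. A rate
  override un-stalls it for scenario analysis.
- The determinant site maximises the expected *remaining* duration (not the
  predicted end date; the two differ when future initiation delays remain).
- Site flagging uses strict inequality: recruited < threshold.
- Overrides equal to the estimated values reproduce the plain call exactly
  (same substream), so scenario deltas are purely due to the changed
  parameter.

## Synthetic data generator

`generate_log` draws exactly the process the model assumes: per site, a
Poisson(λ) count in each period after its delay, each event dated uniformly
at random within its period (consistent with a homogeneous process
conditioned on period counts), with an optional change-point switching the
rate mid-horizon to exercise the GOF test's power. `generate_trial_fixture`
produces a matched plan+log pair shaped like a multi-clinic cluster trial —
default goal 50 per site, rates uniform in [1.0, 4.0] per week (plausible
clinic-level accrual, giving roughly 12–50-week site durations), horizon
4·goal/min-rate — with each site's log truncated at goal attainment.

What passing tests on generated data do *not* show: robustness to the ways
real logs deviate from the model — screening funnels and consent lag,
duplicate participants, time-varying rates beyond a single change-point,
calendar artefacts (holidays, weekends), or data-entry errors. The
generator is a fidelity check of the machinery, not a validation of the
Poisson assumption for any particular trial; that is what `gof` on the real
log is for.

## Numerical and design choices

- Periods are 1-based and half-open: period t covers days [(t−1)L, tL)
  after the origin, L = 7 by default. Day 7 is the first day of period 2.
- Events sharing a site and date are aggregated on log construction; the
  model only ever consumes per-period counts, so within-period ordering is
  immaterial.
- CSV is the interchange format; Excel input is accepted through the same
  schema. Reports are JSON (sorted keys, floats rounded to 6 decimals, so
  fixed seeds give byte-identical files) plus optional CSV tables and a
  cumulative-accrual PNG.
- Durations are integers (period granularity); means and interval bounds
  are reals. Simulated problem sizes in the test suite (10⁴ replications,
  hundreds of GOF replicates, 100–1,000-period synthetic logs) were chosen
  as the smallest sizes at which the statistical tolerances are meaningful.

## Limitations

- Constant-rate Poisson only: no Poisson-gamma site heterogeneity, no
  time-varying rates within a forecast, no change-point *detection* (the
  GOF test detects misfit but does not locate it).
- Planning accuracy is bounded by the accuracy of the supplied rates; early
  in a trial the estimated rates are noisy and forecasts inherit that noise
  (the CI reflects Monte-Carlo error, not rate-estimation error).
- No screening/eligibility funnel: the unit is the recruitment event.
- No calendar semantics beyond dates (time zones, holidays).
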