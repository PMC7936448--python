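# trialaccrual

Poisson-process planning and monitoring of clinical trial recruitment.

Recruitment is usually the hardest phase of a trial to predict and to keep
on schedule, especially in multi-centre (cluster-randomised) trials where
each clinic recruits at its own pace, toward its own goal, possibly starting
late. `trialaccrual` is a scriptable toolkit for exactly that problem:

- **Planning** — given each site's recruitment goal, expected rate and
  initiation delay, simulate how long recruitment will take, per site and
  for the whole trial.
- **Monitoring** — given the dated recruitment log accumulated so far
  (CSV or Excel), estimate each site's actual rate, check the Poisson
  assumption with a chi-squared goodness-of-fit test, forecast the
  *remaining* duration per site, flag underperforming sites, and identify
  the *determinant site* — the one expected to finish last, which sets the
  trial's end date.

## Model

Time is discrete (default: weeks). A site's per-period recruitment count is
modelled as iid Poisson(λ), λ the site's rate in recruitments per period.
The recruitment duration for a goal of *g* participants is the first period
by which the cumulative count reaches the goal:

    D = min{ t ≥ 1 : N₁ + … + N_t ≥ g },   N_t ~ iid Poisson(λ)

Since the cumulative count by period *t* is Poisson(λt),

    E[D] = Σ_{t≥0} P( Poisson(λt) ≤ g − 1 )

which the package evaluates exactly (`expected_duration_analytic`) as an
independent cross-check on the simulator. The simulator draws the per-period
counts directly, replicates the process R times (default 10,000), and builds
a confidence interval by batch means: the R durations are split into B = 50
batches and a Student-t interval is taken over the batch means.

Sites are simulated independently on separate RNG substreams. A trial's
predicted recruitment duration is the latest per-site end period
(initiation delay + simulated mean duration); the site attaining it is the
**determinative site**.

## Worked example

How long does one site need to recruit 50 participants at 2.5 per week?

```console
$ accrual --seed 7 plan-single --goal 50 --rate 2.5
{
  "ci_high": 20.569815,
  "ci_low": 20.444585,
  "delay": 0,
  "end_period": 20.5072,
  "goal": 50,
  "mean_duration": 20.5072,
  "rate": 2.5
}
```

About 20.5 weeks, with a tight 95% batch-means interval around the
Monte-Carlo mean (the exact expectation is 20.500 weeks). For a multi-site
trial, generate a synthetic three-clinic trial and forecast it:

```console
$ accrual --seed 7 synth --n-sites 3 --goal 40 --rate-min 1 --rate-max 3 \
      --seed 7 --out-log log.csv --out-plan plan.csv
$ accrual --seed 7 plan-multi --plan plan.csv
...
  "trial_duration": 36.6926,
  "determinative_site": "S02",
...
determinative site: S02 (trial duration 36.69 weeks)
```

S02 is the slowest site (1.11 recruits/week), so its 36.7-week forecast sets
the trial duration even though the other sites finish in 16–19 weeks.

Mid-trial, the same log drives monitoring:

```console
$ accrual --seed 7 monitor --log log.csv --plan plan.csv --threshold 20 \
      --out report.json --csv report.csv
$ accrual gof --log log.csv --site S01
```

`monitor` writes a JSON report with the cumulative accrual series, per-site
recruited/remaining counts, estimated rates, forecast remaining durations,
the determinant site and the sites flagged below the threshold; `gof` prints
the chi-squared table, statistic, degrees of freedom and p-value for the
Poisson fit of one site's weekly counts. Scenario analysis ("what if this
site's rate doubled?") is available through the library's
`site_status(..., rate_override=...)`.

## Input formats

- **Recruitment log** (`site_id,date[,count]`): one row per recruitment
  event, ISO 8601 dates. Excel spreadsheets with the same columns are
  accepted.
- **Site baseline** (`site_id,goal,rate[,delay,start_date,lat,lon]`): one
  row per site; `lat`/`lon` are passed through to reports for external
  mapping.

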