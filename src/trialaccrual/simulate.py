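"""Poisson-process simulation of trial recruitment duration.

Model
-----
Per-period recruitment counts at a site are independent Poisson(lambda)
draws, lambda the site's recruitment rate per period.  The recruitment
duration for a goal of ``g`` participants is the first period by which the
cumulative count reaches the goal,

    D = min{ t >= 1 : N_1 + ... + N_t >= g },     N_t ~ iid Poisson(lambda),

so the cumulative count by period t is Poisson(lambda * t) and

    P(D > t) = P(Poisson(lambda * t) <= g - 1),
    E[D]     = sum_{t >= 0} P(Poisson(lambda * t) <= g - 1).

The simulator draws the N_t directly and records where the cumulative sum
first crosses the goal; the tail-sum identity above is kept as an
independent analytic oracle (:func:`expected_duration_analytic`).

Uncertainty on the Monte-Carlo mean comes from batch means: the R
replications are split into B equal batches, and a Student-t interval is
built on the B batch means.  For a multi-site trial each site is simulated
on its own RNG substream; the trial duration is the latest per-site end
period (initiation delay + simulated duration), and the site attaining it
is the *determinative site*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import (InfeasiblePlanError, SimulationCapError, SitePlan,
                    TrialPlan)

DEFAULT_MAX_PERIODS = 10_000


@dataclass(frozen=True)
class SimulationConfig:
    """Monte-Carlo settings: R replications in B batches at a confidence level."""

    replications: int = 10_000
    batches: int = 50
    confidence: float = 0.95
    seed: int | None = None
    max_periods: int = DEFAULT_MAX_PERIODS

    def __post_init__(self) -> None:
        if self.batches < 2:
            raise ValueError(f"need at least 2 batches, got {self.batches}")
        if self.replications < self.batches:
            raise ValueError(
                f"replications ({self.replications}) must be >= batches ({self.batches})")
        if self.replications % self.batches:
            raise ValueError(
                f"replications ({self.replications}) must be divisible by batches ({self.batches})")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError(f"confidence must be in (0, 1), got {self.confidence}")
        if self.max_periods < 1:
            raise ValueError(f"max_periods must be >= 1, got {self.max_periods}")


@dataclass(eq=False)
class DurationEstimate:
    """Simulated duration distribution for one site, with batch-means CI.

    ``samples`` holds the R simulated durations in whole periods; ``mean``
    is their grand mean and ``[ci_low, ci_high]`` the Student-t interval on
    the batch means.  ``batch_se`` is the batch-means standard error, the
    natural yardstick for comparing the simulated mean with an analytic
    expectation.  The initiation delay is echoed but NOT added to the mean;
    end period = delay + mean is computed downstream.
    """

    samples: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    goal: int
    rate: float
    delay: int = 0
    batch_se: float = 0.0

    @property
    def end_period(self) -> float:
        return self.delay + self.mean

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DurationEstimate):
            return NotImplemented
        return (np.array_equal(self.samples, other.samples)
                and (self.mean, self.ci_low, self.ci_high, self.goal,
                     self.rate, self.delay, self.batch_se)
                == (other.mean, other.ci_low, other.ci_high, other.goal,
                    other.rate, other.delay, other.batch_se))


@dataclass(eq=False)
class TrialForecast:
    """Multi-site forecast: per-site estimates and the overall trial duration.

    ``trial_duration`` is the maximum expected end period over sites
    (delay + mean duration) and ``determinative_site`` the site attaining
    it (ties broken by plan order).  The trial-level CI comes from pairing
    replication r across sites and taking the batch-means interval of the
    per-replication maximum end period.
    """

    per_site: dict[str, DurationEstimate]
    trial_duration: float
    determinative_site: str
    trial_ci_low: float
    trial_ci_high: float

    def end_period(self, site_id: str) -> float:
        return self.per_site[site_id].end_period


def _check_feasible(goal: int, rate: float, site_id: str | None = None) -> None:
    if goal > 0 and rate <= 0:
        where = f"site {site_id!r}: " if site_id else ""
        raise InfeasiblePlanError(
            f"{where}goal of {goal} is unreachable at recruitment rate {rate}")


def _sample_durations(goal: int, rate: float, n: int, rng: np.random.Generator,
                      max_periods: int = DEFAULT_MAX_PERIODS) -> np.ndarray:
    """Vectorised sampling of n recruitment durations for one (goal, rate)."""
    _check_feasible(goal, rate)
    out = np.zeros(n, dtype=np.int64)
    if goal == 0 or n == 0:
        return out
    active = np.arange(n)
    carried = np.zeros(n, dtype=np.int64)
    offset = 0
    # enough periods that one chunk usually suffices, without over-drawing
    chunk = int(min(max_periods, max(8, math.ceil(goal / rate * 1.5) + 8)))
    while active.size:
        if offset >= max_periods:
            raise SimulationCapError(
                f"goal {goal} not reached within max_periods={max_periods} at rate {rate}")
        width = min(chunk, max_periods - offset)
        draws = rng.poisson(rate, size=(active.size, width))
        cum = draws.cumsum(axis=1) + carried[active, None]
        reached = cum >= goal
        done = reached.any(axis=1)
        first = reached.argmax(axis=1)
        out[active[done]] = offset + first[done] + 1
        carried[active[~done]] = cum[~done, -1]
        active = active[~done]
        offset += width
    return out


def sample_site_duration(goal: int, rate: float, rng: np.random.Generator,
                         max_periods: int = DEFAULT_MAX_PERIODS) -> int:
    """One simulated recruitment duration (whole periods) for a single site.

    Draws Poisson(rate) counts for successive periods and returns the first
    period at which the cumulative count reaches ``goal`` (0 when goal is 0).
    """
    if goal < 0:
        raise ValueError(f"goal must be >= 0, got {goal}")
    return int(_sample_durations(goal, rate, 1, rng, max_periods)[0])


def expected_duration_analytic(goal: int, rate: float, tol: float = 1e-12) -> float:
    """Exact expected recruitment duration via the tail-sum identity.

    E[D] = sum_{t>=0} P(Poisson(rate*t) <= goal-1), truncated once a summand
    falls below ``tol``.  The summands are non-increasing in t, so the
    truncation error is bounded by tol * (remaining effective terms) and is
    negligible at the default tolerance.
    """
    if goal < 1:
        raise ValueError(f"goal must be >= 1, got {goal}")
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    total = 0.0
    t = 0
    block = 256
    while True:
        ts = np.arange(t, t + block)
        terms = stats.poisson.cdf(goal - 1, rate * ts)
        below = terms < tol
        if below.any():
            cut = int(below.argmax())
            total += float(terms[:cut].sum())
            return total
        total += float(terms.sum())
        t += block
        if t > 50_000_000:  # pragma: no cover - unreachable safeguard
            raise RuntimeError("tail sum failed to converge")


def _batch_interval(samples: np.ndarray, batches: int,
                    confidence: float) -> tuple[float, float, float, float]:
    """Grand mean, CI bounds and batch SE from a batch-means t-interval."""
    mean = float(samples.mean())
    batch_means = samples.reshape(batches, -1).mean(axis=1)
    sd = float(batch_means.std(ddof=1))
    se = sd / math.sqrt(batches)
    if se == 0.0:
        return mean, mean, mean, 0.0
    half = float(stats.t.ppf(0.5 + confidence / 2.0, batches - 1)) * se
    return mean, mean - half, mean + half, se


def simulate_site(plan: SitePlan, config: SimulationConfig | None = None,
                  rng: np.random.Generator | None = None) -> DurationEstimate:
    """Monte-Carlo estimate of one site's recruitment duration.

    Runs ``config.replications`` independent duration samples, then builds
    the batch-means confidence interval.  Reproducible given ``config.seed``
    (or an explicit ``rng``, used by :func:`simulate_trial` for per-site
    substreams).
    """
    config = config or SimulationConfig()
    _check_feasible(plan.goal, plan.rate, plan.site_id)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    samples = _sample_durations(plan.goal, plan.rate, config.replications,
                                rng, config.max_periods)
    mean, lo, hi, se = _batch_interval(samples, config.batches, config.confidence)
    return DurationEstimate(samples=samples, mean=mean, ci_low=lo, ci_high=hi,
                            goal=plan.goal, rate=plan.rate, delay=plan.delay,
                            batch_se=se)


def simulate_trial(plan: TrialPlan, config: SimulationConfig | None = None) -> TrialForecast:
    """Forecast a multi-site trial by simulating each site independently.

    Each site runs on an RNG substream spawned from ``config.seed``, so
    adding a site never perturbs the others' draws.  The headline trial
    duration is the maximum expected end period (delay + mean duration);
    the trial-level CI pairs replication r across sites and applies the
    batch-means interval to the per-replication maximum end.
    """
    config = config or SimulationConfig()
    for site in plan:
        _check_feasible(site.goal, site.rate, site.site_id)
    streams = np.random.SeedSequence(config.seed).spawn(len(plan))
    per_site: dict[str, DurationEstimate] = {}
    for site, stream in zip(plan, streams):
        per_site[site.site_id] = simulate_site(site, config,
                                               rng=np.random.default_rng(stream))
    ends = {sid: est.end_period for sid, est in per_site.items()}
    trial_duration = max(ends.values())
    determinative = next(sid for sid in plan.site_ids if ends[sid] == trial_duration)
    max_ends = np.max(np.stack([est.delay + est.samples
                                for est in per_site.values()]), axis=0)
    _, lo, hi, _ = _batch_interval(max_ends.astype(float), config.batches,
                                   config.confidence)
    return TrialForecast(per_site=per_site, trial_duration=float(trial_duration),
                         determinative_site=determinative,
                         trial_ci_low=lo, trial_ci_high=hi)
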