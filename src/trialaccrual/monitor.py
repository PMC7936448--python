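"""Mid-trial monitoring: per-site status, trial overview and site flagging.

Given the recruitment log to date and the site baseline plan, each site's
observed accrual is compared with its goal and the *remaining* duration is
forecast by re-running the Poisson simulator on the residual goal at the
estimated (or scenario-overridden) rate.  The site with the longest
expected remaining duration is the *determinant site*; it sets the trial's
predicted end.  Sites with outstanding recruitments but no observed
activity cannot be forecast and are surfaced as warnings ("stalled") rather
than aborting the overview.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import estimate_rate
from .model import (NoDataError, RecruitmentLog, SitePlan, StalledSiteError,
                    TrialPlan, period_index, periodize)
from .simulate import DurationEstimate, SimulationConfig, simulate_site


@dataclass(eq=False)
class SiteStatus:
    """One site's observed progress and forecast remaining duration."""

    site_id: str
    recruited: int
    goal: int
    remaining: int
    rate_hat: float | None
    remaining_duration: DurationEstimate | None
    complete: bool
    stalled: bool = False

    @property
    def expected_end_offset(self) -> float | None:
        """Expected periods from 'now' until the site finishes (0 if complete)."""
        if self.remaining_duration is None:
            return None
        return self.remaining_duration.mean


@dataclass(eq=False)
class TrialOverview:
    """Whole-trial monitoring snapshot at ``current_period``."""

    total_recruited: int
    cumulative_series: tuple[int, ...]
    statuses: list[SiteStatus]
    determinant_site: str | None
    expected_end_period: float
    current_period: int
    warnings: list[str]


def _current_period(log: RecruitmentLog, period_length: int) -> int:
    latest = max((period_index(ev.date, log.origin, period_length)
                  for ev in log.events), default=1)
    return max(latest, 1)


def site_status(log: RecruitmentLog, plan: SitePlan,
                current_period: int | None = None,
                config: SimulationConfig | None = None,
                period_length: int = 7,
                rate_override: float | None = None,
                goal_override: int | None = None,
                rng: np.random.Generator | None = None) -> SiteStatus:
    """Observed progress and remaining-duration forecast for one site.

    ``rate_override`` / ``goal_override`` support scenario analysis ("what if
    the rate doubled?", "what if the goal grew?") without touching the log.
    With overrides equal to the estimated/planned values the result is
    identical to the plain call.

    Raises
    ------
    StalledSiteError
        Outstanding recruitments remain but the estimated rate is zero and
        no override was given; a forecast would never terminate.
    """
    config = config or SimulationConfig()
    if current_period is None:
        current_period = _current_period(log, period_length)
    if current_period < 1:
        raise ValueError(f"current_period must be >= 1, got {current_period}")
    counts = periodize(log, plan.site_id, period_length, horizon=current_period)
    recruited = counts.total
    goal = plan.goal if goal_override is None else goal_override
    remaining = max(goal - recruited, 0)

    rate_hat: float | None
    if rate_override is not None:
        rate_hat = float(rate_override)
    else:
        start = None
        if plan.start_date is not None:
            start = max(1, period_index(plan.start_date, log.origin, period_length))
        if start is not None and start > current_period:
            rate_hat = None  # site not yet open as of the current period
        else:
            try:
                rate_hat = estimate_rate(counts, through_period=current_period,
                                         from_period=start).rate_hat
            except NoDataError:
                rate_hat = None

    if remaining == 0:
        est = simulate_site(SitePlan(plan.site_id, 0, rate_hat or 0.0), config, rng=rng)
        return SiteStatus(site_id=plan.site_id, recruited=recruited, goal=goal,
                          remaining=0, rate_hat=rate_hat,
                          remaining_duration=est, complete=True)
    if not rate_hat:
        raise StalledSiteError(
            f"site {plan.site_id!r}: {remaining} recruitments outstanding but "
            f"observed rate is zero; supply a rate override to forecast")
    est = simulate_site(SitePlan(plan.site_id, remaining, rate_hat), config, rng=rng)
    return SiteStatus(site_id=plan.site_id, recruited=recruited, goal=goal,
                      remaining=remaining, rate_hat=rate_hat,
                      remaining_duration=est, complete=False)


def trial_overview(log: RecruitmentLog, plan: TrialPlan,
                   current_period: int | None = None,
                   config: SimulationConfig | None = None,
                   period_length: int = 7) -> TrialOverview:
    """Aggregate monitoring snapshot across all planned sites.

    Stalled sites are reported in ``warnings`` (with a placeholder status)
    and excluded from the determinant-site comparison.  The cumulative
    series sums periodized counts over all sites through ``current_period``.
    """
    config = config or SimulationConfig()
    if current_period is None:
        current_period = _current_period(log, period_length)
    streams = np.random.SeedSequence(config.seed).spawn(len(plan))
    statuses: list[SiteStatus] = []
    warnings: list[str] = []
    per_period = np.zeros(current_period, dtype=np.int64)
    for site, stream in zip(plan, streams):
        counts = periodize(log, site.site_id, period_length, horizon=current_period)
        per_period += np.asarray(counts.counts, dtype=np.int64)
        try:
            status = site_status(log, site, current_period, config,
                                 period_length, rng=np.random.default_rng(stream))
        except StalledSiteError as err:
            warnings.append(str(err))
            status = SiteStatus(site_id=site.site_id, recruited=counts.total,
                                goal=site.goal,
                                remaining=max(site.goal - counts.total, 0),
                                rate_hat=None, remaining_duration=None,
                                complete=False, stalled=True)
        statuses.append(status)

    cumulative = tuple(int(x) for x in per_period.cumsum())
    total = int(per_period.sum())

    candidates = [s for s in statuses if not s.complete and not s.stalled]
    if candidates:
        longest = max(s.remaining_duration.mean for s in candidates)
        determinant = next(s.site_id for s in candidates
                           if s.remaining_duration.mean == longest)
        expected_end = current_period + longest
    else:
        determinant = None
        expected_end = float(current_period)
    return TrialOverview(total_recruited=total, cumulative_series=cumulative,
                         statuses=statuses, determinant_site=determinant,
                         expected_end_period=expected_end,
                         current_period=current_period, warnings=warnings)


def flag_sites(statuses: list[SiteStatus], threshold: int) -> list[str]:
    """Site ids with strictly fewer recruitments than ``threshold``, in order."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    return [s.site_id for s in statuses if s.recruited < threshold]
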