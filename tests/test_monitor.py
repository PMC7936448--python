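"""Site status, trial overview and underperforming-site flagging."""

import datetime as dt

import numpy as np
import pytest

from trialaccrual import (RecruitmentEvent, RecruitmentLog, SimulationConfig,
                          SitePlan, SiteStatus, StalledSiteError, TrialPlan,
                          expected_duration_analytic, flag_sites, site_status,
                          trial_overview)


def steady_log(origin, site="A", per_period=3, periods=10):
    """per_period recruitments every Monday for `periods` weeks."""
    events = tuple(RecruitmentEvent(site, origin + dt.timedelta(weeks=w), per_period)
                   for w in range(periods))
    return RecruitmentLog(events, origin)


class TestSiteStatus:
    def test_complete_site(self, origin, fast_config):
        log = steady_log(origin, per_period=5, periods=10)
        status = site_status(log, SitePlan("A", 40, 5.0), config=fast_config)
        assert status.complete and status.remaining == 0
        assert status.remaining_duration.mean == 0.0

    def test_residual_goal_matches_analytic_oracle(self, origin):
        log = steady_log(origin, per_period=3, periods=10)  # 30 recruited
        config = SimulationConfig(replications=20_000, batches=40, seed=3)
        status = site_status(log, SitePlan("A", 50, 3.0), config=config,
                             rate_override=2.5)
        assert status.remaining == 20
        expected = expected_duration_analytic(20, 2.5)
        assert abs(status.remaining_duration.mean - expected) \
            <= 3 * status.remaining_duration.batch_se

    def test_rate_estimated_from_log(self, origin, fast_config):
        log = steady_log(origin, per_period=3, periods=10)
        status = site_status(log, SitePlan("A", 50, 99.0), config=fast_config)
        assert status.rate_hat == pytest.approx(3.0)

    def test_doubling_rate_shortens_forecast(self, origin, fast_config):
        log = steady_log(origin, per_period=2, periods=5)
        slow = site_status(log, SitePlan("A", 60, 2.0), config=fast_config,
                           rate_override=2.0)
        fast = site_status(log, SitePlan("A", 60, 2.0), config=fast_config,
                           rate_override=4.0)
        assert fast.remaining_duration.mean < slow.remaining_duration.mean

    def test_override_neutrality(self, origin, fast_config):
        log = steady_log(origin, per_period=3, periods=10)
        plain = site_status(log, SitePlan("A", 50, 3.0), config=fast_config)
        forced = site_status(log, SitePlan("A", 50, 3.0), config=fast_config,
                             rate_override=plain.rate_hat, goal_override=50)
        assert plain.remaining_duration == forced.remaining_duration

    def test_stalled_site_raises(self, origin, fast_config):
        log = RecruitmentLog((), origin)
        with pytest.raises(StalledSiteError, match="A"):
            site_status(log, SitePlan("A", 10, 2.0), current_period=4,
                        config=fast_config)

    def test_stalled_site_rescued_by_override(self, origin, fast_config):
        log = RecruitmentLog((), origin)
        status = site_status(log, SitePlan("A", 10, 2.0), current_period=4,
                             config=fast_config, rate_override=2.0)
        assert status.recruited == 0 and not status.complete

    def test_start_date_sets_estimation_window(self, origin, fast_config):
        # site opened in period 3; 12 recruits over its 3 open periods, not 5
        events = tuple(RecruitmentEvent("A", origin + dt.timedelta(weeks=w), 4)
                       for w in (2, 3, 4))
        log = RecruitmentLog(events, origin)
        plan = SitePlan("A", 50, 4.0, start_date=origin + dt.timedelta(weeks=2))
        status = site_status(log, plan, current_period=5, config=fast_config)
        assert status.rate_hat == pytest.approx(4.0)

    def test_forecast_never_ends_before_now(self, origin, fast_config):
        log = steady_log(origin, per_period=1, periods=6)
        status = site_status(log, SitePlan("A", 20, 1.0), config=fast_config)
        assert status.remaining_duration.mean >= 0
        assert (status.remaining_duration.samples >= 1).all()


class TestTrialOverview:
    def test_aggregation_matches_brute_force(self, six_site_fixture, fast_config):
        plan, log = six_site_fixture
        ov = trial_overview(log, plan, config=fast_config)
        assert ov.total_recruited == log.total()
        assert ov.total_recruited == ov.cumulative_series[-1]
        assert all(b >= a for a, b in zip(ov.cumulative_series,
                                          ov.cumulative_series[1:]))

    def test_determinant_is_argmax_of_remaining_means(self, six_site_fixture,
                                                      fast_config):
        plan, log = six_site_fixture
        # freeze mid-trial so slower sites are still incomplete
        ov = trial_overview(log, plan, current_period=8, config=fast_config)
        incomplete = [s for s in ov.statuses if not s.complete and not s.stalled]
        assert incomplete, "fixture should be mid-recruitment at period 8"
        best = max(incomplete, key=lambda s: s.remaining_duration.mean)
        assert ov.determinant_site == best.site_id
        assert ov.expected_end_period == pytest.approx(
            8 + best.remaining_duration.mean)

    def test_all_complete(self, origin, fast_config):
        log = steady_log(origin, per_period=5, periods=4)
        plan = TrialPlan((SitePlan("A", 20, 5.0),))
        ov = trial_overview(log, plan, config=fast_config)
        assert ov.determinant_site is None
        assert ov.expected_end_period == ov.current_period

    def test_single_incomplete_site_is_determinant(self, origin, fast_config):
        log = steady_log(origin, per_period=2, periods=4)
        plan = TrialPlan((SitePlan("A", 100, 2.0),))
        ov = trial_overview(log, plan, config=fast_config)
        assert ov.determinant_site == "A"

    def test_stalled_site_warns_but_does_not_crash(self, origin, fast_config):
        log = steady_log(origin, site="A", per_period=2, periods=4)
        plan = TrialPlan((SitePlan("A", 100, 2.0), SitePlan("B", 10, 1.0)))
        ov = trial_overview(log, plan, config=fast_config)
        assert len(ov.warnings) == 1 and "B" in ov.warnings[0]
        assert ov.determinant_site == "A"
        b = next(s for s in ov.statuses if s.site_id == "B")
        assert b.stalled and b.remaining_duration is None

    def test_reproducible_under_seed(self, six_site_fixture, fast_config):
        plan, log = six_site_fixture
        a = trial_overview(log, plan, current_period=8, config=fast_config)
        b = trial_overview(log, plan, current_period=8, config=fast_config)
        assert a.determinant_site == b.determinant_site
        assert a.expected_end_period == b.expected_end_period


class TestFlagSites:
    @staticmethod
    def fake_status(site, recruited):
        return SiteStatus(site_id=site, recruited=recruited, goal=50,
                          remaining=50 - recruited, rate_hat=None,
                          remaining_duration=None, complete=False)

    def test_strict_inequality(self):
        statuses = [self.fake_status(s, r) for s, r in
                    (("a", 8), ("b", 10), ("c", 12))]
        assert flag_sites(statuses, 10) == ["a"]

    def test_zero_threshold_flags_nothing(self):
        statuses = [self.fake_status("a", 0)]
        assert flag_sites(statuses, 0) == []

    def test_matches_brute_force_filter(self, six_site_fixture, fast_config):
        plan, log = six_site_fixture
        ov = trial_overview(log, plan, current_period=8, config=fast_config)
        recruited = np.array([s.recruited for s in ov.statuses])
        threshold = int(np.median(recruited))
        expected = [s.site_id for s in ov.statuses if s.recruited < threshold]
        assert flag_sites(ov.statuses, threshold) == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            flag_sites([], -1)
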