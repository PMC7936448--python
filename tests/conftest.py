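import datetime as dt

import pytest

from trialaccrual import (RecruitmentEvent, RecruitmentLog, SimulationConfig,
                          generate_trial_fixture)

ORIGIN = dt.date(2021, 1, 4)


@pytest.fixture
def origin():
    return ORIGIN


@pytest.fixture
def fast_config():
    """Small but valid Monte-Carlo config for unit tests."""
    return SimulationConfig(replications=2_000, batches=20, seed=42)


@pytest.fixture
def small_log(origin):
    """Three sites, a dozen hand-placed events over five weekly periods."""
    days = {
        "A": [0, 2, 2, 9, 15, 30],
        "B": [1, 8, 8, 22],
        "C": [3, 16],
    }
    events = tuple(RecruitmentEvent(site, origin + dt.timedelta(days=d))
                   for site, ds in days.items() for d in ds)
    return RecruitmentLog(events, origin)


@pytest.fixture
def log_csv(tmp_path):
    """Factory writing a recruitment log CSV from (site_id, date[, count]) rows."""
    def _write(rows, header="site_id,date", name="log.csv"):
        path = tmp_path / name
        path.write_text("\n".join([header, *rows]) + "\n")
        return path
    return _write


@pytest.fixture(scope="session")
def six_site_fixture():
    """A matched (plan, log) pair for a 6-site trial with unequal rates."""
    return generate_trial_fixture(6, goal=30, rate_range=(0.8, 4.0), seed=7)
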