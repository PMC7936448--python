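"""Seeded generation of recruitment logs with known Poisson structure.

The generator emulates exactly the process the accrual model assumes: each
site recruits a Poisson(rate) number of participants per period,
independently across periods and sites, with an optional initiation delay
and an optional change-point after which the rate switches (the change-point
exercises the goodness-of-fit test's power against non-constant rates —
e.g. a site shut for renovation).  Event dates are placed uniformly at
random within their period, consistent with a homogeneous Poisson process
conditioned on the per-period counts.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import RecruitmentEvent, RecruitmentLog, SchemaError, SitePlan, TrialPlan

#: Default origin for generated logs: an arbitrary Monday.
DEFAULT_ORIGIN = dt.date(2021, 1, 4)


@dataclass(frozen=True)
class SiteGeneratorSpec:
    """True data-generating parameters for one simulated site."""

    site_id: str
    rate: float
    delay: int = 0
    change_period: int | None = None
    post_rate: float | None = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"site {self.site_id!r}: rate must be >= 0")
        if self.delay < 0:
            raise ValueError(f"site {self.site_id!r}: delay must be >= 0")
        if (self.change_period is None) != (self.post_rate is None):
            raise ValueError(
                f"site {self.site_id!r}: change_period and post_rate go together")
        if self.post_rate is not None and self.post_rate < 0:
            raise ValueError(f"site {self.site_id!r}: post_rate must be >= 0")

    def rate_at(self, period: int) -> float:
        if self.change_period is not None and period >= self.change_period:
            return self.post_rate  # type: ignore[return-value]
        return self.rate


@dataclass(frozen=True)
class GeneratorSpec:
    """Full specification of a synthetic multi-site recruitment log."""

    sites: tuple[SiteGeneratorSpec, ...]
    horizon: int
    period_length: int = 7
    origin: dt.date = DEFAULT_ORIGIN
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        if not self.sites:
            raise SchemaError("generator spec needs at least one site")
        if self.horizon < 1:
            raise ValueError(f"horizon must be >= 1, got {self.horizon}")
        if self.period_length < 1:
            raise ValueError(f"period_length must be >= 1, got {self.period_length}")
        for s in self.sites:
            if s.change_period is not None and not 1 <= s.change_period <= self.horizon:
                raise ValueError(
                    f"site {s.site_id!r}: change_period {s.change_period} outside "
                    f"horizon 1..{self.horizon}")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorSpec":
        raw = json.loads(Path(path).read_text())
        sites = tuple(SiteGeneratorSpec(**s) for s in raw["sites"])
        origin = (dt.date.fromisoformat(raw["origin"])
                  if "origin" in raw else DEFAULT_ORIGIN)
        return cls(sites=sites, horizon=int(raw["horizon"]),
                   period_length=int(raw.get("period_length", 7)),
                   origin=origin, seed=raw.get("seed"))


def generate_log(spec: GeneratorSpec) -> RecruitmentLog:
    """Draw a recruitment log from the spec's Poisson process.

    Each site gets its own RNG substream spawned from the seed, so the
    generated history of one site is unchanged when sites are added.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(len(spec.sites))
    events: list[RecruitmentEvent] = []
    for site, stream in zip(spec.sites, streams):
        rng = np.random.default_rng(stream)
        for period in range(site.delay + 1, spec.horizon + 1):
            lam = site.rate_at(period)
            n = int(rng.poisson(lam)) if lam > 0 else 0
            if n == 0:
                continue
            day0 = (period - 1) * spec.period_length
            offsets = rng.integers(0, spec.period_length, size=n)
            for off in offsets:
                events.append(RecruitmentEvent(
                    site_id=site.site_id,
                    date=spec.origin + dt.timedelta(days=day0 + int(off))))
    return RecruitmentLog(tuple(events), spec.origin)


def generate_trial_fixture(n_sites: int, goal: int = 50,
                           rate_range: tuple[float, float] = (1.0, 4.0),
                           seed: int | None = None,
                           period_length: int = 7,
                           origin: dt.date = DEFAULT_ORIGIN,
                           ) -> tuple[TrialPlan, RecruitmentLog]:
    """A matched (plan, log) pair shaped like a multi-clinic cluster trial.

    Site rates are drawn uniformly in ``rate_range``; every site shares the
    same recruitment goal.  The log is truncated at each site's goal
    attainment (sites stop recruiting once full), so a site's event total is
    min(goal, events within the horizon).
    """
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {n_sites}")
    lo, hi = rate_range
    if not 0 < lo <= hi:
        raise ValueError(f"rate_range must satisfy 0 < lo <= hi, got {rate_range}")
    root = np.random.SeedSequence(seed)
    rate_stream, log_stream = root.spawn(2)
    rates = np.random.default_rng(rate_stream).uniform(lo, hi, size=n_sites)
    # generous horizon so every site can plausibly reach its goal
    horizon = max(1, math.ceil(goal / lo * 4))
    spec = GeneratorSpec(
        sites=tuple(SiteGeneratorSpec(site_id=f"S{i + 1:02d}", rate=float(r))
                    for i, r in enumerate(rates)),
        horizon=horizon, period_length=period_length, origin=origin,
        seed=int(log_stream.generate_state(1)[0] % (2 ** 31)))
    full = generate_log(spec)
    events: list[RecruitmentEvent] = []
    for site in spec.sites:
        kept = 0
        for ev in full.events:  # already date-sorted
            if ev.site_id != site.site_id or kept >= goal:
                continue
            take = min(ev.count, goal - kept)
            events.append(RecruitmentEvent(ev.site_id, ev.date, take))
            kept += take
    plan = TrialPlan(tuple(SitePlan(site_id=s.site_id, goal=goal, rate=s.rate)
                           for s in spec.sites))
    return plan, RecruitmentLog(tuple(events), origin)
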