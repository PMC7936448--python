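"""Core data model for trial recruitment planning and monitoring.

A trial is a collection of recruitment *sites*, each with a recruitment
goal (participants to enrol), an expected recruitment rate (enrolments per
discrete period, e.g. per week) and an optional initiation delay (whole
periods before the site opens).  Observed recruitment arrives as a dated
event log which is aggregated into per-period counts; the per-period counts
are the quantity the Poisson accrual model describes.

Time convention: periods are 1-based and half-open, period ``t`` covers days
``[(t-1)*L, t*L)`` after the log origin, with ``L`` the period length in days
(default 7, i.e. weekly periods).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class AccrualError(Exception):
    """Base class for all domain errors raised by this package."""


class SchemaError(AccrualError):
    """An input table is missing a required column or violates the schema."""


class LogValidationError(AccrualError):
    """A recruitment log row violates a precondition (bad date, pre-origin event)."""


class UnknownSiteError(AccrualError, LookupError):
    """A site id was requested that the log or plan does not contain."""


class InfeasiblePlanError(AccrualError):
    """A site has a positive goal but a zero recruitment rate."""


class SimulationCapError(AccrualError):
    """A simulated replication exceeded the configured period cap."""


class NoDataError(AccrualError):
    """A site has no recorded activity, so a rate cannot be estimated."""


class InsufficientDataError(AccrualError):
    """Too few count categories survive merging for a chi-squared test."""


class DegenerateDataError(AccrualError):
    """All observed counts are zero; the fitted Poisson mean is 0."""


class StalledSiteError(AccrualError):
    """A site has outstanding recruitments but an estimated rate of zero."""


# --------------------------------------------------------------------------
# Planning types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SitePlan:
    """Planning parameters for one recruitment site.

    Parameters
    ----------
    site_id
        Opaque site label, unique within a trial plan.
    goal
        Number of participants the site must recruit (>= 0).
    rate
        Expected recruitments per period (>= 0).
    delay
        Initiation delay: whole periods before the site starts recruiting.
    start_date, lat, lon
        Optional baseline metadata (recruitment start, coordinates) carried
        through to monitoring reports; they do not affect planning simulations.
    """

    site_id: str
    goal: int
    rate: float
    delay: int = 0
    start_date: dt.date | None = None
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if self.goal < 0:
            raise ValueError(f"site {self.site_id!r}: goal must be >= 0, got {self.goal}")
        if self.rate < 0:
            raise ValueError(f"site {self.site_id!r}: rate must be >= 0, got {self.rate}")
        if self.delay < 0:
            raise ValueError(f"site {self.site_id!r}: delay must be >= 0, got {self.delay}")


@dataclass(frozen=True)
class TrialPlan:
    """An ordered collection of :class:`SitePlan` with distinct site ids."""

    sites: tuple[SitePlan, ...]
    period_unit: str = "week"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        if not self.sites:
            raise SchemaError("a trial plan needs at least one site")
        ids = [s.site_id for s in self.sites]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SchemaError(f"duplicate site_id in plan: {sorted(dupes)}")

    def __iter__(self) -> Iterator[SitePlan]:
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(s.site_id for s in self.sites)

    def get(self, site_id: str) -> SitePlan:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise UnknownSiteError(f"site {site_id!r} not in trial plan")

    @classmethod
    def from_csv(cls, path: str | Path, period_unit: str = "week") -> "TrialPlan":
        """Read a site baseline table.

        Required columns: ``site_id, goal, rate``; optional: ``delay,
        start_date, lat, lon``.  A missing ``delay`` column means no delay.
        """
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path, dtype={"site_id": str})
        for col in ("site_id", "goal", "rate"):
            if col not in df.columns:
                raise SchemaError(f"{path.name}: missing required column '{col}'")
        sites = []
        for i, row in df.iterrows():
            start = None
            if "start_date" in df.columns and pd.notna(row["start_date"]):
                start = _parse_date(row["start_date"], f"{path.name} row {i + 2}")
            sites.append(SitePlan(
                site_id=str(row["site_id"]),
                goal=int(row["goal"]),
                rate=float(row["rate"]),
                delay=int(row["delay"]) if "delay" in df.columns and pd.notna(row.get("delay")) else 0,
                start_date=start,
                lat=float(row["lat"]) if "lat" in df.columns and pd.notna(row.get("lat")) else None,
                lon=float(row["lon"]) if "lon" in df.columns and pd.notna(row.get("lon")) else None,
            ))
        return cls(tuple(sites), period_unit=period_unit)


# --------------------------------------------------------------------------
# Observed recruitment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RecruitmentEvent:
    """``count`` recruitments at one site on one calendar date."""

    site_id: str
    date: dt.date
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"event count must be >= 1, got {self.count}")
        if not isinstance(self.date, dt.date):
            raise TypeError(f"event date must be a datetime.date, got {type(self.date).__name__}")


@dataclass(frozen=True)
class RecruitmentLog:
    """A dated recruitment event log with a fixed origin.

    The origin defines period 1 (trial recruitment start).  Events sharing a
    site and date are aggregated on construction, and events are kept sorted
    by (date, site_id), so two logs with the same event multiset compare
    equal regardless of input order.
    """

    events: tuple[RecruitmentEvent, ...]
    origin: dt.date

    def __post_init__(self) -> None:
        agg: dict[tuple[dt.date, str], int] = {}
        for ev in self.events:
            if ev.date < self.origin:
                raise LogValidationError(
                    f"event for site {ev.site_id!r} on {ev.date} predates origin {self.origin}")
            key = (ev.date, ev.site_id)
            agg[key] = agg.get(key, 0) + ev.count
        object.__setattr__(self, "events", tuple(
            RecruitmentEvent(site_id=s, date=d, count=c) for (d, s), c in sorted(agg.items())))

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(sorted({ev.site_id for ev in self.events}))

    def total(self, site_id: str | None = None) -> int:
        return sum(ev.count for ev in self.events
                   if site_id is None or ev.site_id == site_id)

    def through(self, date: dt.date) -> "RecruitmentLog":
        """Restrict the log to events on or before ``date`` (origin kept)."""
        return RecruitmentLog(tuple(ev for ev in self.events if ev.date <= date), self.origin)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "site_id": [ev.site_id for ev in self.events],
            "date": [ev.date.isoformat() for ev in self.events],
            "count": [ev.count for ev in self.events],
        })
        df.to_csv(path, index=False)


def _parse_date(value, context: str) -> dt.date:
    try:
        ts = pd.Timestamp(value)
        if pd.isna(ts):
            raise ValueError
        return ts.date()
    except (ValueError, TypeError):
        raise LogValidationError(f"{context}: unparseable date {value!r}") from None


def load_log(path: str | Path, origin: dt.date | str | None = None) -> RecruitmentLog:
    """Load a recruitment event log from CSV (or an Excel sheet).

    The table needs columns ``site_id`` and ``date`` (ISO 8601); an optional
    ``count`` column gives multiple recruitments per row, otherwise each row
    is one recruitment.  ``origin`` defaults to the earliest event date.

    Raises
    ------
    FileNotFoundError, SchemaError, LogValidationError
        For a missing file, a missing required column, an unparseable date
        (reported with its 1-based data row number) or a pre-origin event.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".xlsx", ".xls", ".xlsm"}:
        df = pd.read_excel(path, dtype={"site_id": str})
    else:
        df = pd.read_csv(path, dtype={"site_id": str})
    for col in ("site_id", "date"):
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column '{col}'")
    events = []
    for i, row in df.iterrows():
        # +2: header line plus 1-based indexing, matching what an editor shows
        date = _parse_date(row["date"], f"{path.name} row {i + 2}")
        count = 1
        if "count" in df.columns and pd.notna(row.get("count")):
            count = int(row["count"])
            if count < 1:
                raise LogValidationError(f"{path.name} row {i + 2}: count must be >= 1, got {count}")
        events.append(RecruitmentEvent(site_id=str(row["site_id"]), date=date, count=count))
    if origin is None:
        if not events:
            raise LogValidationError(f"{path.name}: empty log requires an explicit origin date")
        origin_date = min(ev.date for ev in events)
    else:
        origin_date = origin if isinstance(origin, dt.date) else _parse_date(origin, "origin")
    try:
        return RecruitmentLog(tuple(events), origin_date)
    except LogValidationError as err:
        # re-raise with the offending row number for file-level context
        for i, ev in enumerate(events):
            if ev.date < origin_date:
                raise LogValidationError(f"{path.name} row {i + 2}: {err}") from None
        raise


# --------------------------------------------------------------------------
# Periodization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PeriodCounts:
    """Per-period recruitment counts for one site.

    ``counts[t-1]`` is the number of recruitments in period ``t``.
    ``first_active_period`` is the site's first period containing an event
    (``None`` when the site has none within the horizon).
    """

    site_id: str
    counts: tuple[int, ...]
    first_active_period: int | None = None

    @property
    def n_periods(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts)

    def active_window(self, through_period: int | None = None) -> "PeriodCounts":
        """Counts from the first active period onward, re-indexed to start at 1."""
        if self.first_active_period is None:
            raise NoDataError(f"site {self.site_id!r} has no recorded activity")
        end = self.n_periods if through_period is None else through_period
        return PeriodCounts(self.site_id,
                            self.counts[self.first_active_period - 1:end],
                            first_active_period=1)


def period_index(date: dt.date, origin: dt.date, period_length: int = 7) -> int:
    """1-based period containing ``date``: floor((date - origin)/L) + 1."""
    return (date - origin).days // period_length + 1


def periodize(log: RecruitmentLog, site_id: str, period_length: int = 7,
              horizon: int | None = None, strict: bool = False) -> PeriodCounts:
    """Aggregate one site's events into per-period counts.

    By default the counts vector spans period 1 through the latest period
    containing an event for *any* site in the log (zero-filled gaps), so the
    sites of one log share a common horizon.  An explicit ``horizon``
    overrides this and truncates later events — used by monitoring to look
    at the trial "as of" a period.

    With ``strict=True`` a site absent from the log raises
    :class:`UnknownSiteError`; by default it yields all-zero counts, which
    is what monitoring needs for a planned site that has not started.
    """
    if period_length < 1:
        raise ValueError(f"period_length must be >= 1, got {period_length}")
    site_events = [ev for ev in log.events if ev.site_id == site_id]
    if strict and not site_events:
        raise UnknownSiteError(f"site {site_id!r} has no events in the log")
    if horizon is None:
        horizon = max((period_index(ev.date, log.origin, period_length)
                       for ev in log.events), default=0)
    counts = [0] * horizon
    first_active: int | None = None
    for ev in site_events:
        p = period_index(ev.date, log.origin, period_length)
        if p <= horizon:
            counts[p - 1] += ev.count
            first_active = p if first_active is None else min(first_active, p)
    return PeriodCounts(site_id, tuple(counts), first_active_period=first_active)


def periodize_all(log: RecruitmentLog, period_length: int = 7,
                  horizon: int | None = None,
                  site_ids: Sequence[str] | None = None) -> dict[str, PeriodCounts]:
    """Periodize every site (of the log, or of an explicit site list)."""
    ids = tuple(site_ids) if site_ids is not None else log.sites
    if horizon is None:
        horizon = max((period_index(ev.date, log.origin, period_length)
                       for ev in log.events), default=0)
    return {sid: periodize(log, sid, period_length, horizon=horizon) for sid in ids}
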