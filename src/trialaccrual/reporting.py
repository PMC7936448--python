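"""Report writers: JSON and CSV renderings of forecasts, overviews and GOF tables."""

from __future__ import annotations

import json
import sys
from pathlib import Path

import pandas as pd

from .inference import GofResult
from .model import TrialPlan
from .monitor import TrialOverview
from .simulate import TrialForecast

_ROUND = 6  # fixed rounding keeps reports byte-stable across runs


def _r(x: float | None) -> float | None:
    return None if x is None else round(float(x), _ROUND)


def forecast_report(forecast: TrialForecast, plan: TrialPlan) -> dict:
    sites = []
    for site in plan:
        est = forecast.per_site[site.site_id]
        sites.append({
            "site_id": site.site_id,
            "goal": est.goal,
            "rate": _r(est.rate),
            "delay": est.delay,
            "mean_duration": _r(est.mean),
            "ci_low": _r(est.ci_low),
            "ci_high": _r(est.ci_high),
            "end_period": _r(est.end_period),
            "determinative": site.site_id == forecast.determinative_site,
        })
    return {
        "period_unit": plan.period_unit,
        "sites": sites,
        "trial_duration": _r(forecast.trial_duration),
        "determinative_site": forecast.determinative_site,
        "trial_ci_low": _r(forecast.trial_ci_low),
        "trial_ci_high": _r(forecast.trial_ci_high),
    }


def forecast_table(forecast: TrialForecast, plan: TrialPlan) -> pd.DataFrame:
    return pd.DataFrame(forecast_report(forecast, plan)["sites"])


def overview_report(overview: TrialOverview, plan: TrialPlan) -> dict:
    statuses = []
    for site, status in zip(plan, overview.statuses):
        rd = status.remaining_duration
        statuses.append({
            "site_id": status.site_id,
            "goal": status.goal,
            "recruited": status.recruited,
            "remaining": status.remaining,
            "rate_hat": _r(status.rate_hat),
            "remaining_mean": _r(rd.mean) if rd is not None else None,
            "remaining_ci_low": _r(rd.ci_low) if rd is not None else None,
            "remaining_ci_high": _r(rd.ci_high) if rd is not None else None,
            "complete": status.complete,
            "stalled": status.stalled,
            "lat": site.lat,
            "lon": site.lon,
        })
    return {
        "current_period": overview.current_period,
        "total_recruited": overview.total_recruited,
        "cumulative_series": list(overview.cumulative_series),
        "determinant_site": overview.determinant_site,
        "expected_end_period": _r(overview.expected_end_period),
        "sites": statuses,
        "warnings": list(overview.warnings),
    }


def overview_table(overview: TrialOverview, plan: TrialPlan) -> pd.DataFrame:
    return pd.DataFrame(overview_report(overview, plan)["sites"])


def gof_report(result: GofResult, site_id: str) -> dict:
    return {
        "site_id": site_id,
        "rate_hat": _r(result.rate_hat),
        "n_periods": result.n_periods,
        "statistic": _r(result.statistic),
        "df": result.df,
        "p_value": _r(result.p_value),
        "bins": [{"category": b.label, "observed": b.observed,
                  "expected": _r(b.expected)} for b in result.bins],
    }


def gof_table(result: GofResult) -> pd.DataFrame:
    return pd.DataFrame([{"category": b.label, "observed": b.observed,
                          "expected": round(b.expected, _ROUND)}
                         for b in result.bins])


def write_json(obj: dict, dest: str | Path) -> None:
    """Write a report as sorted-key JSON; ``-`` writes to stdout."""
    text = json.dumps(obj, indent=2, sort_keys=True) + "\n"
    if str(dest) == "-":
        sys.stdout.write(text)
    else:
        Path(dest).write_text(text)


def write_csv(df: pd.DataFrame, dest: str | Path) -> None:
    if str(dest) == "-":
        sys.stdout.write(df.to_csv(index=False))
    else:
        df.to_csv(dest, index=False)


def plot_cumulative(series, dest: str | Path, period_unit: str = "week") -> None:
    """Step plot of cumulative recruitment over periods, saved to PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    periods = range(1, len(series) + 1)
    ax.step(periods, series, where="post")
    ax.set_xlabel(f"period ({period_unit})")
    ax.set_ylabel("cumulative recruitments")
    ax.set_title("Trial accrual to date")
    fig.tight_layout()
    fig.savefig(dest, dpi=100)
    plt.close(fig)
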