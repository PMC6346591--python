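"""Operational-mode one-step-ahead forecasting.

Each prediction is anchored on the *observed* state: carrying capacities
and the interval growth rate are estimated from the data, the logistic
increment is applied over the actual day gap, and the next observation
resets the anchor.  Because no prediction ever feeds back into a later
one, errors cannot propagate or amplify through time -- the trade-off is
that the horizon is a single monitoring interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibration import DROP_TOL, StandSeries
from .errors import InsufficientDataError
from .model import IBLine, SpeciesParams, StandState, project_to_ibl

__all__ = ["ForecastRecord", "forecast_operational", "forecast_error_summary"]


@dataclass(frozen=True)
class ForecastRecord:
    """Observed vs one-step-ahead predicted state at one monitoring date."""

    t: float
    b_obs: float
    d_obs: float
    b_pred: float
    d_pred: float
    r_used: float
    K_b: float
    K_d: float
    ok: bool = True
    note: str = ""

    @property
    def b_error(self) -> float:
        return self.b_pred - self.b_obs

    @property
    def d_error(self) -> float:
        return self.d_pred - self.d_obs


def _interval_rate(
    series: StandSeries,
    i: int,
    params: SpeciesParams,
    ibl: IBLine,
    tol: float = DROP_TOL,
) -> float | None:
    """Joint rate over interval i -> i+1, averaging the biomass- and
    density-derived linearized estimates; None when both are unusable."""
    dt = series.times[i + 1] - series.times[i]
    b0, d0 = series.b[i], series.d[i]
    caps = project_to_ibl(StandState(d=d0, b=b0), params.alpha1, ibl)
    rates = []
    if abs(b0) > tol and caps.K_b != 0:
        x = b0 / caps.K_b
        if abs(1.0 - x) > tol:
            y = (series.b[i + 1] - b0) / dt / (b0 * params.sin_theta)
            rates.append(y / (1.0 - x))
    if abs(d0) > tol and caps.K_d != 0:
        x = d0 / caps.K_d
        if abs(1.0 - x) > tol:
            y = (series.d[i + 1] - d0) / dt / (d0 * params.cos_theta)
            rates.append(y / (1.0 - x))
    if not rates:
        return None
    return float(np.mean(rates))


def forecast_operational(
    series: StandSeries,
    params: SpeciesParams,
    ibl: IBLine,
    r_source: str = "previous_interval",
) -> list[ForecastRecord]:
    """One-step-ahead forecasts along an observed series.

    For the step from observation i to i+1 the capacities are projected
    from the observed state at i and the increment uses the actual day
    gap.  The interval rate comes either from the interval just completed
    (``previous_interval`` -- an honest forecast, available from the second
    interval on) or from the interval being predicted itself
    (``same_interval`` -- an in-sample reconstruction).  Intervals whose
    rate is not estimable yield a flagged record with NaN predictions.
    """
    if r_source not in ("previous_interval", "same_interval"):
        raise ValueError(f"unknown r_source {r_source!r}")
    n_min = 3 if r_source == "previous_interval" else 2
    if len(series) < n_min:
        raise InsufficientDataError(
            f"{r_source} forecasting needs >= {n_min} observations, "
            f"got {len(series)}"
        )
    records: list[ForecastRecord] = []
    start = 1 if r_source == "previous_interval" else 0
    for i in range(start, len(series) - 1):
        dt = float(series.times[i + 1] - series.times[i])
        state = StandState(d=float(series.d[i]), b=float(series.b[i]))
        caps = project_to_ibl(state, params.alpha1, ibl)
        j = i - 1 if r_source == "previous_interval" else i
        r = _interval_rate(series, j, params, ibl)
        t_next = float(series.times[i + 1])
        obs = dict(t=t_next, b_obs=float(series.b[i + 1]),
                   d_obs=float(series.d[i + 1]), K_b=caps.K_b, K_d=caps.K_d)
        if r is None:
            records.append(ForecastRecord(
                b_pred=math.nan, d_pred=math.nan, r_used=math.nan,
                ok=False, note="interval rate not estimable", **obs))
            continue
        delta_b = dt * r * state.b * ((caps.K_b - state.b) / caps.K_b) * params.sin_theta
        delta_d = dt * r * state.d * ((caps.K_d - state.d) / caps.K_d) * params.cos_theta
        records.append(ForecastRecord(
            b_pred=state.b + delta_b, d_pred=state.d + delta_d,
            r_used=r, **obs))
    return records


def forecast_error_summary(records: list[ForecastRecord]) -> dict:
    """MAE, RMSE and bias (predicted minus observed) for b and d.

    Also returns the observed/predicted pairs for plotting.  Flagged
    records (no prediction) are excluded from the statistics but counted.
    """
    usable = [rec for rec in records if rec.ok]
    if not usable:
        raise InsufficientDataError("no records with predictions")
    out: dict = {"n": len(usable), "n_skipped": len(records) - len(usable)}
    for axis in ("b", "d"):
        err = np.array([getattr(rec, f"{axis}_error") for rec in usable])
        out[axis] = {
            "mae": float(np.mean(np.abs(err))),
            "rmse": float(np.sqrt(np.mean(err ** 2))),
            "bias": float(np.mean(err)),
        }
    out["pairs"] = {
        "t": [rec.t for rec in usable],
        "b_obs": [rec.b_obs for rec in usable],
        "b_pred": [rec.b_pred for rec in usable],
        "d_obs": [rec.d_obs for rec in usable],
        "d_pred": [rec.d_pred for rec in usable],
    }
    return out
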