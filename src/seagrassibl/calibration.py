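"""Parameter estimation from observed biomass-density time series.

Two parameters are estimated per species:

* ``theta`` — the allometry angle, as the arctangent of the slope of the
  dominant principal component of the pooled (d, b) covariance matrix
  (a type-II regression; both coordinates carry error).
* ``r`` — the joint instantaneous growth rate, from the linearized logistic
  model.  Scaling each coordinate by its projected carrying capacity turns
  every observation interval into a point on the line ``y = r (1 - x)``
  with ``x = b/K_b`` (or ``d/K_d``) and ``y`` the per-day log-scale rate
  divided by ``b sin(theta)`` (or ``d cos(theta)``).  Biomass- and
  density-derived points are pooled into a single regression, doubling the
  sample size; ``r`` is simultaneously the slope and the intercept of that
  line.

Per-interval rates ``r_i = y_i / (1 - x_i)`` support the growth/decay
envelopes (quantiles of the r_i) and seasonality profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDirectionError,
    IndeterminateRateError,
    InsufficientDataError,
)
from .model import IBLine, SpeciesParams, StandState, project_to_ibl

__all__ = [
    "StandSeries",
    "CalibrationPoint",
    "IntervalRate",
    "RateEstimate",
    "LinearizationResult",
    "estimate_theta_pca",
    "linearize_series",
    "fit_r",
    "seasonality_profile",
    "pooled_states",
]

#: log-unit tolerance below which a denominator (|b|, |d| or |1-x|) is
#: considered unusable; such points are dropped and counted
DROP_TOL = 1e-6


@dataclass
class StandSeries:
    """Time series of one monitored stand.

    ``times`` are days (numeric, strictly increasing); ``b`` and ``d`` are
    log10 biomass and log10 shoot density at those days.
    """

    study_id: str
    species: str
    times: np.ndarray
    b: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if not (len(self.times) == len(self.b) == len(self.d)):
            raise ValueError("times, b and d must have equal lengths")
        if len(self.times) and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"series {self.study_id!r}: times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def biomass(self) -> np.ndarray:
        """Raw above-ground biomass B = 10**b (g DW m^-2)."""
        return 10.0 ** self.b

    @property
    def density(self) -> np.ndarray:
        """Raw shoot density D = 10**d (shoots m^-2)."""
        return 10.0 ** self.d

    def states(self) -> list[StandState]:
        return [StandState(d=di, b=bi) for di, bi in zip(self.d, self.b)]


@dataclass(frozen=True)
class CalibrationPoint:
    """One interval's contribution to the linearized fit.

    ``x`` is the state scaled by its carrying capacity at the interval
    start; ``y`` is the per-day rate scaled to the joint-rate axis
    (day^-1).  ``source`` records whether the point came from the biomass
    or the density equation.
    """

    x: float
    y: float
    source: str  # "biomass" | "density"
    study_id: str
    t_start: float
    interval_days: float


@dataclass(frozen=True)
class IntervalRate:
    """Per-interval joint rate r_i = y_i / (1 - x_i) with its calendar anchor."""

    study_id: str
    t_start: float
    interval_days: float
    source: str
    r: float


@dataclass
class RateEstimate:
    """Pooled joint growth rate and its envelopes."""

    r_hat: float
    r_max: float
    r_min: float
    n_points: int
    per_interval: list[IntervalRate] = field(default_factory=list)
    q_max: float = 0.95
    q_min: float = 0.05

    def __post_init__(self) -> None:
        slack = 1e-9 * max(1.0, abs(self.r_hat))
        if not (self.r_min - slack <= self.r_hat <= self.r_max + slack):
            # quantile envelopes can exclude the pooled estimate only when
            # the point cloud is pathological; surface it
            warnings.warn(
                f"pooled r_hat={self.r_hat:.4g} outside envelope "
                f"[{self.r_min:.4g}, {self.r_max:.4g}]",
                UserWarning,
                stacklevel=2,
            )


@dataclass
class LinearizationResult:
    """Calibration points plus bookkeeping on dropped denominators."""

    points: list[CalibrationPoint]
    n_dropped: int = 0

    def __iter__(self) -> Iterator[CalibrationPoint]:
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)


def pooled_states(series: Iterable[StandSeries]) -> list[StandState]:
    """All observations of several series as a flat list of states."""
    out: list[StandState] = []
    for s in series:
        out.extend(s.states())
    return out


def estimate_theta_pca(
    points: Sequence[StandState],
    name: str = "pca-fit",
    eigengap_rtol: float = 1e-9,
) -> SpeciesParams:
    """Allometry angle from the dominant principal component of (d, b).

    The covariance matrix (not the correlation matrix) of the pooled
    scatter is eigendecomposed; the central-tendency slope is the ratio of
    the b-loading to the d-loading of the dominant eigenvector, with the
    sign normalized so the d-loading is positive.  The intercept places
    the line through the centroid.
    """
    if len(points) < 3:
        raise InsufficientDataError(
            f"PCA needs at least 3 states, got {len(points)}"
        )
    d = np.array([p.d for p in points], dtype=float)
    b = np.array([p.b for p in points], dtype=float)
    cov = np.cov(np.vstack([d, b]))
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    lam_minor, lam_major = evals
    scale = max(abs(lam_major), abs(lam_minor), 1e-300)
    if (lam_major - lam_minor) / scale <= eigengap_rtol:
        raise DegenerateDirectionError(
            "point cloud is isotropic (equal eigenvalues): no dominant "
            "biomass-density direction"
        )
    vd, vb = evecs[:, 1]  # dominant eigenvector: (d-loading, b-loading)
    if vd < 0:
        vd, vb = -vd, -vb
    if abs(vd) < 1e-15:
        raise DegenerateDirectionError(
            "dominant direction is vertical: slope delta_b/delta_d undefined"
        )
    alpha1 = vb / vd
    if alpha1 <= 0:
        warnings.warn(
            f"central-tendency slope is non-positive ({alpha1:.4g}); the "
            "growth model assumes biomass and density grow jointly",
            UserWarning,
            stacklevel=2,
        )
        # theta must stay in (0, pi/2) for SpeciesParams; report the raw
        # slope via a minimal positive angle is wrong -- fail loudly instead
        raise DegenerateDirectionError(
            f"central-tendency slope {alpha1:.4g} <= 0 is outside the "
            "model's joint-growth domain"
        )
    alpha0 = float(np.mean(b) - alpha1 * np.mean(d))
    return SpeciesParams.from_slope(name, alpha1, alpha0=alpha0)


def linearize_series(
    series: StandSeries,
    params: SpeciesParams,
    ibl: IBLine,
    drop_tol: float = DROP_TOL,
) -> LinearizationResult:
    """Turn consecutive observation pairs into calibration points.

    For each interval the carrying capacities are projected from the state
    at the interval *start*, matching the simulator's step convention.
    Each usable interval yields one biomass-sourced and one density-sourced
    point; a point whose denominator (|b| or |d|) falls below ``drop_tol``
    is dropped and counted.
    """
    if len(series) < 2:
        raise InsufficientDataError(
            f"series {series.study_id!r} has {len(series)} observations; "
            "need at least 2"
        )
    sin_t, cos_t = params.sin_theta, params.cos_theta
    points: list[CalibrationPoint] = []
    n_dropped = 0
    for i in range(len(series) - 1):
        dt = series.times[i + 1] - series.times[i]
        b0, d0 = series.b[i], series.d[i]
        caps = project_to_ibl(StandState(d=d0, b=b0), params.alpha1, ibl)
        db_dt = (series.b[i + 1] - b0) / dt
        dd_dt = (series.d[i + 1] - d0) / dt
        common = dict(study_id=series.study_id, t_start=float(series.times[i]),
                      interval_days=float(dt))
        if abs(b0) < drop_tol or caps.K_b == 0:
            n_dropped += 1
        else:
            points.append(CalibrationPoint(
                x=b0 / caps.K_b, y=db_dt / (b0 * sin_t), source="biomass", **common))
        if abs(d0) < drop_tol or caps.K_d == 0:
            n_dropped += 1
        else:
            points.append(CalibrationPoint(
                x=d0 / caps.K_d, y=dd_dt / (d0 * cos_t), source="density", **common))
    if not points:
        warnings.warn(
            f"series {series.study_id!r}: every calibration point was dropped "
            f"({n_dropped} unusable denominators)",
            UserWarning,
            stacklevel=2,
        )
    return LinearizationResult(points=points, n_dropped=n_dropped)


def fit_r(
    points: Iterable[CalibrationPoint],
    q_max: float = 0.95,
    q_min: float = 0.05,
    w_tol: float = DROP_TOL,
) -> RateEstimate:
    """Pooled least-squares estimate of the joint growth rate.

    Minimizing ``sum (y - r (1 - x))^2`` over the pooled biomass and
    density points gives the closed form
    ``r_hat = sum y (1 - x) / sum (1 - x)^2``.  Per-interval rates
    ``r_i = y_i / (1 - x_i)`` (for ``|1 - x|`` above ``w_tol``) feed the
    growth/decay envelopes, taken as the ``q_max``/``q_min`` quantiles.
    """
    pts = list(points)
    w = np.array([1.0 - p.x for p in pts], dtype=float)
    y = np.array([p.y for p in pts], dtype=float)
    usable = np.abs(w) > w_tol
    if usable.sum() < 2:
        raise IndeterminateRateError(
            "fewer than 2 calibration points away from the carrying capacity "
            "(|1 - x| above tolerance): r is indeterminate"
        )
    denom = float(np.sum(w * w))
    r_hat = float(np.sum(y * w) / denom)
    per_interval = [
        IntervalRate(
            study_id=p.study_id,
            t_start=p.t_start,
            interval_days=p.interval_days,
            source=p.source,
            r=float(p.y / (1.0 - p.x)),
        )
        for p, ok in zip(pts, usable)
        if ok
    ]
    rates = np.array([ir.r for ir in per_interval])
    r_max = float(np.quantile(rates, q_max))
    r_min = float(np.quantile(rates, q_min))
    return RateEstimate(
        r_hat=r_hat,
        r_max=r_max,
        r_min=r_min,
        n_points=len(pts),
        per_interval=per_interval,
        q_max=q_max,
        q_min=q_min,
    )


def seasonality_profile(
    estimate: RateEstimate,
    period_days: float = 365.0,
    n_bins: int = 12,
) -> pd.DataFrame:
    """Descriptive seasonal profile of the per-interval rates.

    Intervals are binned by the phase of their start day within
    ``period_days`` (twelve month-like bins by default).  Returns one row
    per occupied bin with the median rate, the interquartile spread and
    the interval count.  This is purely descriptive: the model itself has
    no seasonal forcing, seasonality enters through the rate schedule.
    """
    if not estimate.per_interval:
        raise InsufficientDataError("no per-interval rates: nothing to bin")
    t_start = np.array([ir.t_start for ir in estimate.per_interval], dtype=float)
    if not np.all(np.isfinite(t_start)):
        raise ValueError(
            "per-interval rates lack calendar anchors; supply observation "
            "times as day-of-year (or days since a calendar date)"
        )
    rates = np.array([ir.r for ir in estimate.per_interval], dtype=float)
    phase = np.mod(t_start, period_days)
    edges = np.linspace(0.0, period_days, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    rows = []
    for k in range(n_bins):
        sel = idx == k
        if not sel.any():
            continue
        rk = rates[sel]
        rows.append({
            "bin": k,
            "phase_start": edges[k],
            "phase_end": edges[k + 1],
            "r_median": float(np.median(rk)),
            "r_q25": float(np.quantile(rk, 0.25)),
            "r_q75": float(np.quantile(rk, 0.75)),
            "n": int(sel.sum()),
        })
    return pd.DataFrame(rows)


def calibrate_species(
    series: Sequence[StandSeries],
    ibl: IBLine,
    theta_params: SpeciesParams | None = None,
    q_max: float = 0.95,
    q_min: float = 0.05,
    name: str = "calibrated",
) -> tuple[SpeciesParams, RateEstimate, int]:
    """Full calibration pipeline for one species.

    Pools all observations for the PCA angle (unless ``theta_params`` is
    given), linearizes every series against that angle, and fits the
    pooled rate.  Returns (params with fitted rates, rate estimate,
    dropped-point count).
    """
    if theta_params is None:
        theta_params = estimate_theta_pca(pooled_states(series), name=name)
    points: list[CalibrationPoint] = []
    n_dropped = 0
    for s in series:
        res = linearize_series(s, theta_params, ibl)
        points.extend(res.points)
        n_dropped += res.n_dropped
    estimate = fit_r(points, q_max=q_max, q_min=q_min)
    fitted = SpeciesParams.from_theta(
        theta_params.name,
        theta_params.theta,
        alpha0=theta_params.alpha0,
        r_max=max(estimate.r_max, 0.0),
        r_min=min(estimate.r_min, 0.0),
    )
    return fitted, estimate, n_dropped
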