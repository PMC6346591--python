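"""Core biomass-density instantaneous growth model.

Stands are described in bi-logarithmic space: ``d = log10(D)`` with D the
shoot density (shoots m^-2) and ``b = log10(B)`` with B the above-ground
biomass (g DW m^-2).  Growth of both coordinates follows a discrete
logistic update whose carrying capacities are not free parameters: at every
step they are re-projected onto the taxon's interspecific boundary line
(IBL) along the species' central-tendency slope ``alpha1 = tan(theta)``.

The angle ``theta`` partitions the single joint growth rate ``r`` (day^-1)
into a biomass component ``r*sin(theta)`` and a density component
``r*cos(theta)``; ``theta = pi/4`` is the isometric null model in which
biomass grows only by adding shoots of fixed adult mass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence, Union

from .errors import (
    DegenerateGeometryError,
    GrowthDomainWarning,
    SimulationError,
    ZeroCapacityError,
)

__all__ = [
    "IBLine",
    "SpeciesParams",
    "StandState",
    "CarryingCapacities",
    "GrowthIncrement",
    "RateSchedule",
    "project_to_ibl",
    "logistic_step",
    "simulate",
    "make_isometric_params",
]

#: tolerance below which the projection direction is treated as parallel
#: to the boundary line (slope units, dimensionless)
PARALLEL_TOL = 1e-9


@dataclass(frozen=True)
class IBLine:
    """Interspecific boundary line ``b = beta0 + beta1 * d``.

    The line is an upper bound in the (d, b) plane that no stand of the
    taxon group crosses; its slope is negative (denser stands support less
    biomass per shoot at maximal space occupation).
    """

    beta0: float
    beta1: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.beta0) and math.isfinite(self.beta1)):
            raise ValueError("boundary-line coefficients must be finite")
        if self.beta1 >= 0:
            raise ValueError(f"boundary-line slope must be negative, got {self.beta1}")

    def biomass_at(self, d: float) -> float:
        """Log-biomass of the boundary at log-density ``d``."""
        return self.beta0 + self.beta1 * d

    def residual(self, d: float, b: float) -> float:
        """Signed vertical distance of (d, b) to the line (negative below)."""
        return b - self.biomass_at(d)


@dataclass(frozen=True)
class SpeciesParams:
    """Species-level model parameters.

    ``alpha1`` is kept consistent with ``theta`` (``alpha1 = tan(theta)``);
    use :meth:`from_theta` or :meth:`from_slope` to build instances.
    ``alpha0`` is the intercept of the central-tendency line through the
    centroid of the species' (d, b) scatter; it is optional because the
    dynamics only need the slope.
    """

    name: str
    theta: float
    alpha1: float
    alpha0: float | None = None
    r_max: float | None = None
    r_min: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.theta < math.pi / 2:
            raise ValueError(f"theta must lie in (0, pi/2), got {self.theta}")
        if not math.isclose(self.alpha1, math.tan(self.theta), rel_tol=0, abs_tol=1e-12):
            raise ValueError(
                f"alpha1={self.alpha1} inconsistent with tan(theta)={math.tan(self.theta)}"
            )
        if self.r_max is not None and self.r_max < 0:
            raise ValueError("r_max must be >= 0")
        if self.r_min is not None and self.r_min > 0:
            raise ValueError("r_min must be <= 0")

    @classmethod
    def from_theta(
        cls,
        name: str,
        theta: float,
        alpha0: float | None = None,
        r_max: float | None = None,
        r_min: float | None = None,
    ) -> "SpeciesParams":
        return cls(name, theta, math.tan(theta), alpha0, r_max, r_min)

    @classmethod
    def from_slope(
        cls,
        name: str,
        alpha1: float,
        alpha0: float | None = None,
        r_max: float | None = None,
        r_min: float | None = None,
    ) -> "SpeciesParams":
        return cls(name, math.atan(alpha1), alpha1, alpha0, r_max, r_min)

    def with_alpha0(self, alpha0: float) -> "SpeciesParams":
        return replace(self, alpha0=alpha0)

    @property
    def sin_theta(self) -> float:
        return math.sin(self.theta)

    @property
    def cos_theta(self) -> float:
        return math.cos(self.theta)


@dataclass(frozen=True)
class StandState:
    """One stand observation in log space: d = log10 density, b = log10 biomass.

    Values may be negative (biomass below 1 g DW m^-2 or density below
    1 shoot m^-2 are legitimate, if extreme, stands).
    """

    d: float
    b: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.d) and math.isfinite(self.b)):
            raise ValueError(f"stand state must be finite, got (d={self.d}, b={self.b})")


@dataclass(frozen=True)
class CarryingCapacities:
    """Boundary-line point (K_d, K_b) acting as the current carrying capacity."""

    K_d: float
    K_b: float


@dataclass(frozen=True)
class GrowthIncrement:
    """One forward-difference update (delta_d, delta_b) over dt days."""

    delta_b: float
    delta_d: float
    dt: float


#: a joint growth rate specification: a constant (day^-1), a per-step
#: sequence, or a callable of the elapsed time in days
RateSchedule = Union[float, Sequence[float], Callable[[float], float]]


def project_to_ibl(state: StandState, alpha1: float, ibl: IBLine) -> CarryingCapacities:
    """Carrying capacities: intersection of the boundary line with the
    line of slope ``alpha1`` through ``state``.

    Solves ``K_d = (b - beta0 - alpha1*d) / (beta1 - alpha1)`` and
    ``K_b = beta0 + beta1 * K_d``.
    """
    denom = ibl.beta1 - alpha1
    if abs(denom) < PARALLEL_TOL:
        raise DegenerateGeometryError(
            f"projection slope alpha1={alpha1} is parallel to the boundary "
            f"slope beta1={ibl.beta1}: no unique intersection"
        )
    K_d = (state.b - ibl.beta0 - alpha1 * state.d) / denom
    K_b = ibl.beta0 + ibl.beta1 * K_d
    return CarryingCapacities(K_d=K_d, K_b=K_b)


def logistic_step(
    state: StandState,
    caps: CarryingCapacities,
    r: float,
    theta: float,
    dt: float,
) -> GrowthIncrement:
    """One forward-Euler logistic update of the log-space coordinates.

    delta_b = dt * r * b * (K_b - b)/K_b * sin(theta)
    delta_d = dt * r * d * (K_d - d)/K_d * cos(theta)

    The update is an exact forward difference: no sub-stepping, no
    integrator.  For b <= 0 (or d <= 0) the logistic term changes sign,
    which is surfaced as a :class:`GrowthDomainWarning` rather than hidden.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if caps.K_b == 0:
        raise ZeroCapacityError("biomass carrying capacity K_b is zero")
    if caps.K_d == 0:
        raise ZeroCapacityError("density carrying capacity K_d is zero")
    if state.b <= 0 or state.d <= 0:
        warnings.warn(
            f"non-positive log state (d={state.d}, b={state.b}): the logistic "
            "term reverses sign at zero",
            GrowthDomainWarning,
            stacklevel=2,
        )
    delta_b = dt * r * state.b * ((caps.K_b - state.b) / caps.K_b) * math.sin(theta)
    delta_d = dt * r * state.d * ((caps.K_d - state.d) / caps.K_d) * math.cos(theta)
    return GrowthIncrement(delta_b=delta_b, delta_d=delta_d, dt=dt)


def _rate_at(schedule: RateSchedule, step: int, t_days: float) -> float:
    if callable(schedule):
        return float(schedule(t_days))
    if isinstance(schedule, (int, float)):
        return float(schedule)
    return float(schedule[step])


def simulate(
    initial: StandState,
    params: SpeciesParams,
    ibl: IBLine,
    r_schedule: RateSchedule,
    dt: float = 1.0,
    n_steps: int = 365,
) -> list[StandState]:
    """Iterate the model ``n_steps`` times from ``initial``.

    At the start of every step the carrying capacities are re-projected
    from the *current* state, then one logistic step is applied.  Returns
    the full trajectory (``n_steps + 1`` states, initial state included).

    ``r_schedule`` may be a constant rate (day^-1), a sequence with one
    rate per step, or a callable of elapsed days (evaluated at the step's
    start time).
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    states = [initial]
    state = initial
    for k in range(n_steps):
        try:
            r = _rate_at(r_schedule, k, k * dt)
            caps = project_to_ibl(state, params.alpha1, ibl)
            inc = logistic_step(state, caps, r, params.theta, dt)
        except (ValueError, ZeroDivisionError, IndexError) as exc:
            raise SimulationError(f"step {k} (t={k * dt:g} d): {exc}") from exc
        state = StandState(d=state.d + inc.delta_d, b=state.b + inc.delta_b)
        states.append(state)
    return states


def make_isometric_params(name: str = "H0") -> SpeciesParams:
    """Isometric null-model parameters: alpha1 = 1, theta = arctan(1) = pi/4.

    Under isometry the allometric exponent of B on D is one: stand biomass
    grows exclusively by iterating new shoots of fixed adult mass, so
    biomass and density advance in lockstep on log axes (theta ~ 0.785).
    """
    return SpeciesParams(name=name, theta=math.atan(1.0), alpha1=1.0)
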