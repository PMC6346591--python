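"""Synthetic seagrass monitoring data.

Emulates the structure of compiled multi-study biomass-density series:
irregular sampling at roughly monthly-to-quarterly intervals, seasonal
alternation of growth and decay, and log-space observation scatter around
a species' central tendency below the seagrass boundary line.  Everything
is seeded and reproducible; raw biomass/density are exactly ``10**b`` and
``10**d`` of the generated log states.

Two ground-truth modes are available:

* default -- the trajectory is iterated at dt = 1 day and observed at the
  sampled dates.  Finite-difference rates over long gaps then deviate
  slightly from the generating rate, as they do in real monitoring data.
* ``exact`` -- one model step spans each observation gap, so the
  linearized calibration inverts the generator algebraically; used for
  exact parameter-recovery checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .calibration import StandSeries
from .errors import BoundaryViolationWarning
from .model import (
    IBLine,
    SpeciesParams,
    StandState,
    logistic_step,
    project_to_ibl,
    simulate,
)
from .presets import IBL_PRESETS, load_preset

__all__ = [
    "ConstantRate",
    "SeasonalRate",
    "SinusoidRate",
    "ScenarioConfig",
    "generate_series",
    "generate_multistudy",
    "sample_central_states",
    "scenario_from_dict",
    "load_scenarios",
]


@dataclass(frozen=True)
class ConstantRate:
    """Time-invariant joint growth rate (day^-1)."""

    r: float

    def __call__(self, day: float) -> float:
        return self.r


@dataclass(frozen=True)
class SeasonalRate:
    """Two-block seasonal schedule: growth inside a day-of-year window,
    decay outside it (both day^-1)."""

    r_growth: float
    r_decay: float
    growth_start: float = 80.0
    growth_end: float = 260.0
    period: float = 365.0

    def __call__(self, day: float) -> float:
        phase = day % self.period
        return self.r_growth if self.growth_start <= phase < self.growth_end else self.r_decay


@dataclass(frozen=True)
class SinusoidRate:
    """Smooth seasonal schedule r(t) = mean + amplitude * sin(2 pi (t - phase)/period)."""

    mean: float
    amplitude: float
    phase_day: float = 80.0
    period: float = 365.0

    def __call__(self, day: float) -> float:
        return self.mean + self.amplitude * math.sin(
            2.0 * math.pi * (day - self.phase_day) / self.period
        )


@dataclass
class ScenarioConfig:
    """One synthetic study: a species, a rate schedule, initial stands,
    a sampling design and an observation-noise level.

    ``noise_sd_b``/``noise_sd_d`` are standard deviations of additive
    Gaussian noise in log10 units (multiplicative on the raw scales).
    Defaults emulate monthly monitoring over two years with a few days of
    scheduling jitter.
    """

    species: SpeciesParams
    r_schedule: object  # ConstantRate | SeasonalRate | SinusoidRate | float
    initial_states: Sequence[StandState]
    ibl: IBLine = field(default_factory=lambda: IBL_PRESETS["seagrass"])
    interval_days: float = 30.0
    jitter_days: float = 0.0
    n_obs: int = 24
    noise_sd_b: float = 0.0
    noise_sd_d: float = 0.0
    seed: int = 0
    start_day: float = 0.0
    exact: bool = False
    study_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.interval_days <= 0:
            raise ValueError("interval_days must be positive")
        if self.noise_sd_b < 0 or self.noise_sd_d < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_obs < 2:
            raise ValueError("need at least 2 observations per series")
        if not self.initial_states:
            raise ValueError("at least one initial state is required")
        if isinstance(self.r_schedule, (int, float)):
            self.r_schedule = ConstantRate(float(self.r_schedule))


def _sample_days(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Observation days: regular grid plus uniform jitter, integer-valued,
    strictly increasing (monitoring dates are whole days)."""
    gaps = np.full(cfg.n_obs - 1, cfg.interval_days)
    if cfg.jitter_days > 0:
        gaps = gaps + rng.uniform(-cfg.jitter_days, cfg.jitter_days, cfg.n_obs - 1)
    gaps = np.maximum(np.round(gaps), 1.0)
    return np.concatenate([[round(cfg.start_day)], round(cfg.start_day) + np.cumsum(gaps)])


def _exact_trajectory(
    cfg: ScenarioConfig, state0: StandState, days: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One forward step per observation gap (model-exact at the sampling
    resolution)."""
    b = [state0.b]
    d = [state0.d]
    state = state0
    for t0, t1 in zip(days[:-1], days[1:]):
        caps = project_to_ibl(state, cfg.species.alpha1, cfg.ibl)
        r = cfg.r_schedule(t0)
        inc = logistic_step(state, caps, r, cfg.species.theta, t1 - t0)
        state = StandState(d=state.d + inc.delta_d, b=state.b + inc.delta_b)
        b.append(state.b)
        d.append(state.d)
    return np.array(d), np.array(b)


def _daily_trajectory(
    cfg: ScenarioConfig, state0: StandState, days: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate at dt = 1 day and read the states off at the sampled days."""
    t0 = days[0]
    n_steps = int(days[-1] - t0)
    states = simulate(
        state0, cfg.species, cfg.ibl,
        r_schedule=lambda t: cfg.r_schedule(t0 + t),
        dt=1.0, n_steps=n_steps,
    )
    idx = (days - t0).astype(int)
    d = np.array([states[i].d for i in idx])
    b = np.array([states[i].b for i in idx])
    return d, b


def generate_series(config: ScenarioConfig) -> list[StandSeries]:
    """Generate one noisy series per initial state in the scenario.

    Initial states above the boundary line are rejected (the model domain
    is the region below the boundary).  After noise is added, observations
    more than three noise standard deviations above the boundary trigger a
    warning -- the generator emulates scatter *below* the line.
    """
    rng = np.random.default_rng(config.seed)
    out: list[StandSeries] = []
    multi = len(config.initial_states) > 1
    for k, state0 in enumerate(config.initial_states):
        if config.ibl.residual(state0.d, state0.b) > 0:
            raise ValueError(
                f"initial state (d={state0.d}, b={state0.b}) lies above the "
                "boundary line; the model is only valid below it"
            )
        days = _sample_days(config, rng)
        if config.exact:
            d, b = _exact_trajectory(config, state0, days)
        else:
            d, b = _daily_trajectory(config, state0, days)
        if config.noise_sd_b > 0:
            b = b + rng.normal(0.0, config.noise_sd_b, size=b.shape)
        if config.noise_sd_d > 0:
            d = d + rng.normal(0.0, config.noise_sd_d, size=d.shape)
        guard = 3.0 * max(config.noise_sd_b, config.noise_sd_d)
        above = config.ibl.residual(d, b) > guard
        if np.any(above):
            warnings.warn(
                f"{int(above.sum())} generated observation(s) lie more than "
                "3 noise sd above the boundary line",
                BoundaryViolationWarning,
                stacklevel=2,
            )
        sid = f"{config.study_id}/site{k + 1}" if multi else config.study_id
        out.append(StandSeries(
            study_id=sid, species=config.species.name, times=days, b=b, d=d))
    return out


def generate_multistudy(
    configs: Sequence[ScenarioConfig], species: str | None = None
) -> list[StandSeries]:
    """Concatenate several scenarios into one pooled multi-study dataset.

    Scenarios must carry distinct study_ids; heterogeneous initial states
    and sampling intervals across configs emulate between-study scatter.
    """
    if not configs:
        raise ValueError("need at least one scenario config")
    ids = [c.study_id for c in configs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate study_ids across scenarios: {dupes}")
    out: list[StandSeries] = []
    for cfg in configs:
        series = generate_series(cfg)
        if species is not None:
            for s in series:
                s.species = species
        out.extend(series)
    return out


def sample_central_states(
    params: SpeciesParams,
    n: int,
    d_range: tuple[float, float] = (2.0, 4.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    alpha0: float | None = None,
) -> list[StandState]:
    """Stand states scattered along the species' central-tendency line.

    Emulates a compiled multi-study snapshot: log-densities uniform over
    ``d_range``, log-biomass on ``b = alpha0 + alpha1 * d`` plus Gaussian
    noise of sd ``noise_sd`` on both coordinates.  With ``noise_sd = 0``
    the states are exactly collinear, which is the layout under which the
    principal-component angle estimate is exact.
    """
    a0 = alpha0 if alpha0 is not None else params.alpha0
    if a0 is None:
        raise ValueError("central-tendency intercept alpha0 is required")
    rng = np.random.default_rng(seed)
    d = rng.uniform(*d_range, size=n)
    b = a0 + params.alpha1 * d
    if noise_sd > 0:
        d = d + rng.normal(0.0, noise_sd, size=n)
        b = b + rng.normal(0.0, noise_sd, size=n)
    return [StandState(d=float(di), b=float(bi)) for di, bi in zip(d, b)]


def _schedule_from_dict(spec) -> object:
    if isinstance(spec, (int, float)):
        return ConstantRate(float(spec))
    kind = spec.get("type", "constant")
    if kind == "constant":
        return ConstantRate(float(spec["r"]))
    if kind == "seasonal":
        return SeasonalRate(
            r_growth=float(spec["growth"]),
            r_decay=float(spec["decay"]),
            growth_start=float(spec.get("growth_start", 80)),
            growth_end=float(spec.get("growth_end", 260)),
            period=float(spec.get("period", 365)),
        )
    if kind == "sinusoid":
        return SinusoidRate(
            mean=float(spec.get("mean", 0.0)),
            amplitude=float(spec["amplitude"]),
            phase_day=float(spec.get("phase_day", 80)),
            period=float(spec.get("period", 365)),
        )
    raise ValueError(f"unknown rate-schedule type {kind!r}")


def scenario_from_dict(doc: dict) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from a plain mapping (YAML-friendly)."""
    sp = doc["species"]
    if isinstance(sp, str):
        params = load_preset(sp)
        if isinstance(params, IBLine):
            raise ValueError(f"{sp!r} is a boundary-line preset, not a species")
    else:
        params = SpeciesParams.from_theta(
            sp.get("name", "custom"), float(sp["theta"]),
            alpha0=sp.get("alpha0"),
        )
    ibl = doc.get("ibl", "seagrass")
    if isinstance(ibl, str):
        ibl = IBL_PRESETS[ibl]
    else:
        ibl = IBLine(float(ibl["beta0"]), float(ibl["beta1"]))
    sampling = doc.get("sampling", {})
    noise = doc.get("noise_sd", {})
    if isinstance(noise, (int, float)):
        noise = {"b": noise, "d": noise}
    return ScenarioConfig(
        species=params,
        r_schedule=_schedule_from_dict(doc.get("r", 0.0)),
        initial_states=[StandState(d=float(d), b=float(b))
                        for d, b in doc["initial_states"]],
        ibl=ibl,
        interval_days=float(sampling.get("interval_days", 30)),
        jitter_days=float(sampling.get("jitter_days", 0)),
        n_obs=int(sampling.get("n_obs", 24)),
        noise_sd_b=float(noise.get("b", 0.0)),
        noise_sd_d=float(noise.get("d", 0.0)),
        seed=int(doc.get("seed", 0)),
        start_day=float(doc.get("start_day", 0)),
        exact=bool(doc.get("exact", False)),
        study_id=str(doc.get("study_id", "synthetic")),
    )


def load_scenarios(path) -> list[ScenarioConfig]:
    """Read scenario configs from a YAML file (single doc or ``scenarios:`` list)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, dict) and "scenarios" in doc:
        return [scenario_from_dict(d) for d in doc["scenarios"]]
    return [scenario_from_dict(doc)]
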