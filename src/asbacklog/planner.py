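"""Strategy surfaces, isoclines and inverse capacity planning.

Answers the planning questions: what does each combination of conversion
fraction p and capacity increase c deliver (grid/heatmap), which
combinations deliver the same outcome (isocline), and how much capacity is
needed at a given conversion level to hit a target (inverse).

In ``mc-mean`` mode every cell and every root-finding candidate reuses one
fixed set of Monte-Carlo draws (common random numbers), which makes the
outcome a smooth, strictly monotone function of c and the inversion
well-posed. Isoclines are traced by per-column root finding in c rather
than by a marching-squares contouring pass, so each returned point can be
verified independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import mc_uncertainty, model_core, strategies
from .mc_uncertainty import DEFAULT_N, DEFAULT_SEED
from .model_core import PopulationParams
from .strategies import ConversionRatio, Strategy

__all__ = [
    "BracketError",
    "LevelUnattainableError",
    "StrategyGrid",
    "Isocline",
    "compute_grid",
    "find_capacity_for_deaths",
    "find_capacity_for_time",
    "extract_isocline",
]

Mode = Literal["point", "mc-mean"]

#: root-located c is accurate to this tolerance
C_XTOL = 1e-6
#: tiny lower bracket used when c = 0 leaves zero surplus (p = 0)
_C_EPS = 1e-9


class BracketError(ValueError):
    """Target outcome outside the attainable range over [0, c_max]."""


class LevelUnattainableError(ValueError):
    """An isocline level attained at no point of the p axis."""


@dataclass(frozen=True)
class StrategyGrid:
    """Outcome surfaces over the (conversion p, capacity c) plane.

    Matrices are indexed ``[i, j]`` for ``c_axis[i]`` (rows) and
    ``p_axis[j]`` (columns), matching a heatmap with c on the y axis.
    The zero-surplus cell (p = 0, c = 0) never clears: it carries
    ``inf`` days and, as a severity marker, the 1-year zero-surplus
    death toll; ``non_clearing`` flags such cells.
    """

    p_axis: np.ndarray
    c_axis: np.ndarray
    tc_days: np.ndarray
    deaths: np.ndarray
    non_clearing: np.ndarray
    mode: Mode
    n: int | None = None
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per cell with columns p, c, tc_days, deaths."""
        cc, pp = np.meshgrid(self.c_axis, self.p_axis, indexing="ij")
        return pd.DataFrame(
            {
                "p": pp.ravel(),
                "c": cc.ravel(),
                "tc_days": self.tc_days.ravel(),
                "deaths": self.deaths.ravel(),
                "non_clearing": self.non_clearing.ravel(),
            }
        )


@dataclass(frozen=True)
class Isocline:
    """A level curve of constant outcome in the (p, c) plane."""

    level: float
    outcome: Literal["time", "deaths"]
    points: list[tuple[float, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["p", "c"])


def _make_objective(
    params: PopulationParams,
    p: float,
    ratio: ConversionRatio,
    outcome: Literal["time", "deaths"],
    mode: Mode,
    n: int,
    seed: int,
) -> Callable[[float], float]:
    """Outcome (tc in days or deaths) as a function of c, draws held fixed."""
    if mode == "mc-mean":
        w0_dist, mu_dist = mc_uncertainty.default_distributions(params)
        w0, mu = mc_uncertainty.draw_parameters(w0_dist, mu_dist, n, seed)

    def objective(c: float) -> float:
        strat = Strategy(
            capacity_increase=c,
            conversion_fraction=p,
            ratio=ratio,
            allow_above_cap=True,
        )
        Te = strategies.total_surplus(params, strat)
        if Te <= 0:
            Te = _C_EPS  # continuous limit of the zero-surplus corner
        if mode == "mc-mean":
            tc_days, deaths = mc_uncertainty.mc_outcomes(
                Te, w0, mu, params.days_per_year
            )
            return float(tc_days.mean() if outcome == "time" else deaths.mean())
        res = model_core.point_estimate(params, Te)
        return res.tc_days if outcome == "time" else res.deaths

    return objective


def compute_grid(
    params: PopulationParams,
    p_axis,
    c_axis,
    ratio: ConversionRatio | None = None,
    mode: Mode = "mc-mean",
    n: int = DEFAULT_N,
    seed: int = DEFAULT_SEED,
) -> StrategyGrid:
    """Evaluate clearance time and deaths on a (p, c) grid.

    ``mc-mean`` mode draws one parameter set and reuses it for every cell
    (common random numbers), so neighbouring cells differ only through Te
    and the surfaces are monotone along both axes.
    """
    ratio = ratio or ConversionRatio()
    p_axis = np.asarray(p_axis, dtype=float)
    c_axis = np.asarray(c_axis, dtype=float)
    conv = np.array([strategies.conversion_surplus(params, p, ratio) if p > 0
                     else 0.0 for p in p_axis])
    # Te[i, j] for c_axis[i], p_axis[j]
    Te = conv[None, :] + c_axis[:, None] * (params.baseline_throughput + conv[None, :])
    non_clearing = Te <= 0.0

    tc_days = np.empty_like(Te)
    deaths = np.empty_like(Te)
    if mode == "mc-mean":
        w0_dist, mu_dist = mc_uncertainty.default_distributions(params)
        w0, mu = mc_uncertainty.draw_parameters(w0_dist, mu_dist, n, seed)
        for idx in np.ndindex(Te.shape):
            if non_clearing[idx]:
                continue
            tc_d, d = mc_uncertainty.mc_outcomes(
                float(Te[idx]), w0, mu, params.days_per_year
            )
            tc_days[idx] = tc_d.mean()
            deaths[idx] = d.mean()
    elif mode == "point":
        ok = ~non_clearing
        tc_years = model_core.clearance_time(
            params.W0_mean, params.mu_mean, np.where(ok, Te, 1.0)
        )
        tc_days[ok] = (tc_years * params.days_per_year)[ok]
        deaths[ok] = (params.W0_mean - Te * tc_years)[ok]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    tc_days[non_clearing] = np.inf
    deaths[non_clearing] = model_core.deaths_by_time(
        params.W0_mean, params.mu_mean, 1.0
    )
    return StrategyGrid(
        p_axis=p_axis,
        c_axis=c_axis,
        tc_days=tc_days,
        deaths=deaths,
        non_clearing=non_clearing,
        mode=mode,
        n=n if mode == "mc-mean" else None,
        seed=seed if mode == "mc-mean" else None,
    )


def _invert(
    params: PopulationParams,
    target: float,
    p: float,
    ratio: ConversionRatio | None,
    outcome: Literal["time", "deaths"],
    mode: Mode,
    c_max: float,
    n: int,
    seed: int,
) -> float:
    ratio = ratio or ConversionRatio()
    f = _make_objective(params, p, ratio, outcome, mode, n, seed)
    lo = 0.0 if (p > 0) else _C_EPS  # p = 0, c = 0 has no surplus
    f_lo, f_hi = f(lo), f(c_max)
    # both outcomes decrease in c
    if not (f_hi <= target <= f_lo):
        raise BracketError(
            f"target {outcome} {target:g} outside the attainable range "
            f"[{f_hi:.6g}, {f_lo:.6g}] for c in [0, {c_max:g}] at p={p:g}"
        )
    if f_lo == target:
        return float(lo)
    if f_hi == target:
        return float(c_max)
    c_star = brentq(lambda c: f(c) - target, lo, c_max, xtol=C_XTOL)
    return float(c_star)


def find_capacity_for_deaths(
    params: PopulationParams,
    target_deaths: float,
    p: float,
    ratio: ConversionRatio | None = None,
    mode: Mode = "mc-mean",
    c_max: float = 1.0,
    n: int = DEFAULT_N,
    seed: int = DEFAULT_SEED,
) -> float:
    """Capacity increase c achieving a target death toll at conversion p.

    Root finding on a bracketed, monotone objective; c is resolved to
    1e-6. Raises :class:`BracketError` (reporting the attainable range)
    when the target lies outside what c in [0, c_max] can deliver.
    """
    return _invert(params, target_deaths, p, ratio, "deaths", mode, c_max, n, seed)


def find_capacity_for_time(
    params: PopulationParams,
    target_days: float,
    p: float,
    ratio: ConversionRatio | None = None,
    mode: Mode = "mc-mean",
    c_max: float = 1.0,
    n: int = DEFAULT_N,
    seed: int = DEFAULT_SEED,
) -> float:
    """Capacity increase c achieving a target clearance time (days)."""
    return _invert(params, target_days, p, ratio, "time", mode, c_max, n, seed)


def extract_isocline(
    params: PopulationParams,
    level: float,
    outcome: Literal["time", "deaths"],
    p_axis=None,
    ratio: ConversionRatio | None = None,
    mode: Mode = "mc-mean",
    c_max: float = 1.0,
    n: int = DEFAULT_N,
    seed: int = DEFAULT_SEED,
) -> Isocline:
    """Trace the (p, c) contour along which the outcome equals ``level``.

    For each p on the axis the matching c is found by the inverse
    operations; p values where the level is unattainable are skipped. An
    empty contour raises :class:`LevelUnattainableError`.
    """
    if p_axis is None:
        p_axis = np.linspace(0.0, 0.5, 11)
    points: list[tuple[float, float]] = []
    for p in np.asarray(p_axis, dtype=float):
        try:
            c = _invert(params, level, float(p), ratio, outcome, mode,
                        c_max, n, seed)
        except BracketError:
            continue
        points.append((float(p), c))
    if not points:
        raise LevelUnattainableError(
            f"{outcome} level {level:g} attained nowhere on the p axis"
        )
    return Isocline(level=level, outcome=outcome, points=points)
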