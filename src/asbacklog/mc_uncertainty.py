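"""Monte-Carlo propagation of parameter uncertainty.

The backlog size W0 and the mortality hazard mu are uncertain; both are
modelled as independent normals whose standard deviations are recovered
from published 95% CIs (sd = half-width / 1.959964). Draws below a floor
(0 for W0, 1e-4/yr for mu — the closed form is undefined or non-clearing
for mu <= 0, and P(mu < 0) is only ~0.16% under the stated normal) are
rejection-resampled, i.e. the distributions are truncated normals.

For each strategy we draw n = 10 000 (W0, mu) pairs, push each through the
closed-form clearance time and deaths, and report the mean together with
the empirical 2.5/97.5 percentiles — a 95% *reference range* of the
outcome distribution, not a confidence interval of the mean. Because the
clearance time is convex in the parameters, its MC mean sits slightly
above the point estimate (Jensen gap).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import model_core, strategies
from .model_core import PopulationParams
from .strategies import Strategy

__all__ = [
    "ConfigurationError",
    "ParamDistribution",
    "MCSummary",
    "default_distributions",
    "draw_parameters",
    "mc_outcomes",
    "mc_summary",
    "DEFAULT_SEED",
    "DEFAULT_N",
]

#: normal 97.5% quantile used to unpack CI half-widths into sd.
Z_975 = 1.959964
#: mortality-hazard truncation floor, 1/year.
MU_FLOOR = 1e-4
DEFAULT_N = 10_000
DEFAULT_SEED = 20220616


class ConfigurationError(ValueError):
    """Distribution configuration under which rejection sampling stalls."""


@dataclass(frozen=True)
class ParamDistribution:
    """A truncated normal for one uncertain parameter.

    ``sd = 0`` is permitted as a degenerate (point-mass) configuration.
    """

    mean: float
    sd: float
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.floor > self.mean + 5.0 * self.sd:
            raise ConfigurationError(
                "floor lies above mean + 5*sd; rejection sampling would stall"
            )

    @classmethod
    def from_ci(
        cls, mean: float, ci: tuple[float, float], floor: float = 0.0
    ) -> "ParamDistribution":
        """Build from a 95% CI: sd = (upper - lower) / (2 * 1.959964)."""
        lo, hi = ci
        if hi <= lo:
            raise ValueError("CI upper bound must exceed lower bound")
        return cls(mean=mean, sd=(hi - lo) / (2.0 * Z_975), floor=floor)


@dataclass(frozen=True)
class MCSummary:
    """Monte-Carlo outcome summary: means and 95% reference ranges."""

    n: int
    seed: int
    Te_per_year: float
    tc_mean: float
    tc_p2_5: float
    tc_p97_5: float
    deaths_mean: float
    deaths_p2_5: float
    deaths_p97_5: float

    def to_dict(self) -> dict:
        return asdict(self)


def default_distributions(
    params: PopulationParams,
    w0_floor: float = 0.0,
    mu_floor: float = MU_FLOOR,
) -> tuple[ParamDistribution, ParamDistribution]:
    """The (W0, mu) distributions implied by the population parameters."""
    return (
        ParamDistribution.from_ci(params.W0_mean, params.W0_ci, floor=w0_floor),
        ParamDistribution.from_ci(params.mu_mean, params.mu_ci, floor=mu_floor),
    )


def _draw_truncated(
    dist: ParamDistribution, n: int, rng: np.random.Generator
) -> np.ndarray:
    if dist.sd == 0.0:
        if dist.mean < dist.floor:
            raise ConfigurationError("degenerate distribution below its floor")
        return np.full(n, dist.mean)
    draws = rng.normal(dist.mean, dist.sd, size=n)
    below = draws < dist.floor
    while below.any():
        draws[below] = rng.normal(dist.mean, dist.sd, size=int(below.sum()))
        below = draws < dist.floor
    return draws


def draw_parameters(
    w0_dist: ParamDistribution,
    mu_dist: ParamDistribution,
    n: int,
    seed: int | np.random.Generator = DEFAULT_SEED,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` i.i.d. independent (W0, mu) pairs, reproducibly.

    Sub-floor draws are rejection-resampled, so each marginal is a
    truncated normal. Passing the same integer seed yields identical
    draws; a Generator may be passed to share a stream.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    w0 = _draw_truncated(w0_dist, n, rng)
    mu = _draw_truncated(mu_dist, n, rng)
    return w0, mu


def mc_outcomes(
    Te: float, w0: np.ndarray, mu: np.ndarray, days_per_year: float = 365.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw clearance time (days) and deaths for a fixed surplus Te.

    Exposed separately so callers can reuse one draw set across many Te
    values (common random numbers), as the planner's root finding does.
    """
    tc_years = model_core.clearance_time(w0, mu, Te)
    deaths = model_core.deaths_at_clearance(w0, Te, tc_years)
    return tc_years * days_per_year, deaths


def mc_summary(
    params: PopulationParams,
    strategy: Strategy,
    n: int = DEFAULT_N,
    seed: int = DEFAULT_SEED,
    w0_floor: float = 0.0,
    mu_floor: float = MU_FLOOR,
) -> MCSummary:
    """Monte-Carlo summary of a strategy's clearance time and deaths.

    Percentiles use NumPy's default linear interpolation between order
    statistics, so ranges are bit-reproducible given the seed.
    """
    Te = strategies.total_surplus(params, strategy)
    if Te <= 0:
        raise model_core.CapacityError(
            "strategy yields no surplus capacity; MC outcomes undefined"
        )
    w0_dist, mu_dist = default_distributions(params, w0_floor, mu_floor)
    w0, mu = draw_parameters(w0_dist, mu_dist, n, seed)
    tc_days, deaths = mc_outcomes(Te, w0, mu, params.days_per_year)
    tc_lo, tc_hi = np.percentile(tc_days, [2.5, 97.5])
    d_lo, d_hi = np.percentile(deaths, [2.5, 97.5])
    return MCSummary(
        n=n,
        seed=seed if isinstance(seed, int) else -1,
        Te_per_year=Te,
        tc_mean=float(tc_days.mean()),
        tc_p2_5=float(tc_lo),
        tc_p97_5=float(tc_hi),
        deaths_mean=float(deaths.mean()),
        deaths_p2_5=float(d_lo),
        deaths_p97_5=float(d_hi),
    )
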