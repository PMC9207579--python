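"""Closed-form dynamics of an excess surgical waiting list.

The excess waiting list ``W(t)`` (patients left untreated relative to the
pre-pandemic steady state) shrinks only through two flows: deaths of
untreated patients, at instantaneous hazard ``mu`` per year, and treatment
through *surplus* capacity ``Te`` (procedures/year above the baseline
throughput, which is fully consumed by the steady-state inflow):

    dW/dt = -mu * W - Te,        W(0) = W0.

For ``Te > 0`` the list reaches zero at the clearance time

    tc = ln(1 + W0 * mu / Te) / mu                          (years)

and the cumulative deaths on the excess list up to clearance are

    m(tc) = W0 - Te * tc.

With ``Te = 0`` the list never clears and deaths grow as
``W0 * (1 - exp(-mu t))``.

All public functions are vectorised over their numeric arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CapacityError",
    "NonClearingError",
    "InconsistencyError",
    "PopulationParams",
    "ClearanceResult",
    "clearance_time",
    "deaths_at_clearance",
    "deaths_by_time",
    "waitlist_trajectory",
    "point_estimate",
]

#: below this |mu| the log form loses accuracy; switch to the series in mu.
_MU_SERIES_THRESHOLD = 1e-8


class CapacityError(ValueError):
    """Raised when Te <= 0: the backlog cannot clear by treatment."""


class NonClearingError(ValueError):
    """Raised when 1 + W0*mu/Te <= 0 (non-clearing parameter regime)."""


class InconsistencyError(ValueError):
    """Raised when deaths fall outside [0, W0] beyond numerical tolerance."""


@dataclass(frozen=True)
class PopulationParams:
    """Epidemiological constants of the backlog system.

    Defaults are the NHS England severe aortic-stenosis figures: an excess
    backlog of 4989 patients (95% CI 4020-5959) accumulated March-November
    2020, a 36%/year mortality hazard for untreated symptomatic severe AS
    (95% CI 12-60%), and 2018/19 baseline throughput of 7830 SAVR and
    5197 TAVI procedures per year.

    Parameters
    ----------
    W0_mean : float
        Excess backlog size, persons.
    W0_ci : tuple of float
        95% CI (lower, upper) for the backlog size, persons.
    mu_mean : float
        Annual mortality hazard of untreated patients, 1/year.
    mu_ci : tuple of float
        95% CI (lower, upper) for the hazard, 1/year.
    rS0, rT0 : float
        Baseline SAVR / TAVI throughput, procedures/year.
    inflow_f : float or None
        Steady-state arrival rate of new patients, patients/year. Recorded
        for completeness; it cancels out of the excess-list equations under
        the steady-state assumption and no published value exists.
    days_per_year : float
        Day-count convention used to report times in days.
    """

    W0_mean: float = 4989.0
    W0_ci: tuple[float, float] = (4020.0, 5959.0)
    mu_mean: float = 0.36
    mu_ci: tuple[float, float] = (0.12, 0.60)
    rS0: float = 7830.0
    rT0: float = 5197.0
    inflow_f: float | None = None
    days_per_year: float = 365.0

    def __post_init__(self) -> None:
        if not self.W0_mean > 0:
            raise ValueError("W0_mean must be positive")
        lo, hi = self.W0_ci
        if not lo < self.W0_mean < hi:
            raise ValueError("W0_ci must bracket W0_mean: lower < mean < upper")
        if not 0.0 < self.mu_mean < 1.0:
            raise ValueError("mu_mean must lie in (0, 1) per year")
        lo, hi = self.mu_ci
        if not lo < self.mu_mean < hi:
            raise ValueError("mu_ci must bracket mu_mean: lower < mean < upper")
        if self.rS0 <= 0 or self.rT0 <= 0:
            raise ValueError("baseline throughputs rS0, rT0 must be positive")
        if self.days_per_year != 365.0:
            raise ValueError("day-count convention is fixed at 365 days/year")

    @property
    def baseline_throughput(self) -> float:
        """Total pre-pandemic throughput rS0 + rT0, procedures/year."""
        return self.rS0 + self.rT0


@dataclass(frozen=True)
class ClearanceResult:
    """Point-estimate outcomes of one surplus-capacity configuration.

    Attributes
    ----------
    Te_per_year : float
        Surplus treatment capacity, procedures/year.
    tc_days : float
        Time to clear the excess backlog, days.
    deaths : float
        Patients dying on the excess list before treatment, persons.
    treated : float
        Patients treated from the excess backlog (= Te * tc), persons.
    """

    Te_per_year: float
    tc_days: float
    deaths: float
    treated: float


def clearance_time(W0, mu, Te):
    """Time (years) to clear a backlog of ``W0`` at surplus capacity ``Te``.

    Evaluates ``ln(1 + W0*mu/Te) / mu`` via ``log1p`` for numerical
    stability; for ``|mu|`` below 1e-8 the series continuation
    ``(W0/Te) * (1 - x/2 + x^2/3)`` with ``x = W0*mu/Te`` is used, so the
    function is continuous through ``mu -> 0`` where ``tc -> W0/Te``.

    Raises
    ------
    CapacityError
        If any ``Te <= 0`` (the backlog cannot clear by treatment).
    NonClearingError
        If ``1 + W0*mu/Te <= 0`` (non-clearing regime, only reachable for
        sufficiently negative ``mu``).
    """
    W0 = np.asarray(W0, dtype=float)
    mu = np.asarray(mu, dtype=float)
    Te = np.asarray(Te, dtype=float)
    if np.any(W0 < 0):
        raise ValueError("W0 must be nonnegative")
    if np.any(Te <= 0):
        raise CapacityError(
            "Te <= 0: backlog cannot clear by treatment "
            "(use deaths_by_time for the zero-capacity system)"
        )
    x = W0 * mu / Te
    if np.any(1.0 + x <= 0.0):
        raise NonClearingError("1 + W0*mu/Te <= 0: non-clearing regime")
    small = np.abs(mu) < _MU_SERIES_THRESHOLD
    mu_safe = np.where(small, 1.0, mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        tc = np.where(
            small,
            (W0 / Te) * (1.0 - 0.5 * x + x * x / 3.0),
            np.log1p(x) / mu_safe,
        )
    return tc if tc.ndim else float(tc)


def deaths_at_clearance(W0, Te, tc, rel_tol: float = 1e-6):
    """Deaths on the excess list before clearance: ``m = W0 - Te * tc``.

    ``tc`` must come from :func:`clearance_time` with consistent parameters;
    then ``m`` lies in ``[0, W0]``. Values outside that interval within
    ``rel_tol * max(1, W0)`` are clipped (floating-point slack); larger
    violations raise :class:`InconsistencyError` because they indicate
    inconsistent inputs, not round-off.
    """
    W0 = np.asarray(W0, dtype=float)
    Te = np.asarray(Te, dtype=float)
    tc = np.asarray(tc, dtype=float)
    m = W0 - Te * tc
    slack = rel_tol * np.maximum(1.0, W0)
    if np.any(m < -slack) or np.any(m > W0 + slack):
        raise InconsistencyError(
            "W0 - Te*tc outside [0, W0] beyond tolerance; "
            "tc is not the clearance time of these parameters"
        )
    m = np.clip(m, 0.0, W0)
    return m if m.ndim else float(m)


def deaths_by_time(W0, mu, t):
    """Cumulative deaths by time ``t`` (years) with zero surplus capacity.

    ``W0 * (1 - exp(-mu t))``; monotone increasing in ``t`` and ``mu``,
    approaching ``W0`` as ``t -> inf``.
    """
    W0 = np.asarray(W0, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    d = -W0 * np.expm1(-np.asarray(mu, dtype=float) * t)
    return d if d.ndim else float(d)


def waitlist_trajectory(W0: float, mu: float, Te: float, t_grid) -> pd.DataFrame:
    """Closed-form trajectory of the excess list on a time grid (years).

    Solves ``dW/dt = -mu W - Te``:

        W(t) = (W0 + Te/mu) * exp(-mu t) - Te/mu,

    truncated at 0 after the clearance time (the model is defined only up
    to clearance). ``Te = 0`` is allowed — the list then decays purely by
    mortality and never clears.

    Returns a DataFrame with columns ``time_years``, ``waiting``,
    ``cumulative_deaths``, ``cumulative_treated`` satisfying
    ``waiting + cumulative_deaths + cumulative_treated = W0`` at every t.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_grid must be nonnegative")
    if np.any(np.diff(t) < 0):
        raise ValueError("t_grid must be increasing")
    if Te < 0:
        raise ValueError("Te must be nonnegative")
    tc = clearance_time(W0, mu, Te) if Te > 0 else np.inf
    if abs(mu) < _MU_SERIES_THRESHOLD:
        waiting = W0 - Te * t
    else:
        waiting = (W0 + Te / mu) * np.exp(-mu * t) - Te / mu
    waiting = np.where(t >= tc, 0.0, np.maximum(waiting, 0.0))
    treated = Te * np.minimum(t, tc)
    deaths = np.maximum(W0 - waiting - treated, 0.0)
    return pd.DataFrame(
        {
            "time_years": t,
            "waiting": waiting,
            "cumulative_deaths": deaths,
            "cumulative_treated": treated,
        }
    )


def point_estimate(params: PopulationParams, Te: float) -> ClearanceResult:
    """Evaluate the closed forms at the central parameter values."""
    tc_years = clearance_time(params.W0_mean, params.mu_mean, Te)
    deaths = deaths_at_clearance(params.W0_mean, Te, tc_years)
    return ClearanceResult(
        Te_per_year=float(Te),
        tc_days=tc_years * params.days_per_year,
        deaths=deaths,
        treated=params.W0_mean - deaths,
    )
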