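"""Closed-form clearance time, deaths and trajectory."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

from asbacklog import model_core as mc
from asbacklog.model_core import (
    CapacityError,
    InconsistencyError,
    NonClearingError,
    PopulationParams,
    clearance_time,
    deaths_at_clearance,
    deaths_by_time,
    point_estimate,
    waitlist_trajectory,
)


@pytest.mark.parametrize(
    ("W0", "mu", "Te", "tc_days"),
    [
        (4989.0, 0.36, 13027.0, 130.9524697706413),   # doubled capacity
        (4989.0, 0.36, 2605.4, 531.6281228535147),    # +20% capacity
        (0.0, 0.36, 100.0, 0.0),                      # empty backlog
        (100.0, 1e-12, 365.0, 100.0),                 # mu -> 0 limit: W0/Te
    ],
)
def test_clearance_time_known_values(W0, mu, Te, tc_days):
    assert clearance_time(W0, mu, Te) * 365.0 == pytest.approx(tc_days, rel=1e-9)


def test_clearance_time_rejects_nonpositive_capacity():
    with pytest.raises(CapacityError):
        clearance_time(4989.0, 0.36, 0.0)
    with pytest.raises(CapacityError):
        clearance_time(4989.0, 0.36, -10.0)


def test_clearance_time_rejects_nonclearing_regime():
    # strongly negative hazard: list grows faster than treatment shrinks it
    with pytest.raises(NonClearingError):
        clearance_time(4989.0, -2.0, 100.0)


def test_clearance_time_is_vectorised():
    Te = np.array([2605.4, 13027.0])
    out = clearance_time(4989.0, 0.36, Te)
    assert out.shape == (2,)
    assert out[0] > out[1]


def test_series_branch_is_continuous_at_threshold():
    W0, Te = 4989.0, 2605.4
    below = clearance_time(W0, 0.999e-8, Te)
    above = clearance_time(W0, 1.001e-8, Te)
    assert below == pytest.approx(above, rel=1e-9)


@pytest.mark.parametrize(
    ("Te", "deaths"),
    [(13027.0, 315.2525378023447), (3915.0, 882.7542701101256)],
)
def test_deaths_at_clearance_known_values(Te, deaths):
    tc = clearance_time(4989.0, 0.36, Te)
    assert deaths_at_clearance(4989.0, Te, tc) == pytest.approx(deaths, rel=1e-9)


def test_deaths_at_clearance_mu_zero_limit():
    # tc = W0/Te exactly when nobody dies
    assert deaths_at_clearance(100.0, 365.0, 100.0 / 365.0) == pytest.approx(0.0, abs=1e-9)


def test_deaths_at_clearance_rejects_inconsistent_tc():
    with pytest.raises(InconsistencyError):
        deaths_at_clearance(4989.0, 13027.0, 10.0)  # tc far too large
    with pytest.raises(InconsistencyError):
        deaths_at_clearance(4989.0, 13027.0, -1.0)


def test_deaths_by_time_first_year_and_limits(params):
    d1 = deaths_by_time(params.W0_mean, params.mu_mean, 1.0)
    assert d1 == pytest.approx(1508.2928092316263, rel=1e-9)
    assert deaths_by_time(4989.0, 0.36, 0.0) == 0.0
    assert deaths_by_time(4989.0, 0.36, 1e6) == pytest.approx(4989.0)
    with pytest.raises(ValueError):
        deaths_by_time(4989.0, 0.36, -1.0)


def test_deaths_by_time_monotone_in_t_and_mu():
    t = np.linspace(0.0, 5.0, 50)
    d = deaths_by_time(4989.0, 0.36, t)
    assert np.all(np.diff(d) > 0)
    mus = np.linspace(0.05, 0.9, 20)
    d_mu = np.array([deaths_by_time(4989.0, m, 1.0) for m in mus])
    assert np.all(np.diff(d_mu) > 0)


class TestTrajectory:
    def test_initial_condition(self, params):
        traj = waitlist_trajectory(params.W0_mean, params.mu_mean, 2605.4, [0.0])
        row = traj.iloc[0]
        assert row.waiting == params.W0_mean
        assert row.cumulative_deaths == 0.0
        assert row.cumulative_treated == 0.0

    def test_zero_surplus_first_year(self, params):
        traj = waitlist_trajectory(params.W0_mean, params.mu_mean, 0.0, [1.0])
        assert traj.waiting.iloc[0] == pytest.approx(3480.707190768374, rel=1e-9)
        assert traj.cumulative_deaths.iloc[0] == pytest.approx(1508.29, abs=0.01)

    def test_consistency_with_closed_forms_at_tc(self, params):
        Te = 2605.4
        tc = clearance_time(params.W0_mean, params.mu_mean, Te)
        traj = waitlist_trajectory(params.W0_mean, params.mu_mean, Te, [tc, tc + 1.0])
        assert traj.waiting.iloc[0] == pytest.approx(0.0, abs=1e-6)
        expected = deaths_at_clearance(params.W0_mean, Te, tc)
        assert traj.cumulative_deaths.iloc[0] == pytest.approx(expected, rel=1e-9)
        # frozen after clearance
        assert traj.cumulative_deaths.iloc[1] == pytest.approx(expected, rel=1e-9)

    def test_conservation_on_grid(self, params):
        t = np.linspace(0.0, 3.0, 200)
        traj = waitlist_trajectory(params.W0_mean, params.mu_mean, 2605.4, t)
        total = traj.waiting + traj.cumulative_deaths + traj.cumulative_treated
        assert np.allclose(total, params.W0_mean, rtol=1e-9)
        assert (traj[["waiting", "cumulative_deaths", "cumulative_treated"]] >= 0).all().all()

    def test_rejects_bad_grid(self, params):
        with pytest.raises(ValueError):
            waitlist_trajectory(4989.0, 0.36, 100.0, [-1.0, 0.0])
        with pytest.raises(ValueError):
            waitlist_trajectory(4989.0, 0.36, 100.0, [1.0, 0.5])


@settings(max_examples=150, derandomize=True, deadline=None)
@given(
    W0=hs.floats(min_value=1.0, max_value=1e5),
    mu=hs.floats(min_value=1e-6, max_value=0.99),
    Te=hs.floats(min_value=1.0, max_value=1e6),
)
def test_conservation_property(W0, mu, Te):
    """Treated + died = initial backlog, for any valid parameters."""
    tc = clearance_time(W0, mu, Te)
    m = deaths_at_clearance(W0, Te, tc)
    assert Te * tc + m == pytest.approx(W0, rel=1e-9)


def test_outcomes_strictly_decreasing_in_capacity():
    Te_grid = np.linspace(500.0, 20000.0, 40)
    tc = clearance_time(4989.0, 0.36, Te_grid)
    m = deaths_at_clearance(np.full_like(Te_grid, 4989.0), Te_grid, tc)
    assert np.all(np.diff(tc) < 0)
    assert np.all(np.diff(m) < 0)


def test_outcome_monotonicity_in_mortality():
    mus = np.linspace(0.05, 0.9, 30)
    tc = np.array([clearance_time(4989.0, m, 2605.4) for m in mus])
    deaths = np.array([deaths_at_clearance(4989.0, 2605.4, t) for t in tc])
    assert np.all(np.diff(tc) < 0)       # more deaths shrink the list faster
    assert np.all(np.diff(deaths) > 0)


def test_diminishing_returns_in_capacity():
    """Deaths averted per extra unit of Te shrink as Te grows (convexity)."""
    Te_grid = np.linspace(500.0, 20000.0, 60)
    tc = clearance_time(4989.0, 0.36, Te_grid)
    m = deaths_at_clearance(np.full_like(Te_grid, 4989.0), Te_grid, tc)
    assert np.all(np.diff(m, n=2) > 0)


def test_small_mu_limit_agrees_with_W0_over_Te():
    W0, Te = 4989.0, 2605.4
    tc = clearance_time(W0, 1e-10, Te)
    assert abs(tc - W0 / Te) / (W0 / Te) < 1e-6


class TestPopulationParams:
    def test_defaults_are_published_values(self, params):
        assert params.W0_mean == 4989.0
        assert params.mu_mean == 0.36
        assert params.baseline_throughput == 13027.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"W0_mean": -1.0},
            {"W0_ci": (5000.0, 5959.0)},          # lower above mean
            {"mu_mean": 1.5},
            {"mu_ci": (0.40, 0.60)},              # does not bracket mean
            {"rS0": 0.0},
            {"days_per_year": 360.0},
        ],
    )
    def test_invariants_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PopulationParams(**kwargs)


def test_point_estimate_bundles_consistent_outputs(params):
    res = point_estimate(params, 2605.4)
    assert res.tc_days == pytest.approx(531.6281228535147, rel=1e-9)
    assert res.deaths + res.treated == pytest.approx(params.W0_mean, rel=1e-12)
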