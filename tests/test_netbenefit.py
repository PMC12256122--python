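"""Schedules, EFLY integrals, net benefit and the schedule optimizer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cvsched as cs
from cvsched.exceptions import InputError
from cvsched.netbenefit import (_argmax_interval, optimal_f_by_person,
                                schedule_components)
from cvsched.params import NbParams
from cvsched.survival import StepSurvival


def exp_step_survival(h, la=40.0, horizon=10.0, dt=1e-5):
    """Dense step-grid approximation of exponential survival (midpoint values)."""
    knots = la + np.arange(1, int(round(horizon / dt)) + 1) * dt
    return StepSurvival(origin=la, end=la + horizon, knots=knots,
                        values=np.exp(-h * (knots + dt / 2 - la)))


@st.composite
def random_step_survival(draw):
    n = draw(st.integers(min_value=1, max_value=8))
    gaps = draw(st.lists(st.floats(0.2, 2.0), min_size=n, max_size=n))
    knots = 40.0 + np.cumsum(gaps)
    knots = knots[knots < 50.0]
    if len(knots) == 0:
        knots = np.array([45.0])
    drops = draw(st.lists(st.floats(0.01, 0.5), min_size=len(knots),
                          max_size=len(knots)))
    vals = np.cumprod(1.0 - 0.9 * np.asarray(drops[:len(knots)]))
    return StepSurvival(origin=40.0, end=50.0, knots=knots, values=vals)


class TestSchedules:
    def test_yearly_schedule_has_eleven_visits(self):
        s = cs.make_schedule(1, 40.0)
        assert s.visit_times == tuple(range(40, 51))

    @pytest.mark.parametrize("f,expected", [
        (10, (40.0, 50.0)),
        (7, (40.0, 47.0)),     # 54 would overshoot the horizon
        (4, (40.0, 44.0, 48.0)),
    ])
    def test_visits_stay_within_horizon(self, f, expected):
        assert cs.make_schedule(f, 40.0).visit_times == expected

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(InputError):
            cs.make_schedule(0, 40.0)


class TestStatinVisit:
    def test_first_visit_at_or_after_crossing(self):
        s2, s3 = cs.make_schedule(2, 40.0), cs.make_schedule(3, 40.0)
        assert cs.statin_visit(s2, 43.5) == (3, 44.0)
        assert cs.statin_visit(s3, 43.5) == (3, 46.0)

    def test_crossing_at_landmark_hits_first_visit(self):
        assert cs.statin_visit(cs.make_schedule(2, 40.0), 40.0) == (1, 40.0)

    def test_no_visit_after_crossing_returns_absent(self):
        assert cs.statin_visit(cs.make_schedule(7, 40.0), 48.0) is None

    def test_never_crossing_returns_absent(self):
        assert cs.statin_visit(cs.make_schedule(2, 40.0), None) is None

    def test_crossing_before_landmark_rejected(self):
        with pytest.raises(InputError):
            cs.statin_visit(cs.make_schedule(2, 40.0), 39.0)


class TestExpectedVisits:
    def test_never_crossing_uses_continuous_formula(self):
        assert cs.expected_visits(cs.make_schedule(2, 40.0), None) == 6.0
        assert np.isclose(cs.expected_visits(cs.make_schedule(3, 40.0), None),
                          1 + 10 / 3)

    def test_crossers_count_visits_up_to_initiation(self):
        for f in (2, 3):
            sched = cs.make_schedule(f, 40.0)
            k, _ = cs.statin_visit(sched, 43.5)
            assert cs.expected_visits(sched, k) == 3.0


class TestEflyIntegrals:
    def test_certain_survival_and_degenerate_bounds(self):
        S = StepSurvival(origin=40.0, end=50.0, knots=np.array([]),
                         values=np.array([]))
        assert cs.efly_ns(S, 40.0, 44.0) == 4.0
        assert cs.efly_ns(S, 40.0, 40.0) == 0.0
        assert cs.efly_s(S, 0.8, 50.0, 40.0) == 0.0

    def test_constant_hazard_closed_forms(self):
        h, theta, tau, la = 0.08, 0.8, 44.0, 40.0
        S = exp_step_survival(h, la)
        d = tau - la
        assert abs(cs.efly_ns(S, la, tau) - (1 - np.exp(-h * d)) / h) < 1e-6
        expect = np.exp(-h * d) * (1 - np.exp(-theta * h * (10 - d))) / (theta * h)
        assert abs(cs.efly_s(S, theta, tau, la) - expect) < 1e-6

    def test_theta_one_reduces_to_untreated_survival(self):
        S = exp_step_survival(0.1, dt=1e-3)
        tau = 43.0
        assert np.isclose(cs.efly_s(S, 1.0, tau, 40.0),
                          S.integrate(tau, 50.0), rtol=1e-12)

    def test_dead_at_initiation_gives_zero(self):
        S = StepSurvival(origin=40.0, end=50.0, knots=np.array([42.0]),
                         values=np.array([0.0]))
        assert cs.efly_s(S, 0.8, 45.0, 40.0) == 0.0

    @given(random_step_survival(), st.floats(0.1, 1.0), st.floats(0.1, 1.0),
           st.floats(40.0, 50.0))
    @settings(max_examples=150, deadline=None)
    def test_theta_monotonicity_and_conservation(self, S, th1, th2, tau):
        """More effective statins (smaller theta) never shorten on-statin
        event-free time; total EFLY never exceeds the horizon."""
        lo, hi = sorted((th1, th2))
        assert cs.efly_s(S, lo, tau, 40.0) >= cs.efly_s(S, hi, tau, 40.0) - 1e-12
        total = cs.efly_ns(S, 40.0, tau) + cs.efly_s(S, lo, tau, 40.0)
        assert total <= 10.0 + 1e-9


class TestNetBenefitValue:
    def test_worked_arithmetic_with_defaults(self):
        qaly, cost, nb = cs.net_benefit_value(10.0, 0.0, 2.0, NbParams())
        assert np.isclose(nb, 10 * 25_000 - 18.39 * 2)
        assert np.isclose(nb, 249_963.22)

    def test_cost_free_limit(self):
        p = NbParams(statin_utility=1.0, statin_cost=0.0, visit_cost=0.0)
        _, _, nb = cs.net_benefit_value(3.0, 4.0, 5.0, p)
        assert np.isclose(nb, 25_000 * 7.0)

    def test_all_zero(self):
        assert cs.net_benefit_value(0.0, 0.0, 0.0, NbParams())[2] == 0.0


class _Profile:
    def __init__(self, pid, la, t_star, category):
        self.person_id, self.landmark_age = pid, la
        self.crossing_time, self.category = t_star, category


class TestOptimizer:
    def test_never_crossing_person_prefers_ten_year_interval(self):
        S = exp_step_survival(0.01, dt=1e-3)
        res = cs.optimize_schedule(_Profile(0, 40.0, None, "low"), S, NbParams())
        assert res.special_case == "never_crosses"
        assert res.optimal_f == 10.0
        # with positive visit cost, NB strictly decreases with visit count
        tab = res.per_interval.sort_values("e_visits")
        assert np.all(np.diff(tab["nb"].to_numpy()) < 0)

    def test_crossing_after_horizon_treated_as_never(self):
        S = exp_step_survival(0.01, dt=1e-3)
        res = cs.optimize_schedule(_Profile(0, 40.0, 50.0, "med_low"), S,
                                   NbParams())
        assert res.special_case == "never_crosses"

    def test_very_high_person_not_optimized(self):
        S = exp_step_survival(0.01, dt=1e-3)
        res = cs.optimize_schedule(_Profile(0, 40.0, 40.0, "very_high"), S,
                                   NbParams())
        assert res.special_case == "very_high_at_La"
        assert res.optimal_f is None and len(res.per_interval) == 0

    def test_tie_breaks_toward_larger_interval(self):
        per = pd.DataFrame({"f": [1.0, 5.0, 10.0], "nb": [1.0, 1.0, 1.0]})
        assert _argmax_interval(per) == 10.0


class TestSensitivity:
    @pytest.fixture()
    def components(self):
        rows = []
        rng = np.random.default_rng(8)
        for pid in range(30):
            h = rng.uniform(0.005, 0.05)
            S = exp_step_survival(h, dt=1e-3)
            t_star = None if pid % 3 == 0 else 40.0 + rng.uniform(1, 9)
            comp = schedule_components(S, t_star, 40.0, NbParams())
            comp.insert(0, "person_id", pid)
            rows.append(comp)
        return pd.concat(rows, ignore_index=True)

    def test_grid_shape_and_base_case(self, components):
        base = NbParams()
        tab = cs.sensitivity_grid(components, {"lambda_wtp": [25_000.0]}, base)
        assert len(tab) == 10
        opts = optimal_f_by_person(components, base)
        expect = opts.value_counts(normalize=True)
        for f in base.intervals:
            got = tab.loc[tab["f"] == float(f), "proportion"].iloc[0]
            assert np.isclose(got, expect.get(float(f), 0.0))

    def test_empty_grid_rejected(self, components):
        with pytest.raises(InputError):
            cs.sensitivity_grid(components, {}, NbParams())
        with pytest.raises(InputError):
            cs.sensitivity_grid(components, {"lambda_wtp": []}, NbParams())

    def test_hazard_ratio_grid_rejected(self, components):
        with pytest.raises(InputError):
            cs.sensitivity_grid(components, {"hazard_ratio": [0.7]}, NbParams())
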