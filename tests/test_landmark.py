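"""Landmark cohorts, Cox fitting, risk prediction and threshold crossing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cvsched as cs
from cvsched.exceptions import EstimationError, InputError
from cvsched.landmark import CoxFit, _breslow_baseline
from cvsched.params import INDICATORS


def _person_row(pid, entry=40.0, dco=80.0, cvd=np.nan, statin=np.nan, town=1):
    row = {"person_id": pid, "entry_age": entry, "exit_age": dco,
           "cvd_event": not np.isnan(cvd), "cvd_age": cvd,
           "death_or_censor_age": dco, "statin_start_age": statin,
           "townsend": town, "practice_id": 0, "sex": "all"}
    for ind in INDICATORS:
        row[f"{ind}_onset_age"] = np.nan
    return row


def _persons(*rows):
    return pd.DataFrame(list(rows))


class TestCohortSelection:
    def test_landmark_eligibility_rules(self):
        la = 60.0
        persons = _persons(
            _person_row(0),                               # eligible
            _person_row(1, cvd=la - 1),                   # prior CVD
            _person_row(2, statin=la + 2),                # statin after La: in
            _person_row(3, entry=la + 1),                 # not yet enrolled
            _person_row(4, statin=la - 3),                # statin before La
            _person_row(5, dco=la),                       # not alive beyond La
        )
        assert list(cs.select_landmark_cohort(persons, la)) == [0, 2]

    def test_sub_cohort_nesting_and_equality_at_origin(self):
        la = 60.0
        persons = _persons(
            _person_row(0),
            _person_row(1, cvd=la + 2.5),
            _person_row(2, dco=la + 4.0),
        )
        base = cs.select_landmark_cohort(persons, la)
        assert list(cs.select_sub_cohort(persons, la, la)) == list(base)
        assert list(cs.select_sub_cohort(persons, la, la + 3)) == [0, 2]
        assert list(cs.select_sub_cohort(persons, la, la + 5)) == [0]
        sizes = [len(cs.select_sub_cohort(persons, la, la + s)) for s in range(11)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_sub_cohort_monotone_on_simulated_cohort(self, small_cohort):
        persons, _ = small_cohort
        sizes = [len(cs.select_sub_cohort(persons, 60.0, 60.0 + s))
                 for s in range(11)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestCoxFit:
    def test_null_model_baseline_is_nelson_aalen(self, small_cohort):
        from lifelines import NelsonAalenFitter

        persons, _ = small_cohort
        la = 60.0
        ids = cs.select_landmark_cohort(persons, la)
        fit = cs.fit_landmark_cox(persons, pd.DataFrame(index=pd.Index(
            ids, name="person_id")), ids, la, 10.0)
        per = persons.set_index("person_id").loc[ids]
        ev = per["cvd_age"].fillna(np.inf)
        stop = np.minimum(np.minimum(ev, per["death_or_censor_age"]), la + 10)
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(stop - la, event_observed=(ev <= stop))
        na = naf.cumulative_hazard_.iloc[:, 0]
        mine = fit.cumhaz_at(na.index.to_numpy())
        assert np.allclose(mine, na.to_numpy(), atol=1e-10)

    def test_recovers_binary_covariate_log_hazard_ratio(self):
        rng = np.random.default_rng(31)
        n, h, beta = 5000, 0.05, 0.5
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (h * np.exp(beta * x)))
        origin, window = 50.0, 10.0
        persons = pd.DataFrame([_person_row(i) for i in range(n)])
        persons["cvd_age"] = np.where(t <= window, origin + t, np.nan)
        persons["cvd_event"] = t <= window
        covs = pd.DataFrame({"x": x},
                            index=pd.Index(np.arange(n), name="person_id"))
        fit = cs.fit_landmark_cox(persons, covs, np.arange(n), origin, window)
        assert abs(fit.coefficients["x"] - beta) < 3 * fit.coef_se["x"]
        # the null-covariate survival curve matches exponential survival
        S = cs.survival_curve_ns(fit, {"x": 0.0})
        expect = np.exp(-5 * h)
        assert abs(S(origin + 5.0) - expect) < 0.02  # ~3 MC standard errors

    def test_no_events_in_window_raises(self):
        persons = _persons(_person_row(0, cvd=75.0), _person_row(1))
        covs = pd.DataFrame(index=pd.Index([0, 1], name="person_id"))
        with pytest.raises(EstimationError):
            cs.fit_landmark_cox(persons, covs, [0, 1], 60.0, 5.0)

    def test_constant_covariates_are_dropped(self, small_cohort):
        persons, _ = small_cohort
        la = 60.0
        ids = cs.select_landmark_cohort(persons, la)
        covs = pd.DataFrame({"const_col": 1.0},
                            index=pd.Index(ids, name="person_id"))
        fit = cs.fit_landmark_cox(persons, covs, ids, la, 10.0)
        assert "const_col" in fit.dropped
        assert len(fit.coefficients) == 0


class TestRiskPrediction:
    @pytest.fixture()
    def toy_fit(self):
        return CoxFit(origin=60.0, window=5.0,
                      coefficients=pd.Series({"a": 0.4, "b": -0.2}),
                      coef_se=pd.Series({"a": 0.1, "b": 0.1}),
                      baseline_times=np.array([1.0, 2.5, 4.0]),
                      baseline_cumhaz=np.array([0.01, 0.03, 0.06]),
                      n_fit=100, n_events=3)

    def test_reference_covariates_use_baseline_only(self, toy_fit):
        r = cs.predict_risk(toy_fit, {"a": 0.0, "b": 0.0})
        assert np.isclose(r, 1 - np.exp(-0.06))

    def test_zero_cumulative_hazard_gives_zero_risk(self, toy_fit):
        toy_fit.baseline_cumhaz = np.zeros(3)
        assert cs.predict_risk(toy_fit, {"a": 1.0, "b": 2.0}) == 0.0

    def test_linear_predictor_scaling_closed_form(self, toy_fit):
        x = {"a": 1.0, "b": 0.5}
        eta = 0.4 * 1.0 - 0.2 * 0.5
        r1 = cs.predict_risk(toy_fit, x)
        assert np.isclose(r1, 1 - np.exp(-0.06 * np.exp(eta)))
        x2 = {k: 2 * v for k, v in x.items()}
        assert np.isclose(cs.predict_risk(toy_fit, x2),
                          1 - np.exp(-0.06 * np.exp(2 * eta)))

    def test_missing_covariate_rejected(self, toy_fit):
        with pytest.raises(InputError):
            cs.predict_risk(toy_fit, {"a": 1.0})

    def test_survival_curve_starts_at_one_and_decreases(self, toy_fit):
        toy_fit.window = 5.0
        S = cs.survival_curve_ns(toy_fit, {"a": 0.3, "b": 0.1})
        assert S(60.0) == 1.0
        grid = np.linspace(60.0, 65.0, 50)
        vals = S(grid)
        assert np.all(np.diff(vals) <= 1e-15)

    def test_risk_bounded_for_extreme_inputs(self, toy_fit):
        assert 0.0 <= cs.predict_risk(toy_fit, {"a": 50.0, "b": -50.0}) <= 1.0
        assert 0.0 <= cs.predict_risk(toy_fit, {"a": -50.0, "b": 50.0}) <= 1.0


class TestCrossingTime:
    AGES = np.arange(40.0, 51.0)

    def test_linear_interpolation_between_grid_years(self):
        risks = np.full(11, 0.01)
        risks[2], risks[3] = 0.04, 0.06
        t, very_high = cs.crossing_time(self.AGES, risks, 0.05)
        assert np.isclose(t, 42.5)
        assert not very_high

    def test_never_exceeding_returns_absent(self):
        t, very_high = cs.crossing_time(self.AGES, np.full(11, 0.05), 0.05)
        assert t is None and not very_high  # exactly 5% does not exceed

    def test_exceedance_at_landmark_flags_very_high(self):
        risks = np.full(11, 0.07)
        t, very_high = cs.crossing_time(self.AGES, risks, 0.05)
        assert t == 40.0 and very_high

    def test_only_first_exceedance_counts(self):
        risks = np.array([0.01, 0.04, 0.06, 0.02, 0.08] + [0.01] * 6)
        t, _ = cs.crossing_time(self.AGES, risks, 0.05)
        assert np.isclose(t, 41.5)

    def test_truncated_profile_scans_available_prefix(self):
        risks = np.array([0.01, 0.02, np.nan, np.nan] + [np.nan] * 7)
        t, very_high = cs.crossing_time(self.AGES, risks, 0.05)
        assert t is None and not very_high

    def test_non_finite_risk_rejected(self):
        risks = np.full(11, 0.01)
        risks[4] = np.inf
        with pytest.raises(InputError):
            cs.crossing_time(self.AGES, risks, 0.05)

    @given(st.lists(st.floats(min_value=0.0, max_value=0.2), min_size=2,
                    max_size=11))
    @settings(max_examples=200, deadline=None)
    def test_crossing_time_properties(self, risks):
        risks = np.asarray(risks)
        ages = 40.0 + np.arange(len(risks), dtype=float)
        t, very_high = cs.crossing_time(ages, risks, 0.05)
        if t is None:
            assert not np.any(risks > 0.05)
        else:
            assert ages[0] <= t <= ages[-1]
            if not very_high:
                # the linearly interpolated risk at t equals the threshold
                j = int(np.floor(t - ages[0])) + 1
                j = min(j, len(risks) - 1)
                r0, r1 = risks[j - 1], risks[j]
                interp = r0 + (t - ages[j - 1]) * (r1 - r0)
                assert np.isclose(interp, 0.05, atol=1e-12)


class TestClassifyRisk:
    @pytest.mark.parametrize("risk,expected", [
        (0.06, "very_high"),
        (0.05, "high"),          # boundary: exactly 5% is not very high
        (0.04, "high"),
        (0.0375, "med_high"),
        (0.03, "med_high"),
        (0.025, "med_low"),
        (0.02, "med_low"),
        (0.0125, "low"),
        (0.001, "low"),
        (0.0, "low"),
    ])
    def test_category_boundaries(self, risk, expected):
        assert cs.classify_risk(risk) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            cs.classify_risk(1.5)
        with pytest.raises(InputError):
            cs.classify_risk(float("nan"))


def test_breslow_reduces_to_nelson_aalen_with_zero_coefficients():
    durations = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
    events = np.array([1, 1, 0, 1, 0, 0], dtype=bool)
    times, ch = _breslow_baseline(durations, events, np.zeros(6))
    # hand-computed Nelson-Aalen: 1/6 at t=1, +1/5 at t=2, +1/3 at t=3
    assert np.allclose(times, [1.0, 2.0, 3.0])
    assert np.allclose(ch, [1 / 6, 1 / 6 + 1 / 5, 1 / 6 + 1 / 5 + 1 / 3])
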