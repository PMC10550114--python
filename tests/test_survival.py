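"""Kaplan–Meier, log-rank and IP-weighted discrete-time hazard curves."""

import numpy as np
import pytest
import statsmodels.api as sm

from vettrial.propensity import default_spec, fit_propensity
from vettrial.simulate import default_study_config, generate_cohort
from vettrial.survival import (
    TIMEPOINT_DAYS,
    ipw_survival,
    km_curve,
    logrank,
    person_day_expand,
)

from conftest import build_cohort, unit_weightset


@pytest.fixture(scope="module")
def sim_cohort():
    cohort, _ = generate_cohort(default_study_config(n=800, seed=21))
    return cohort


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        # times 1,2,2*,3 (*=censored): S(1)=3/4, S(2)=3/4 * 2/3 = 1/2, S(3)=0
        est = km_curve([1, 2, 2, 3], [1, 1, 0, 1], [0, 0, 0, 0], horizon=5)
        s = est.survival[0]
        assert s[0] == 1.0
        assert s[1] == pytest.approx(0.75)
        assert s[2] == pytest.approx(0.5)
        assert s[3] == pytest.approx(0.0)

    def test_no_events_curve_is_flat_one(self):
        est = km_curve([30, 30, 30], [0, 0, 0], [0, 0, 0])
        np.testing.assert_allclose(est.survival[0], 1.0)

    def test_day_zero_event_counts_on_day_one(self):
        est = km_curve([0, 30], [1, 0], [0, 0])
        assert est.survival[0][1] == pytest.approx(0.5)

    def test_times_outside_horizon_rejected(self):
        with pytest.raises(ValueError):
            km_curve([1, 45], [1, 0], [0, 0])

    def test_at_risk_counts(self):
        est = km_curve([1, 2, 3], [1, 1, 1], [0, 0, 0], horizon=3)
        np.testing.assert_allclose(est.n_at_risk[0], [3, 3, 2, 1])


class TestLogrank:
    def test_hand_computed_statistic(self):
        # A:(1,event),(2,event)  B:(1,censored),(2,event)
        # day1: O-E = 1 - 0.5, var 0.25; day2: O-E = 1 - 1, var 0
        # chi-square = 0.5^2 / 0.25 = 1, p = 0.3173
        stat, p = logrank([1, 2, 1, 2], [1, 1, 0, 1], ["A", "A", "B", "B"])
        assert stat == pytest.approx(1.0, abs=1e-8)
        assert p == pytest.approx(0.31731, abs=1e-4)

    def test_group_label_symmetry(self):
        t = [1, 3, 5, 2, 4, 30]
        e = [1, 1, 0, 1, 0, 0]
        g = [1, 1, 1, 0, 0, 0]
        s1, p1 = logrank(t, e, g)
        s2, p2 = logrank(t, e, [1 - x for x in g])
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_identical_groups_give_no_signal(self):
        t = [1, 2, 3, 30, 1, 2, 3, 30]
        e = [1, 1, 1, 0, 1, 1, 1, 0]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        stat, p = logrank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-8)

    def test_requires_two_groups(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank([1, 2], [1, 1], [0, 0])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            logrank([30, 30], [0, 0], [0, 1])


class TestPersonDayExpansion:
    def test_rows_and_event_conservation(self):
        rows = [
            {"escalation_day": 3, "escalated": 1, "antimicrobial": 1},
            {"escalation_day": 30, "escalated": 0, "antimicrobial": 0},
            {"escalation_day": 0, "escalated": 1, "antimicrobial": 0},
        ]
        cohort = build_cohort(rows)
        pdf = person_day_expand(cohort, "antimicrobial")
        # 3 + 30 + 1 (day-0 event moved to day 1) person-days
        assert len(pdf) == 34
        assert pdf["event"].sum() == 2
        d0 = pdf[pdf.dog_id == cohort.dog_id.iloc[2]]
        assert list(d0["day"]) == [1] and int(d0["event"].iloc[0]) == 1

    def test_event_on_final_day_only(self, sim_cohort):
        pdf = person_day_expand(sim_cohort, "antimicrobial")
        assert pdf["event"].sum() == sim_cohort["escalated"].sum()
        last = pdf.groupby("dog_id")["day"].transform("max")
        assert (pdf.loc[pdf["day"] < last, "event"] == 0).all()

    def test_weights_carried_through(self, sim_cohort):
        ws = fit_propensity(sim_cohort, default_spec("antimicrobial"))
        pdf = person_day_expand(sim_cohort, "antimicrobial", ws.sw)
        per_dog = pdf.groupby("dog_id")["sw"].nunique()
        assert (per_dog == 1).all()


class TestIpwSurvival:
    def test_unit_weight_saturated_model_equals_km(self, sim_cohort):
        ws = unit_weightset(sim_cohort, "antimicrobial")
        est, _ = ipw_survival(sim_cohort, "antimicrobial", ws,
                              time_model="per-day-indicators", n_boot=0)
        km = km_curve(sim_cohort["escalation_day"], sim_cohort["escalated"],
                      sim_cohort["antimicrobial"])
        for arm in (0, 1):
            np.testing.assert_allclose(est.survival[arm], km.survival[arm],
                                       atol=1e-6)

    def test_smooth_model_matches_person_day_logit(self, sim_cohort):
        # the grouped-binomial fit must equal the Bernoulli person-day MLE
        ws = unit_weightset(sim_cohort, "antimicrobial")
        est, _ = ipw_survival(sim_cohort, "antimicrobial", ws,
                              time_model="linear+quadratic", n_boot=0)
        pdf = person_day_expand(sim_cohort, "antimicrobial")
        d = pdf["day"].to_numpy(dtype=float)
        a = pdf["exposure"].to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(d), d, d ** 2, a, a * d, a * d ** 2])
        res = sm.GLM(pdf["event"].to_numpy(), X,
                     family=sm.families.Binomial()).fit()
        days = np.arange(1, 31, dtype=float)
        for arm in (0, 1):
            Xa = np.column_stack([np.ones_like(days), days, days ** 2,
                                  np.full_like(days, arm), arm * days,
                                  arm * days ** 2])
            h = 1 / (1 + np.exp(-(Xa @ res.params)))
            s = np.concatenate([[1.0], np.cumprod(1 - h)])
            np.testing.assert_allclose(est.survival[arm], s, atol=1e-6)

    @pytest.mark.parametrize("tm", ["linear+quadratic", "per-day-indicators"])
    def test_curves_start_at_one_and_decrease(self, sim_cohort, tm):
        ws = fit_propensity(sim_cohort, default_spec("antimicrobial"))
        est, _ = ipw_survival(sim_cohort, "antimicrobial", ws,
                              time_model=tm, n_boot=0)
        for arm in (0, 1):
            s = est.survival[arm]
            assert s[0] == 1.0
            assert (np.diff(s) <= 1e-12).all()
            assert (s >= 0).all()

    def test_invalid_time_model_rejected(self, sim_cohort):
        ws = unit_weightset(sim_cohort, "antimicrobial")
        with pytest.raises(ValueError, match="time_model"):
            ipw_survival(sim_cohort, "antimicrobial", ws,
                         time_model="cubic-spline", n_boot=0)

    def test_timepoint_table_layout(self, sim_cohort):
        ws = fit_propensity(sim_cohort, default_spec("antimicrobial"))
        _, table = ipw_survival(sim_cohort, "antimicrobial", ws, n_boot=0)
        assert list(table["day"]) == list(TIMEPOINT_DAYS)
        np.testing.assert_allclose(
            table["difference_pct"],
            (table["survival_treated_pct"] - table["survival_untreated_pct"]).round(2),
            atol=0.011)
        assert table["ci_low_pct"].isna().all()

    def test_bootstrap_deterministic_and_brackets_estimate(self):
        cohort, _ = generate_cohort(default_study_config(n=300, seed=9))
        ws = fit_propensity(cohort, default_spec("antimicrobial"))
        est1, t1 = ipw_survival(cohort, "antimicrobial", ws, n_boot=25, seed=5)
        est2, t2 = ipw_survival(cohort, "antimicrobial", ws, n_boot=25, seed=5)
        for arm in (0, 1):
            np.testing.assert_array_equal(est1.ci_low[arm], est2.ci_low[arm])
            np.testing.assert_array_equal(est1.ci_high[arm], est2.ci_high[arm])
        assert t1.equals(t2)

    def test_null_difference_interval_covers_zero(self):
        # exposure has no causal effect on escalation in the generator
        cohort, _ = generate_cohort(default_study_config(n=2000, seed=71))
        ws = fit_propensity(cohort, default_spec("antimicrobial"))
        _, table = ipw_survival(cohort, "antimicrobial", ws,
                                n_boot=200, seed=13)
        covered = ((table["ci_low_pct"] <= 0) & (table["ci_high_pct"] >= 0))
        assert covered.sum() >= 6  # allow at most one of 7 timepoints to miss
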