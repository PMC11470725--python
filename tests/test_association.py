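"""Logistic fits against closed-form oracles; Nagelkerke formula; complete-case builds."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fallstrat.association import (
    AssociationSpec,
    DegenerateDesignError,
    InsufficientDataError,
    SeparationError,
    build_design,
    fit_logistic,
    nagelkerke_r2,
    odds_ratio,
    run_association,
)
from fallstrat.cohort_model import FallsCount, TriState
from fallstrat.synthetic import SyntheticConfig, generate_cohort
from conftest import make_record


def _design_from_table(a, b, c, d):
    """2x2 table (exposed-event a, exposed-nonevent b, unexposed-event c, unexposed d)."""
    y = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
    x = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
    return y, pd.DataFrame({"const": np.ones_like(x), "x": x})


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        """MLE intercept is log(k/(n-k)); e.g. 30 successes of 100 -> log(30/70)."""
        y = np.array([1.0] * 30 + [0.0] * 70)
        X = pd.DataFrame({"const": np.ones(100)})
        res = fit_logistic(y, X)
        assert res.coef[0] == pytest.approx(math.log(30 / 70), abs=1e-8)
        assert res.ll1 == pytest.approx(res.ll0, abs=1e-8)

    def test_univariable_or_equals_cross_product_ratio(self):
        y, X = _design_from_table(20, 30, 10, 40)
        res = fit_logistic(y, X)
        assert res.odds_ratio[1] == pytest.approx((20 * 40) / (30 * 10), abs=1e-6)

    @given(st.tuples(*[st.integers(min_value=2, max_value=40)] * 4))
    def test_cross_product_property_on_random_tables(self, table):
        a, b, c, d = table
        y, X = _design_from_table(a, b, c, d)
        res = fit_logistic(y, X)
        assert res.odds_ratio[1] == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_fitted_probabilities_sum_to_successes(self):
        """Score equation at the MLE for the intercept column."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        X = pd.DataFrame({"const": np.ones(300), "x": x})
        res = fit_logistic(y, X)
        fitted = 1 / (1 + np.exp(-(res.coef[0] + res.coef[1] * x)))
        assert fitted.sum() == pytest.approx(y.sum(), abs=1e-6)

    def test_constant_column_is_degenerate(self):
        y = np.array([1.0, 0.0] * 10)
        X = pd.DataFrame({"const": np.ones(20), "x": np.zeros(20)})
        with pytest.raises(DegenerateDesignError):
            fit_logistic(y, X)

    def test_perfect_separation_raises_not_silent(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        x = np.array([0.0] * 10 + [1.0] * 10)
        with pytest.raises(SeparationError):
            fit_logistic(y, pd.DataFrame({"const": np.ones(20), "x": x}))

    def test_wald_z_and_p_are_consistent(self):
        y, X = _design_from_table(25, 25, 15, 35)
        res = fit_logistic(y, X)
        from scipy import stats
        for z, p in zip(res.z, res.p):
            assert p == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)


class TestNagelkerke:
    def test_null_model_is_zero(self):
        assert nagelkerke_r2(-6.73, -6.73, 10) == pytest.approx(0.0)

    def test_saturated_fit_is_one(self):
        assert nagelkerke_r2(-6.73, 0.0, 10) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # direct evaluation: (1-exp(2/10*(-1.73)))/(1-exp(2/10*(-6.73)))
        expected = (1 - math.exp(0.2 * (-6.73 + 5.00))) / (1 - math.exp(0.2 * (-6.73)))
        assert nagelkerke_r2(-6.73, -5.00, 10) == pytest.approx(expected, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(-5.0, -6.0, 10)  # fitted worse than null
        with pytest.raises(ValueError):
            nagelkerke_r2(-5.0, -4.0, 0)

    @given(st.floats(min_value=-200.0, max_value=-1.0),
           st.floats(min_value=0.0, max_value=100.0))
    def test_always_in_unit_interval(self, ll0, gain):
        r2 = nagelkerke_r2(ll0, min(ll0 + gain, 0.0), 50)
        assert 0.0 <= r2 <= 1.0


class TestOddsRatio:
    @pytest.mark.parametrize("b,expected", [(0.68, 1.97), (0.0, 1.0), (1.1, 3.00)])
    def test_printed_coefficients(self, b, expected):
        assert round(odds_ratio(b), 2) == pytest.approx(expected)

    def test_infinite_coefficient_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio(float("inf"))


class TestRunAssociation:
    def test_parameter_recovery_hearing_only(self):
        """Generator with only the hearing effect: adjusted fit recovers b=0.68."""
        cfg = SyntheticConfig(
            n=20000, effects={"hearing": 0.68, "dizziness": 0.0,
                              "vision": 0.0, "balance": 0.0},
            missingness={})
        records = generate_cohort(cfg, seed=42)
        res = run_association(records, AssociationSpec("hearing", "fall_past_year"))
        b = res.term("hearing")["b"]
        assert b == pytest.approx(0.68, abs=0.1)
        assert res.term("hearing")["or"] == pytest.approx(1.97, abs=0.2)

    def test_complete_case_build_drops_and_counts(self):
        records = [
            make_record(patient_id="a", fall_past_year=TriState.YES,
                        falls_count_category=FallsCount.ONE,
                        hearing_impaired=TriState.YES),
            make_record(patient_id="b", hearing_impaired=TriState.NO),
            make_record(patient_id="c", hearing_impaired=TriState.MISSING),  # dropped
            make_record(patient_id="d", cfs=None, hearing_impaired=TriState.NO),  # dropped
        ]
        df = build_design(records, AssociationSpec("hearing", "fall_past_year"))
        assert len(df) == 2

    def test_risk_outcome_excludes_intermediate_and_unclassifiable(self, fixture_cohort):
        df = build_design(fixture_cohort,
                          AssociationSpec("hearing", "high_vs_low_risk"))
        # only high (1) and low (0) rows survive
        assert set(df["outcome"].unique()) <= {0.0, 1.0}
        assert len(df) <= 170 + 149

    def test_insufficient_data_error(self):
        records = [make_record(patient_id=f"p{i}", hearing_impaired=TriState.YES)
                   for i in range(5)]
        with pytest.raises(InsufficientDataError):
            run_association(records, AssociationSpec("hearing", "fall_past_year"))

    def test_constant_predictor_reports_degenerate_design(self):
        cfg = SyntheticConfig(n=200, prevalence={"vision": 0.5, "hearing": 0.0,
                                                 "dizziness": 0.2, "balance": 0.5},
                              missingness={})
        records = generate_cohort(cfg, seed=7)
        with pytest.raises(DegenerateDesignError):
            run_association(records, AssociationSpec("hearing", "fall_past_year"))

    def test_null_age_interaction_not_preferred(self):
        """Generator has no sensory-by-age interaction; LR test should not reject."""
        cfg = SyntheticConfig(n=4000, missingness={})
        records = generate_cohort(cfg, seed=99)
        res = run_association(records,
                              AssociationSpec("hearing", "fall_past_year",
                                              interaction_with_age=True))
        assert "hearing:age" in res.terms
        assert res.lr_p_interaction > 0.05
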