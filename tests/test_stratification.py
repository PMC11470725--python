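"""Stratification engine vs an independent completion-enumeration oracle."""
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fallstrat.cohort_model import EmptyCohortError, FallsCount, TriState
from fallstrat.stratification import (
    FULL_GUIDELINE,
    PAPER_ADAPTED,
    InconsistentRecordError,
    RiskClass,
    RiskPath,
    StratificationMode,
    classify,
    classify_completions,
    stratify_cohort,
)
from _oracle import oracle_classes, oracle_classify
from conftest import make_record


def _records(allow_missing=True, severity=False):
    """Hypothesis strategy over deciding-field combinations, consistent by construction."""
    tri = st.sampled_from([TriState.YES, TriState.NO] +
                          ([TriState.MISSING] if allow_missing else []))
    cfs = st.sampled_from(list(range(1, 10)) + ([None] if allow_missing else []))

    @st.composite
    def build(draw):
        fall = draw(tri)
        if fall is TriState.NO:
            count = draw(st.sampled_from(
                [FallsCount.ZERO] + ([FallsCount.MISSING] if allow_missing else [])))
        elif fall is TriState.YES:
            count = draw(st.sampled_from(
                [FallsCount.ONE, FallsCount.TWO_PLUS]
                + ([FallsCount.MISSING] if allow_missing else [])))
        else:
            count = draw(st.sampled_from(list(FallsCount)))
        kwargs = dict(fall_past_year=fall, falls_count_category=count,
                      cfs=draw(cfs), balance_issue=draw(tri))
        if severity:
            kwargs.update(severity_lying_on_floor=draw(tri),
                          severity_loss_of_consciousness=draw(tri),
                          severity_injury=draw(tri))
        return make_record(**kwargs)

    return build()


class TestClassifyExamples:
    def test_no_fall_is_low_risk(self):
        a = classify(make_record(fall_past_year=TriState.NO))
        assert (a.risk, a.path) == (RiskClass.LOW, RiskPath.LOW_NO_FALLS)

    def test_two_plus_falls_high_even_with_everything_else_missing(self):
        a = classify(make_record(fall_past_year=TriState.YES,
                                 falls_count_category=FallsCount.TWO_PLUS,
                                 cfs=None, balance_issue=TriState.MISSING))
        assert (a.risk, a.path) == (RiskClass.HIGH, RiskPath.HIGH_FALLS)

    def test_missing_count_with_high_frailty_still_high(self):
        """Both completions (one fall + frail; two-plus falls) are high."""
        rec = make_record(fall_past_year=TriState.YES,
                          falls_count_category=FallsCount.MISSING, cfs=7)
        assert classify_completions(rec) == {RiskClass.HIGH}
        a = classify(rec)
        assert a.risk is RiskClass.HIGH
        assert a.path is RiskPath.HIGH_FRAILTY  # the observed condition

    def test_one_fall_missing_frailty_is_unclassifiable(self):
        rec = make_record(fall_past_year=TriState.YES,
                          falls_count_category=FallsCount.ONE,
                          cfs=None, balance_issue=TriState.NO)
        assert classify_completions(rec) == {RiskClass.HIGH, RiskClass.LOW}
        assert classify(rec).risk is RiskClass.UNCLASSIFIABLE
        assert classify(rec).path is RiskPath.NA

    def test_missing_fall_history_unclassifiable(self):
        rec = make_record(fall_past_year=TriState.MISSING,
                          falls_count_category=FallsCount.MISSING)
        assert classify(rec).risk is RiskClass.UNCLASSIFIABLE

    def test_observed_count_pins_missing_fall_history(self):
        """count=zero forces no-fall -> low; count=2plus forces fall -> high."""
        low = make_record(fall_past_year=TriState.MISSING,
                          falls_count_category=FallsCount.ZERO)
        high = make_record(fall_past_year=TriState.MISSING,
                           falls_count_category=FallsCount.TWO_PLUS)
        assert classify(low).risk is RiskClass.LOW
        assert classify(high).risk is RiskClass.HIGH

    def test_one_fall_missing_frailty_and_balance_spans_three_classes(self):
        rec = make_record(fall_past_year=TriState.YES,
                          falls_count_category=FallsCount.ONE,
                          cfs=None, balance_issue=TriState.MISSING)
        assert classify_completions(rec) == {
            RiskClass.HIGH, RiskClass.INTERMEDIATE, RiskClass.LOW}

    def test_inconsistent_record_raises(self):
        with pytest.raises(InconsistentRecordError):
            classify(make_record(fall_past_year=TriState.YES,
                                 falls_count_category=FallsCount.ZERO))

    def test_severity_flag_forces_high_in_full_guideline_only(self):
        rec = make_record(fall_past_year=TriState.YES,
                          falls_count_category=FallsCount.ONE, cfs=2,
                          balance_issue=TriState.NO,
                          severity_injury=TriState.YES)
        assert classify(rec, PAPER_ADAPTED).risk is RiskClass.LOW
        full = classify(rec, FULL_GUIDELINE)
        assert (full.risk, full.path) == (RiskClass.HIGH, RiskPath.HIGH_SEVERITY)

    def test_uncollected_severity_defaults_make_full_guideline_unclassifiable(self):
        """Default-missing severity flags are enumerated in full-guideline mode."""
        rec = make_record(fall_past_year=TriState.YES,
                          falls_count_category=FallsCount.ONE, cfs=2,
                          balance_issue=TriState.NO)
        assert classify(rec, FULL_GUIDELINE).risk is RiskClass.UNCLASSIFIABLE


class TestOracleEquivalence:
    @given(_records())
    def test_classify_matches_enumeration_oracle(self, rec):
        assert classify_completions(rec, PAPER_ADAPTED) == oracle_classes(rec, PAPER_ADAPTED)
        assert classify(rec, PAPER_ADAPTED).risk is oracle_classify(rec, PAPER_ADAPTED)

    @given(_records(severity=True))
    def test_full_guideline_matches_oracle(self, rec):
        assert classify_completions(rec, FULL_GUIDELINE) == oracle_classes(rec, FULL_GUIDELINE)
        assert classify(rec, FULL_GUIDELINE).risk is oracle_classify(rec, FULL_GUIDELINE)

    @given(_records(allow_missing=False))
    def test_complete_records_never_unclassifiable(self, rec):
        a = classify(rec)
        assert a.risk is not RiskClass.UNCLASSIFIABLE
        assert len(classify_completions(rec)) == 1

    @given(_records())
    def test_monotone_severity_in_falls_count(self, rec):
        """Raising one fall to two-plus never lowers a classifiable record's risk."""
        if rec.falls_count_category is not FallsCount.ONE:
            return
        import dataclasses
        worse = dataclasses.replace(rec, falls_count_category=FallsCount.TWO_PLUS)
        order = {RiskClass.LOW: 0, RiskClass.INTERMEDIATE: 1, RiskClass.HIGH: 2}
        before, after = classify(rec).risk, classify(worse).risk
        if before in order and after in order:
            assert order[after] >= order[before]


class TestStratifyCohort:
    def test_fixture_reproduces_printed_distribution(self, fixture_cohort):
        res = stratify_cohort(fixture_cohort)
        assert res.class_counts == {"high": 170, "low": 149,
                                    "intermediate": 19, "unclassifiable": 54}
        assert res.path_counts == {"low_no_falls": 139, "low_frailty": 10,
                                   "high_falls": 104, "high_frailty": 66,
                                   "intermediate": 19, "na": 54}

    def test_partition_and_order_invariance(self, fixture_cohort):
        res = stratify_cohort(fixture_cohort)
        assert sum(res.class_counts.values()) == res.n_total == 392
        assert sum(res.path_counts.values()) == res.n_total
        assert sum(res.class_percentages.values()) == pytest.approx(100.0)
        rev = stratify_cohort(list(reversed(fixture_cohort)))
        assert rev.class_counts == res.class_counts
        assert rev.path_counts == res.path_counts

    def test_single_no_fall_record(self):
        res = stratify_cohort([make_record(fall_past_year=TriState.NO)])
        assert res.class_counts["low"] == 1
        assert sum(res.class_counts.values()) == 1

    def test_empty_cohort_raises(self):
        with pytest.raises(EmptyCohortError):
            stratify_cohort([])

    def test_mode_requires_fall_history_field(self):
        with pytest.raises(ValueError, match="fall_past_year"):
            StratificationMode("custom", frozenset({"cfs"}))
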