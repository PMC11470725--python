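"""Independent brute-force oracle for the risk-stratification semantics.

Deliberately written without reusing any of the package's enumeration code:
it materialises every completion of a record's missing deciding fields with
``itertools.product``, filters logically inconsistent combinations with its
own predicate, and classifies each completion with a standalone decision
tree. Used by the property tests to cross-check ``classify`` /
``classify_completions``.
"""
from __future__ import annotations

import itertools

from fallstrat.cohort_model import FallsCount, PatientRecord, TriState
from fallstrat.stratification import RiskClass, StratificationMode

_SEVERITIES = ("severity_lying_on_floor", "severity_loss_of_consciousness",
               "severity_injury")


def _tree(fall: str, count: str, frailty: str, balance: str, severity: str) -> RiskClass:
    """Plain complete-case guideline tree on string-valued inputs."""
    if fall == "no":
        return RiskClass.LOW
    if count == "2plus":
        return RiskClass.HIGH
    if frailty == "high":
        return RiskClass.HIGH
    if severity == "yes":
        return RiskClass.HIGH
    if balance == "yes":
        return RiskClass.INTERMEDIATE
    return RiskClass.LOW


def _consistent(fall: str, count: str) -> bool:
    if fall == "no":
        return count == "zero"
    return count in ("one", "2plus")


def oracle_classes(record: PatientRecord, mode: StratificationMode) -> set:
    """Set of classes over every consistent completion of the record."""
    av = mode.available_fields

    fall_dom = {TriState.YES: ["yes"], TriState.NO: ["no"],
                TriState.MISSING: ["yes", "no"]}[record.fall_past_year]

    if "falls_count_category" in av:
        count_dom = {FallsCount.ZERO: ["zero"], FallsCount.ONE: ["one"],
                     FallsCount.TWO_PLUS: ["2plus"],
                     FallsCount.MISSING: ["zero", "one", "2plus"],
                     }[record.falls_count_category]
    else:
        count_dom = ["zero", "one"]  # never collected: two-plus criterion can't fire

    if "cfs" in av:
        if record.cfs is None:
            frail_dom = ["low", "high"]
        else:
            frail_dom = ["high"] if record.cfs >= 5 else ["low"]
    else:
        frail_dom = ["low"]

    if "balance_issue" in av:
        bal_dom = {TriState.YES: ["yes"], TriState.NO: ["no"],
                   TriState.MISSING: ["yes", "no"]}[record.balance_issue]
    else:
        bal_dom = ["no"]

    sev_available = [s for s in _SEVERITIES if s in av]
    if not sev_available:
        sev_dom = ["no"]
    else:
        flags = [getattr(record, s) for s in sev_available]
        if any(f is TriState.YES for f in flags):
            sev_dom = ["yes"]
        elif any(f is TriState.MISSING for f in flags):
            sev_dom = ["yes", "no"]
        else:
            sev_dom = ["no"]

    classes = set()
    for fall, count, frailty, balance, severity in itertools.product(
            fall_dom, count_dom, frail_dom, bal_dom, sev_dom):
        if not _consistent(fall, count):
            continue
        classes.add(_tree(fall, count, frailty, balance, severity))
    return classes


def oracle_classify(record: PatientRecord, mode: StratificationMode) -> RiskClass:
    classes = oracle_classes(record, mode)
    if len(classes) == 1:
        return next(iter(classes))
    return RiskClass.UNCLASSIFIABLE
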