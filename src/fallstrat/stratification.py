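"""Falls-risk stratification with three-valued missing-data semantics.

The world falls-prevention guidelines triage an older adult by (1) any fall
in the past 12 months — if not, low risk; (2) severity screening — two or
more falls, high frailty, or (in the full guideline) lying on the floor
unable to get up, loss of consciousness, or injury — any of which makes the
patient high risk; (3) otherwise impaired balance/gait puts them at
intermediate risk, else low. The study's CGA collected fall history, fall
count, the Clinical Frailty Scale and balance status, so the *paper-adapted*
mode decides on exactly those four fields; *full-guideline* mode additionally
consults the three severity flags.

Missing data is handled by determinate-completion semantics: a partially
observed record is assigned a class only if **every** logically consistent
completion of its missing deciding fields yields that same class; otherwise
it is unclassifiable (the "N/A" category of the study's waffle plot).
Completions respect the coupling between fall history and fall count
(count zero iff no fall in the past year), so an observed count of two-plus
pins an unrecorded fall history to "yes". Fields outside the mode's
``available_fields`` are structurally absent — never enumerated — because a
field the service never collected should not drag every patient into N/A.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .cohort_model import (
    EmptyCohortError,
    FallsCount,
    FrailtyLevel,
    PatientRecord,
    TriState,
)


class RiskClass(Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"
    UNCLASSIFIABLE = "unclassifiable"


class RiskPath(Enum):
    """Decision-path labels matching the study's waffle-plot legend.

    ``HIGH_SEVERITY`` extends the legend for full-guideline mode, where a
    severity flag alone can force high risk (the study never collected those
    fields, so the legend has no label for it).
    """

    LOW_NO_FALLS = "low_no_falls"
    LOW_FRAILTY = "low_frailty"
    HIGH_FALLS = "high_falls"
    HIGH_FRAILTY = "high_frailty"
    HIGH_SEVERITY = "high_severity"
    INTERMEDIATE = "intermediate"
    NA = "na"


_SEVERITY_FIELDS = (
    "severity_lying_on_floor",
    "severity_loss_of_consciousness",
    "severity_injury",
)

#: deciding fields the study's CGA actually collected
PAPER_ADAPTED_FIELDS = frozenset(
    {"fall_past_year", "falls_count_category", "cfs", "balance_issue"}
)
FULL_GUIDELINE_FIELDS = PAPER_ADAPTED_FIELDS | frozenset(_SEVERITY_FIELDS)


@dataclass(frozen=True)
class StratificationMode:
    """Which deciding fields count as collected.

    ``available_fields`` drives the missing-data enumeration: a missing value
    of an available field is enumerated over its domain; an unavailable field
    is treated as criterion-not-met and never enumerated.
    """

    mode: str
    available_fields: frozenset

    def __post_init__(self):
        if "fall_past_year" not in self.available_fields:
            raise ValueError("fall_past_year is the root of the decision tree and must be available")
        unknown = self.available_fields - FULL_GUIDELINE_FIELDS
        if unknown:
            raise ValueError(f"unknown deciding fields: {sorted(unknown)}")

    @property
    def uses_severity(self) -> bool:
        return any(f in self.available_fields for f in _SEVERITY_FIELDS)


PAPER_ADAPTED = StratificationMode("paper_adapted", PAPER_ADAPTED_FIELDS)
FULL_GUIDELINE = StratificationMode("full_guideline", FULL_GUIDELINE_FIELDS)


@dataclass(frozen=True)
class RiskAssignment:
    risk: RiskClass
    path: RiskPath
    deciding_variables: tuple = ()


@dataclass(frozen=True)
class StratificationResult:
    """Cohort-level class/path counts; percentages are of the full cohort."""

    n_total: int
    class_counts: dict
    path_counts: dict
    class_percentages: dict  # full precision, of n_total
    assignments: tuple  # per-record RiskAssignment, input order

    def rounded_percentages(self, decimals: int = 1) -> dict:
        return {k: round(v, decimals) for k, v in self.class_percentages.items()}


class InconsistentRecordError(ValueError):
    """Observed deciding fields admit no logically consistent completion."""


def _decide_complete(fall_yes: bool, count: FallsCount, frailty_high: bool,
                     balance_yes: bool, severity_yes: bool) -> tuple:
    """Decision tree on a fully determined set of deciding values."""
    if not fall_yes:
        return RiskClass.LOW, RiskPath.LOW_NO_FALLS
    if count is FallsCount.TWO_PLUS:
        return RiskClass.HIGH, RiskPath.HIGH_FALLS
    if frailty_high:
        return RiskClass.HIGH, RiskPath.HIGH_FRAILTY
    if severity_yes:
        return RiskClass.HIGH, RiskPath.HIGH_SEVERITY
    if balance_yes:
        return RiskClass.INTERMEDIATE, RiskPath.INTERMEDIATE
    return RiskClass.LOW, RiskPath.LOW_FRAILTY


def _completion_outcomes(record: PatientRecord, mode: StratificationMode) -> set:
    """(class, path) pairs over every consistent completion of missing deciding fields."""
    av = mode.available_fields

    fall = record.fall_past_year
    count_available = "falls_count_category" in av
    count = record.falls_count_category if count_available else FallsCount.MISSING
    frailty = record.frailty if "cfs" in av else FrailtyLevel.LOW
    balance = record.balance_issue if "balance_issue" in av else TriState.NO

    fall_options = [fall] if fall is not TriState.MISSING else [TriState.NO, TriState.YES]

    # severity: any observed "yes" forces the flag; missing available flags can
    # complete either way, so the flag ranges over {False, True} in that case
    sev_flags = [getattr(record, f) for f in _SEVERITY_FIELDS if f in av]
    if any(s is TriState.YES for s in sev_flags):
        severity_options = [True]
    elif any(s is TriState.MISSING for s in sev_flags):
        severity_options = [False, True]
    else:
        severity_options = [False]

    outcomes: set = set()
    for f in fall_options:
        if f is TriState.NO:
            # count must complete to zero; an observed one/two_plus contradicts
            if count in (FallsCount.ONE, FallsCount.TWO_PLUS):
                continue
            outcomes.add(_decide_complete(False, FallsCount.ZERO, False, False, False))
            continue
        # fall = yes: count completes over {one, two_plus}; observed zero contradicts;
        # a structurally absent count is never enumerated - the two-plus
        # criterion simply cannot fire
        if count is FallsCount.ZERO:
            continue
        if not count_available:
            count_options = [FallsCount.ONE]
        elif count is FallsCount.MISSING:
            count_options = [FallsCount.ONE, FallsCount.TWO_PLUS]
        else:
            count_options = [count]
        frail_options = ([frailty is FrailtyLevel.HIGH] if frailty is not FrailtyLevel.MISSING
                         else [False, True])
        bal_options = ([balance is TriState.YES] if balance is not TriState.MISSING
                       else [False, True])
        for c in count_options:
            for fr in frail_options:
                for sv in severity_options:
                    for b in bal_options:
                        outcomes.add(_decide_complete(True, c, fr, b, sv))
    if not outcomes:
        raise InconsistentRecordError(
            f"record {record.patient_id!r}: fall_past_year={fall.value} contradicts "
            f"falls_count_category={count.value}")
    return outcomes


def classify_completions(record: PatientRecord,
                         mode: StratificationMode = PAPER_ADAPTED) -> set:
    """Set of risk classes over all consistent completions of the record."""
    return {cls for cls, _ in _completion_outcomes(record, mode)}


# paths whose legend definition names an observable condition; used to
# disambiguate when completions agree on the class but not the path
def _path_observed(path: RiskPath, record: PatientRecord) -> bool:
    if path is RiskPath.HIGH_FALLS:
        return record.falls_count_category is FallsCount.TWO_PLUS
    if path is RiskPath.HIGH_FRAILTY:
        return record.frailty is FrailtyLevel.HIGH
    if path is RiskPath.HIGH_SEVERITY:
        return any(getattr(record, f) is TriState.YES for f in _SEVERITY_FIELDS)
    if path is RiskPath.LOW_NO_FALLS:
        return record.fall_past_year is TriState.NO
    return True


_PATH_PRECEDENCE = list(RiskPath)


def classify(record: PatientRecord,
             mode: StratificationMode = PAPER_ADAPTED) -> RiskAssignment:
    """Assign a risk class under determinate-completion semantics.

    The record gets class C iff every consistent completion of its missing
    deciding fields lands on C; otherwise it is unclassifiable with path
    ``na``. When the class is determinate but different completions take
    different legend paths (e.g. an unrecorded fall count with high frailty
    is high either way), the reported path is the one whose defining
    condition is actually observed.
    """
    outcomes = _completion_outcomes(record, mode)
    classes = {cls for cls, _ in outcomes}
    deciding = tuple(sorted(mode.available_fields))
    if len(classes) != 1:
        return RiskAssignment(RiskClass.UNCLASSIFIABLE, RiskPath.NA, deciding)
    (risk,) = classes
    paths = {p for _, p in outcomes}
    if len(paths) > 1:
        observed = [p for p in paths if _path_observed(p, record)]
        paths = set(observed) if observed else paths
    path = min(paths, key=_PATH_PRECEDENCE.index)
    return RiskAssignment(risk, path, deciding)


def stratify_cohort(records: Sequence[PatientRecord],
                    mode: StratificationMode = PAPER_ADAPTED) -> StratificationResult:
    """Classify every record and aggregate class/path counts.

    Aggregation is order-free; percentages are over the full cohort
    (the study reported the unclassifiable fraction, 13.8%, as part of the
    denominator).
    """
    if not records:
        raise EmptyCohortError("cannot stratify an empty cohort")
    assignments = tuple(classify(rec, mode) for rec in records)
    n = len(records)
    class_counts = {cls.value: 0 for cls in RiskClass}
    path_counts = {p.value: 0 for p in RiskPath}
    for a in assignments:
        class_counts[a.risk.value] += 1
        path_counts[a.path.value] += 1
    if not mode.uses_severity:
        path_counts.pop(RiskPath.HIGH_SEVERITY.value)
    pct = {k: 100.0 * v / n for k, v in class_counts.items()}
    return StratificationResult(n_total=n, class_counts=class_counts,
                                path_counts=path_counts, class_percentages=pct,
                                assignments=assignments)
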