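"""Sensory-intervention coverage and fall-risk-increasing drug (FRID) summaries.

For each risk group the coverage report asks: of the patients with a given
sensory issue (vision loss, hearing loss, balance issue), how many already
have the matching intervention (glasses, hearing aid, mobility aid)?
Percentages are computed after removing patients with missing aid data, and
patients whose impairment status is itself missing are excluded from both
numerator and denominator.

FRID status arrives as an input (it comes from a pharmacist's medicines
reconciliation, available only for a subset of patients); the summary is
restricted to records with non-missing FRID data.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

from .cohort_model import PatientRecord, TriState
from .stratification import RiskAssignment, RiskClass

#: condition label -> (impairment field, matching aid field)
CONDITIONS = {
    "vision_loss": ("vision_impaired", "glasses"),
    "hearing_loss": ("hearing_impaired", "hearing_aid"),
    "balance_issue": ("balance_issue", "mobility_aid"),
}


class AlignmentError(ValueError):
    """Records and assignments do not line up one-to-one."""


@dataclass(frozen=True)
class CoverageReport:
    """Aid coverage for one risk class x condition cell."""

    risk: str
    condition: str
    n_with_condition: int
    n_aided: int
    n_unaided: int
    n_missing_aid_data: int
    pct_aided: Union[float, None]  # None when no non-missing aid data

    def to_dict(self) -> dict:
        return dict(risk=self.risk, condition=self.condition,
                    n_with_condition=self.n_with_condition, n_aided=self.n_aided,
                    n_unaided=self.n_unaided, n_missing_aid_data=self.n_missing_aid_data,
                    pct_aided=self.pct_aided)


@dataclass(frozen=True)
class FridClassSummary:
    risk: str
    n_with_frid_data: int
    n_taking_frid: int
    pct_taking_frid: Union[float, None]
    n_on_five_plus_frids: int

    def to_dict(self) -> dict:
        return dict(risk=self.risk, n_with_frid_data=self.n_with_frid_data,
                    n_taking_frid=self.n_taking_frid, pct_taking_frid=self.pct_taking_frid,
                    n_on_five_plus_frids=self.n_on_five_plus_frids)


@dataclass(frozen=True)
class FridReport:
    per_class: tuple  # FridClassSummary per risk class

    @property
    def n_with_frid_data(self) -> int:
        return sum(c.n_with_frid_data for c in self.per_class)

    @property
    def n_on_five_plus_frids(self) -> int:
        return sum(c.n_on_five_plus_frids for c in self.per_class)

    def for_class(self, risk: str) -> FridClassSummary:
        for c in self.per_class:
            if c.risk == risk:
                return c
        raise KeyError(risk)


def _check_alignment(records: Sequence[PatientRecord],
                     assignments: Sequence[RiskAssignment]) -> None:
    if len(records) != len(assignments):
        raise AlignmentError(
            f"{len(records)} records vs {len(assignments)} assignments")


def intervention_coverage(records: Sequence[PatientRecord],
                          assignments: Sequence[RiskAssignment]) -> list:
    """Per risk-class, per-condition aid coverage.

    ``records`` and ``assignments`` must be index-aligned (as produced by
    ``stratify_cohort``). One report row per (risk class, condition) pair.
    """
    _check_alignment(records, assignments)
    reports = []
    for risk in RiskClass:
        members = [rec for rec, a in zip(records, assignments) if a.risk is risk]
        for condition, (impair_field, aid_field) in CONDITIONS.items():
            with_cond = [r for r in members
                         if getattr(r, impair_field) is TriState.YES]
            aided = sum(1 for r in with_cond if getattr(r, aid_field) is TriState.YES)
            unaided = sum(1 for r in with_cond if getattr(r, aid_field) is TriState.NO)
            missing = len(with_cond) - aided - unaided
            known = aided + unaided
            pct = 100.0 * aided / known if known else None
            reports.append(CoverageReport(
                risk=risk.value, condition=condition,
                n_with_condition=len(with_cond), n_aided=aided, n_unaided=unaided,
                n_missing_aid_data=missing, pct_aided=pct))
    return reports


def frid_summary(records: Sequence[PatientRecord],
                 assignments: Sequence[RiskAssignment]) -> FridReport:
    """FRID exposure by risk class among records with reconciliation data."""
    _check_alignment(records, assignments)
    per_class = []
    for risk in RiskClass:
        members = [rec for rec, a in zip(records, assignments) if a.risk is risk]
        with_data = [r for r in members if r.frid_use is not TriState.MISSING]
        taking = sum(1 for r in with_data if r.frid_use is TriState.YES)
        five_plus = sum(1 for r in with_data
                        if r.frid_count is not None and r.frid_count >= 5)
        pct = 100.0 * taking / len(with_data) if with_data else None
        per_class.append(FridClassSummary(
            risk=risk.value, n_with_frid_data=len(with_data), n_taking_frid=taking,
            pct_taking_frid=pct, n_on_five_plus_frids=five_plus))
    return FridReport(per_class=tuple(per_class))
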