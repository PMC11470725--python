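"""Coded comprehensive geriatric assessment (CGA) cohort data model.

A cohort is a list of :class:`PatientRecord`, one per patient assessed by
the frailty intervention team. Every clinical variable that can be absent
from a chart is tri-state (yes / no / missing): missingness is data here,
not an error, because whether a patient can be risk-stratified at all
depends on which fields were collected.

The CSV coding scheme mirrors the source charts: binaries are 0/1, sex is
1 (female) / 2 (male), the Clinical Frailty Scale (CFS) is an integer 1-9,
and missing cells are "N/A" (also accepted: "NA" and the empty cell;
always written back as "NA"). Codes exist only at the I/O boundary -
in memory sex is a label and tri-states are enum members, so nothing can
accidentally do arithmetic on nominal codes.
"""
from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, fields
from enum import Enum
from typing import IO, Iterable, Sequence, Union

logger = logging.getLogger(__name__)

#: cell spellings accepted as missing on input
MISSING_TOKENS = frozenset({"N/A", "NA", "", "na", "n/a"})
#: canonical missing token on output
MISSING_OUT = "NA"

MIN_INCLUSION_AGE = 65


class CohortFormatError(ValueError):
    """Structurally invalid cohort CSV (bad header, uncodable cell in strict mode)."""


class CohortValidationError(ValueError):
    """Cohort-level consistency failure (e.g. duplicate patient_id)."""


class EmptyCohortError(ValueError):
    """An operation requiring at least one record was given none."""


class TriState(Enum):
    """Three-valued clinical status: yes / no / missing.

    Missing is a first-class state, distinct from any default, because the
    stratification engine must reason about what *could* be true of an
    uncollected field.
    """

    YES = "yes"
    NO = "no"
    MISSING = "missing"

    @property
    def is_missing(self) -> bool:
        return self is TriState.MISSING

    @classmethod
    def from_code(cls, cell: str, *, strict: bool = True, context: str = "") -> "TriState":
        cell = cell.strip()
        if cell in MISSING_TOKENS:
            return cls.MISSING
        if cell == "1":
            return cls.YES
        if cell == "0":
            return cls.NO
        if strict:
            raise CohortFormatError(f"uncodable tri-state cell {cell!r} ({context})")
        logger.warning("coercing uncodable cell %r to missing (%s)", cell, context)
        return cls.MISSING

    def to_code(self) -> str:
        return {TriState.YES: "1", TriState.NO: "0", TriState.MISSING: MISSING_OUT}[self]


class FallsCount(Enum):
    """Category of falls in the past 12 months; the charts distinguish only 0 / 1 / >=2."""

    ZERO = "zero"
    ONE = "one"
    TWO_PLUS = "two_plus"
    MISSING = "missing"

    @classmethod
    def from_code(cls, cell: str, *, strict: bool = True, context: str = "") -> "FallsCount":
        cell = cell.strip()
        if cell in MISSING_TOKENS:
            return cls.MISSING
        mapping = {"0": cls.ZERO, "1": cls.ONE, "2plus": cls.TWO_PLUS, "2+": cls.TWO_PLUS}
        if cell in mapping:
            return mapping[cell]
        if strict:
            raise CohortFormatError(f"uncodable falls_count cell {cell!r} ({context})")
        logger.warning("coercing uncodable falls_count %r to missing (%s)", cell, context)
        return cls.MISSING

    def to_code(self) -> str:
        return {
            FallsCount.ZERO: "0",
            FallsCount.ONE: "1",
            FallsCount.TWO_PLUS: "2plus",
            FallsCount.MISSING: MISSING_OUT,
        }[self]


class FrailtyLevel(Enum):
    """CFS dichotomised: 1-4 low frailty, 5-9 high frailty."""

    LOW = "low"
    HIGH = "high"
    MISSING = "missing"


def dichotomize_frailty(cfs: Union[int, None]) -> FrailtyLevel:
    """Dichotomise a Clinical Frailty Scale score: 1-4 -> low, 5-9 -> high.

    Missing (None) propagates; a score outside 1..9 is a domain error.
    """
    if cfs is None:
        return FrailtyLevel.MISSING
    if not (1 <= int(cfs) <= 9):
        raise ValueError(f"CFS must lie in 1..9, got {cfs!r}")
    return FrailtyLevel.LOW if cfs <= 4 else FrailtyLevel.HIGH


@dataclass(frozen=True)
class PatientRecord:
    """One coded CGA row.

    ``severity_*`` fields are the three high-risk severity criteria the
    guideline asks about but the study's CGA never collected; they exist so
    the full-guideline stratification mode has somewhere to read them, and
    default to missing.
    """

    patient_id: str
    age: Union[int, None]
    sex: Union[str, None]  # "female" | "male" | None
    presented_with_fall: TriState = TriState.MISSING
    fall_past_year: TriState = TriState.MISSING
    falls_count_category: FallsCount = FallsCount.MISSING
    cfs: Union[int, None] = None
    vision_impaired: TriState = TriState.MISSING
    hearing_impaired: TriState = TriState.MISSING
    dizziness: TriState = TriState.MISSING
    balance_issue: TriState = TriState.MISSING
    glasses: TriState = TriState.MISSING
    hearing_aid: TriState = TriState.MISSING
    mobility_aid: TriState = TriState.MISSING
    frid_use: TriState = TriState.MISSING
    frid_count: Union[int, None] = None
    severity_lying_on_floor: TriState = TriState.MISSING
    severity_loss_of_consciousness: TriState = TriState.MISSING
    severity_injury: TriState = TriState.MISSING

    @property
    def frailty(self) -> FrailtyLevel:
        return dichotomize_frailty(self.cfs)


@dataclass(frozen=True)
class Violation:
    """One invariant breach on a record; data, not an exception."""

    patient_id: str
    field: str
    rule: str
    message: str


@dataclass(frozen=True)
class CohortSummary:
    """Demographic roll-up of a cohort (means over complete cases only)."""

    n_total: int
    n_female: int
    pct_female: float
    n_missing_sex: int
    age_min: Union[int, None]
    age_max: Union[int, None]
    age_mean: Union[float, None]
    cfs_mean: Union[float, None]
    n_missing_cfs: int
    n_fall_past_year: int
    n_no_fall: int
    n_missing_falls: int
    pct_fall_past_year: float
    n_presented_with_fall: int

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# CSV I/O

MANDATORY_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "presented_with_fall",
    "fall_past_year",
    "falls_count",
    "cfs",
    "vision",
    "hearing",
    "dizziness",
    "balance",
    "glasses",
    "hearing_aids",
    "mobility_aid",
    "frid_use",
    "frid_count",
)
OPTIONAL_COLUMNS = (
    "severity_lying_on_floor",
    "severity_loss_of_consciousness",
    "severity_injury",
)

_TRISTATE_COLS = {
    "presented_with_fall": "presented_with_fall",
    "fall_past_year": "fall_past_year",
    "vision": "vision_impaired",
    "hearing": "hearing_impaired",
    "dizziness": "dizziness",
    "balance": "balance_issue",
    "glasses": "glasses",
    "hearing_aids": "hearing_aid",
    "mobility_aid": "mobility_aid",
    "frid_use": "frid_use",
    "severity_lying_on_floor": "severity_lying_on_floor",
    "severity_loss_of_consciousness": "severity_loss_of_consciousness",
    "severity_injury": "severity_injury",
}

_SEX_CODES = {"1": "female", "2": "male"}
_SEX_LABELS = {"female": "1", "male": "2", None: MISSING_OUT}


def _parse_int(cell: str, *, lo: int, hi: int, strict: bool, context: str) -> Union[int, None]:
    cell = cell.strip()
    if cell in MISSING_TOKENS:
        return None
    try:
        value = int(cell)
    except ValueError:
        if strict:
            raise CohortFormatError(f"non-integer cell {cell!r} ({context})") from None
        logger.warning("coercing non-integer cell %r to missing (%s)", cell, context)
        return None
    if not (lo <= value <= hi):
        if strict:
            raise CohortFormatError(f"cell {value} outside {lo}..{hi} ({context})")
        logger.warning("coercing out-of-range cell %r to missing (%s)", cell, context)
        return None
    return value


def parse_cohort(source: Union[str, IO[str]], strict: bool = True) -> list[PatientRecord]:
    """Read a coded cohort CSV into records, preserving row order.

    ``source`` is a path or an open text stream. In strict mode any cell
    that does not follow the coding scheme raises :class:`CohortFormatError`
    naming the offending row/column; in lenient mode it is coerced to
    missing with a logged warning. A missing mandatory column or a
    duplicate patient_id always raises.
    """
    if isinstance(source, str):
        with open(source, newline="", encoding="utf-8") as fh:
            return parse_cohort(fh, strict=strict)

    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        raise CohortFormatError("empty input: no header row")
    header = [name.strip() for name in reader.fieldnames]
    absent = [col for col in MANDATORY_COLUMNS if col not in header]
    if absent:
        raise CohortFormatError(f"missing mandatory column(s): {', '.join(absent)}")

    records: list[PatientRecord] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(reader, start=2):  # line 1 is the header
        ctx = f"row {i}"
        pid = (row.get("patient_id") or "").strip()
        if not pid:
            raise CohortFormatError(f"blank patient_id ({ctx})")
        if pid in seen_ids:
            raise CohortValidationError(f"duplicate patient_id {pid!r} ({ctx})")
        seen_ids.add(pid)

        sex_cell = (row.get("sex") or "").strip()
        if sex_cell in MISSING_TOKENS:
            sex = None
        elif sex_cell in _SEX_CODES:
            sex = _SEX_CODES[sex_cell]
        elif strict:
            raise CohortFormatError(f"uncodable sex cell {sex_cell!r} ({ctx})")
        else:
            logger.warning("coercing uncodable sex %r to missing (%s)", sex_cell, ctx)
            sex = None

        kwargs: dict = {
            "patient_id": pid,
            "age": _parse_int(row.get("age") or "", lo=0, hi=130, strict=strict,
                              context=f"{ctx} col age"),
            "sex": sex,
            "falls_count_category": FallsCount.from_code(
                row.get("falls_count") or "", strict=strict, context=f"{ctx} col falls_count"),
            "cfs": _parse_int(row.get("cfs") or "", lo=1, hi=9, strict=strict,
                              context=f"{ctx} col cfs"),
            "frid_count": _parse_int(row.get("frid_count") or "", lo=0, hi=99, strict=strict,
                                     context=f"{ctx} col frid_count"),
        }
        for col, attr in _TRISTATE_COLS.items():
            if col in OPTIONAL_COLUMNS and col not in header:
                continue
            kwargs[attr] = TriState.from_code(
                row.get(col) or "", strict=strict, context=f"{ctx} col {col}")
        records.append(PatientRecord(**kwargs))
    return records


def write_cohort(records: Iterable[PatientRecord], dest: Union[str, IO[str], None] = None) -> str:
    """Serialise records back to the coded CSV dialect (missing -> "NA").

    Returns the CSV text; also writes it to ``dest`` (path or stream) if given.
    Round-trips with :func:`parse_cohort` cell-for-cell on canonical input.
    """
    buf = io.StringIO()
    columns = list(MANDATORY_COLUMNS) + list(OPTIONAL_COLUMNS)
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(columns)
    attr_for = {**{c: c for c in ("patient_id",)}, **_TRISTATE_COLS}
    for rec in records:
        row = []
        for col in columns:
            if col == "patient_id":
                row.append(rec.patient_id)
            elif col == "age":
                row.append(MISSING_OUT if rec.age is None else str(rec.age))
            elif col == "sex":
                row.append(_SEX_LABELS[rec.sex])
            elif col == "falls_count":
                row.append(rec.falls_count_category.to_code())
            elif col == "cfs":
                row.append(MISSING_OUT if rec.cfs is None else str(rec.cfs))
            elif col == "frid_count":
                row.append(MISSING_OUT if rec.frid_count is None else str(rec.frid_count))
            else:
                row.append(getattr(rec, attr_for[col]).to_code())
        writer.writerow(row)
    text = buf.getvalue()
    if dest is not None:
        if isinstance(dest, str):
            with open(dest, "w", encoding="utf-8") as fh:
                fh.write(text)
        else:
            dest.write(text)
    return text


# ---------------------------------------------------------------------------
# Validation and summaries

def validate_record(record: PatientRecord) -> list[Violation]:
    """Check a record against the study invariants; violations are returned, never raised.

    Rules: inclusion age >= 65; CFS in 1..9 when present; falls count category
    consistent with the yes/no fall history when both are observed; frid_count
    non-negative and only present alongside frid_use.
    """
    out: list[Violation] = []
    pid = record.patient_id
    if record.age is None:
        out.append(Violation(pid, "age", "age-missing", "age is missing"))
    elif record.age < MIN_INCLUSION_AGE:
        out.append(Violation(pid, "age", "age-below-inclusion",
                             f"age {record.age} below inclusion threshold {MIN_INCLUSION_AGE}"))
    if record.cfs is not None and not (1 <= record.cfs <= 9):
        out.append(Violation(pid, "cfs", "cfs-out-of-range", f"CFS {record.cfs} outside 1..9"))
    fall, count = record.fall_past_year, record.falls_count_category
    if fall is TriState.NO and count not in (FallsCount.ZERO, FallsCount.MISSING):
        out.append(Violation(pid, "falls_count_category", "inconsistent-falls",
                             f"no fall in past year but falls count {count.value}"))
    if fall is TriState.YES and count is FallsCount.ZERO:
        out.append(Violation(pid, "falls_count_category", "inconsistent-falls",
                             "fall in past year but falls count zero"))
    if record.frid_count is not None and record.frid_count < 0:
        out.append(Violation(pid, "frid_count", "negative-frid-count",
                             f"frid_count {record.frid_count} negative"))
    if record.frid_count not in (None, 0) and record.frid_use is TriState.NO:
        out.append(Violation(pid, "frid_count", "frid-count-without-use",
                             "positive frid_count but frid_use is no"))
    return out


def tri_state_counts(records: Sequence[PatientRecord], attr: str) -> dict:
    """Yes/no/missing counts for one tri-state field; always sums to len(records)."""
    counts = {"yes": 0, "no": 0, "missing": 0}
    for rec in records:
        counts[getattr(rec, attr).value] += 1
    return counts


def summarize_cohort(records: Sequence[PatientRecord]) -> CohortSummary:
    """Demographic summary: counts over all records, means over complete cases.

    Percentages are kept at full precision; round only at presentation.
    """
    if not records:
        raise EmptyCohortError("cannot summarise an empty cohort")
    n = len(records)
    ages = [r.age for r in records if r.age is not None]
    cfs = [r.cfs for r in records if r.cfs is not None]
    n_female = sum(1 for r in records if r.sex == "female")
    n_missing_sex = sum(1 for r in records if r.sex is None)
    falls = tri_state_counts(records, "fall_past_year")
    return CohortSummary(
        n_total=n,
        n_female=n_female,
        pct_female=100.0 * n_female / n,
        n_missing_sex=n_missing_sex,
        age_min=min(ages) if ages else None,
        age_max=max(ages) if ages else None,
        age_mean=sum(ages) / len(ages) if ages else None,
        cfs_mean=sum(cfs) / len(cfs) if cfs else None,
        n_missing_cfs=n - len(cfs),
        n_fall_past_year=falls["yes"],
        n_no_fall=falls["no"],
        n_missing_falls=falls["missing"],
        pct_fall_past_year=100.0 * falls["yes"] / n,
        n_presented_with_fall=tri_state_counts(records, "presented_with_fall")["yes"],
    )
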