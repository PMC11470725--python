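"""Shared random-record builder for classifier property checks (seeded numpy, not hypothesis)."""
from fallstrat.cohort_model import FallsCount, PatientRecord, TriState

_TRI = [TriState.YES, TriState.NO, TriState.MISSING]


def random_partial_records(rng, n):
    """Consistent-by-construction records with random missingness on deciding fields."""
    out = []
    for i in range(n):
        fall = _TRI[rng.integers(0, 3)]
        if fall is TriState.NO:
            count = [FallsCount.ZERO, FallsCount.MISSING][rng.integers(0, 2)]
        elif fall is TriState.YES:
            count = [FallsCount.ONE, FallsCount.TWO_PLUS,
                     FallsCount.MISSING][rng.integers(0, 3)]
        else:
            count = list(FallsCount)[rng.integers(0, 4)]
        cfs = None if rng.random() < 0.25 else int(rng.integers(1, 10))
        balance = _TRI[rng.integers(0, 3)]
        out.append(PatientRecord(
            patient_id=f"r{i}", age=int(rng.integers(65, 104)),
            sex="female" if rng.random() < 0.5 else "male",
            fall_past_year=fall, falls_count_category=count,
            cfs=cfs, balance_issue=balance))
    return out
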