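#!/usr/bin/env python
"""Intervention coverage and FRID exposure by risk group on the fixture cohort.

For each risk group: how many patients with each sensory issue already have
the matching aid (after removing missing aid data), and what fraction of
those with a medicines reconciliation take at least one fall-risk-increasing
drug. Writes results/interventions.csv and results/frid.csv.
"""
import csv
from pathlib import Path

from fallstrat import (
    PAPER_ADAPTED,
    frid_summary,
    generate_fixture,
    intervention_coverage,
    stratify_cohort,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cohort = generate_fixture()
    strat = stratify_cohort(cohort, PAPER_ADAPTED)

    coverage = intervention_coverage(cohort, strat.assignments)
    with open(RESULTS / "interventions.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(coverage[0].to_dict()),
                           lineterminator="\n")
        w.writeheader()
        w.writerows(c.to_dict() for c in coverage)

    print("aid coverage in the high-risk group (excluding missing aid data):")
    for row in coverage:
        if row.risk == "high" and row.n_with_condition:
            pct = "undefined" if row.pct_aided is None else f"{row.pct_aided:.0f}%"
            print(f"  {row.condition:13s} n={row.n_with_condition:3d} "
                  f"aided={row.n_aided:3d} unaided={row.n_unaided:3d} "
                  f"missing={row.n_missing_aid_data:3d}  -> {pct} aided")

    frid = frid_summary(cohort, strat.assignments)
    with open(RESULTS / "frid.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(frid.per_class[0].to_dict()),
                           lineterminator="\n")
        w.writeheader()
        w.writerows(c.to_dict() for c in frid.per_class)

    print(f"\nFRID exposure ({frid.n_with_frid_data} with reconciliation data, "
          f"{frid.n_on_five_plus_frids} on five or more FRIDs):")
    for c in frid.per_class:
        if c.n_with_frid_data:
            print(f"  {c.risk:13s} {c.n_taking_frid}/{c.n_with_frid_data} "
                  f"({c.pct_taking_frid:.1f}%)")
    print(f"\nwrote {RESULTS / 'interventions.csv'} and {RESULTS / 'frid.csv'}")


if __name__ == "__main__":
    main()
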