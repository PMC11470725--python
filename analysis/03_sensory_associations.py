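#!/usr/bin/env python
"""Adjusted sensory-association models on a simulated cohort.

Fits each sensory variable (and FRID use) one at a time against (a) a fall
in the past year and (b) high- vs low-risk group membership, controlling for
age, sex and frailty, first at the study scale (n=392, where estimates are
noisy and often non-significant) and then at n=20,000 to show the generator's
log-odds (hearing 0.68, dizziness 0.81, vision 0.33, balance 0.34) are
recovered by the fitting chain. Writes results/associations.csv.
"""
import csv
from pathlib import Path

from fallstrat import AssociationSpec, SyntheticConfig, generate_cohort, run_association
from fallstrat.association import InsufficientDataError

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 17
SENSORY = ("hearing", "dizziness", "vision", "balance")


def fit_block(records, label, rows):
    print(f"\n{label} (n={len(records)} records)")
    print(f"  {'predictor':10s} {'outcome':18s} {'n':>6s} {'b':>7s} {'z':>6s} "
          f"{'p':>7s} {'OR':>5s} {'R2_N':>6s}")
    for outcome in ("fall_past_year", "high_vs_low_risk"):
        preds = SENSORY + (("frid_use",) if outcome == "high_vs_low_risk" else ())
        for pred in preds:
            try:
                res = run_association(records, AssociationSpec(pred, outcome))
            except InsufficientDataError as exc:
                print(f"  {pred:10s} {outcome:18s} skipped: {exc}")
                continue
            r = res.predictor_row()
            print(f"  {pred:10s} {outcome:18s} {r['n_used']:6d} {r['b']:+7.2f} "
                  f"{r['z']:6.2f} {r['p']:7.3f} {r['or_2dp']:5.2f} "
                  f"{100 * r['nagelkerke_r2']:5.1f}%")
            rows.append({"cohort": label, "predictor": pred, "outcome": outcome,
                         **{k: r[k] for k in ("n_used", "b", "se", "z", "p",
                                              "or", "or_2dp", "nagelkerke_r2")}})


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    fit_block(generate_cohort(SyntheticConfig(n=392), seed=SEED),
              "study-scale simulation", rows)
    fit_block(generate_cohort(SyntheticConfig(n=20000), seed=SEED + 1),
              "large-sample recovery", rows)
    with open(RESULTS / "associations.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(rows[0]), lineterminator="\n")
        w.writeheader()
        w.writerows(rows)
    print(f"\nwrote {RESULTS / 'associations.csv'}")


if __name__ == "__main__":
    main()
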