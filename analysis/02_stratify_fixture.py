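#!/usr/bin/env python
"""Risk-stratify the deterministic 392-record fixture cohort.

Applies the paper-adapted triage (fall history -> fall count / frailty ->
balance) with determinate-completion handling of missing data, and writes
the class distribution and waffle-plot path counts under results/.
Expected outcome: high 170 (43.4%), low 149 (38.0%), intermediate 19
(4.8%), unclassifiable 54 (13.8%); paths 139/10/104/66/19/54.
"""
import csv
import json
from pathlib import Path

from fallstrat import PAPER_ADAPTED, generate_fixture, stratify_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cohort = generate_fixture()
    res = stratify_cohort(cohort, PAPER_ADAPTED)
    pct = res.rounded_percentages(1)
    payload = {"n_total": res.n_total, "class_counts": res.class_counts,
               "class_percentages": pct, "path_counts": res.path_counts}
    (RESULTS / "stratification_fixture.json").write_text(json.dumps(payload, indent=2))
    with open(RESULTS / "waffle_counts.csv", "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["path", "count"])
        w.writerows(res.path_counts.items())

    print(f"stratified {res.n_total} records (paper-adapted mode):")
    for cls in ("high", "low", "intermediate", "unclassifiable"):
        print(f"  {cls:15s} {res.class_counts[cls]:4d}  ({pct[cls]}%)")
    print("decision paths:", dict(res.path_counts))
    print(f"wrote {RESULTS / 'stratification_fixture.json'}")


if __name__ == "__main__":
    main()
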