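#!/usr/bin/env python
"""Generate the study-scale synthetic cohort and summarise its demographics.

Draws one 392-patient cohort from the default generating model (age ~82,
58% female, CFS mean ~5.1, fall rate ~57%, study-level missingness) and
writes the coded CSV plus a demographic summary under results/.
"""
import json
from pathlib import Path

from fallstrat import SyntheticConfig, generate_cohort, summarize_cohort, write_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 17


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = SyntheticConfig(n=392)
    records = generate_cohort(cfg, seed=SEED)
    write_cohort(records, str(RESULTS / "synthetic_cohort.csv"))
    summary = summarize_cohort(records)
    (RESULTS / "synthetic_cohort_summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2))
    print(f"simulated cohort: n={summary.n_total}, "
          f"{summary.pct_female:.1f}% female, mean age {summary.age_mean:.1f} "
          f"({summary.age_min}-{summary.age_max})")
    print(f"fallers {summary.n_fall_past_year} ({summary.pct_fall_past_year:.1f}%), "
          f"missing falls data {summary.n_missing_falls}, "
          f"mean CFS {summary.cfs_mean:.2f}")
    print(f"wrote {RESULTS / 'synthetic_cohort.csv'}")


if __name__ == "__main__":
    main()
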