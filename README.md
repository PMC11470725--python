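# fallstrat

Falls-risk stratification and sensory-impairment association analysis for
older adults assessed in an emergency department, as done for comprehensive
geriatric assessment (CGA) data gathered by a frailty intervention team.

## The problem

The 2022 world guidelines for falls prevention and management triage a
community-dwelling older adult into **low**, **intermediate** or **high**
falls risk:

1. *Any fall in the past 12 months?* No → **low risk**.
2. *Severity screen*: ≥2 falls in the past year, frailty, lying on the
   floor unable to get up, loss of consciousness, or injury — any one →
   **high risk**. Frailty is the Clinical Frailty Scale (CFS, 1–9)
   dichotomised 1–4 = low, 5–9 = high.
3. Otherwise: impaired balance or gait → **intermediate risk**, else
   **low risk**.

Real CGA charts collect only part of this (fall history, fall count,
CFS, balance — not the three severity questions or gait speed) and have
substantial missing data. `fallstrat` implements the triage with
**determinate-completion semantics**: a partially observed patient is
assigned a class only when *every* logically consistent completion of the
missing collected fields gives the same class; otherwise they are
**unclassifiable** (N/A). Fields the service never collected are
structurally absent and are not enumerated. The engine is cross-checked
against a brute-force completion-enumeration oracle in the test suite.

Around the classifier the package provides:

* a typed, tri-state patient data model with a strict/lenient coded-CSV
  reader and writer (binaries 0/1, sex 1=female/2=male, missing = `NA`);
* adjusted association models: binomial logistic regression of each sensory
  variable (vision, hearing, dizziness, balance) and fall-risk-increasing
  drug (FRID) use against falls incidence or high- vs low-risk membership,
  controlling for age, sex and frailty, reporting log-odds *b*, Wald
  *z = b/SE*, two-sided *p*, odds ratio exp(*b*) and Nagelkerke pseudo-R²;
* intervention-coverage (glasses / hearing aids / mobility aids) and FRID
  summaries by risk group, with explicit missing-data denominators;
* a synthetic cohort generator (logistic data-generating model with
  configurable prevalences, effect sizes and MCAR missingness) plus a
  deterministic 392-record fixture cohort that realises the study
  distribution this package was built around.

## Worked example

```python
from fallstrat import PAPER_ADAPTED, generate_fixture, stratify_cohort

cohort = generate_fixture()            # deterministic 392-record cohort
res = stratify_cohort(cohort, PAPER_ADAPTED)
print(res.class_counts)
print(res.rounded_percentages(1))
print(res.path_counts)
```

prints

```
{'low': 149, 'intermediate': 19, 'high': 170, 'unclassifiable': 54}
{'low': 38.0, 'intermediate': 4.8, 'high': 43.4, 'unclassifiable': 13.8}
{'low_no_falls': 139, 'low_frailty': 10, 'high_falls': 104, 'high_frailty': 66, 'intermediate': 19, 'na': 54}
```

i.e. of 392 patients, 170 (43.4%) are high risk (104 via two-plus falls, 66
via one fall with high frailty), 149 (38.0%) low risk (139 with no recent
fall, 10 with one fall but neither frailty nor balance issues), 19 (4.8%)
intermediate (one fall, balance issue, no frailty), and 54 (13.8%) cannot
be stratified because a deciding field is missing and its completions
disagree.

The same pipeline runs from the shell:

```bash
fallstrat fixture --output cohort.csv
fallstrat stratify --input cohort.csv --mode paper_adapted --output strat.json
fallstrat simulate --seed 17 --n 2000 --output sim.csv
fallstrat associate --input sim.csv --outcome falls --predictors hearing,dizziness --output assoc.json
fallstrat run --source fixture --output report/
```

The numbered scripts under `analysis/` run the full narrative —
simulation, stratification, association models, intervention/FRID
summaries — and write their tables under `results/`.

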