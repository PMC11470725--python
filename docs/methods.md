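# Methods

## Risk stratification model

The triage is a three-level decision tree over a patient's past-year fall
history, fall count (0 / 1 / ≥2), frailty (Clinical Frailty Scale 1–9,
dichotomised 1–4 low / 5–9 high), balance status, and — in full-guideline
mode — three fall-severity flags (lying on the floor unable to get up,
loss of consciousness, injury):

```
no fall in past year                        → low        (path low_no_falls)
fall + ≥2 falls                             → high       (high_falls)
fall + 1 fall + high frailty                → high       (high_frailty)
fall + 1 fall + any severity flag (full)    → high       (high_severity)
fall + 1 fall + balance issue               → intermediate
fall + 1 fall, none of the above            → low        (low_frailty)
```

Balance stands in for the guideline's "impaired balance or gait" test;
gait speed / timed-up-and-go is not a collected field in this data model.

### Missing data: determinate-completion semantics

Chart data is incomplete, so the engine evaluates the tree under
three-valued (Kleene-style) semantics by explicit enumeration: every
logically consistent completion of the missing *collected* deciding fields
is classified, and the patient receives a class only when all completions
agree; otherwise they are **unclassifiable**. Consistency couples fall
history and count (count = 0 ⟺ no fall), so an observed count pins an
unrecorded history: count = 2plus alone implies high risk, count = 0 alone
implies low. This is strictly more informative than "any missing deciding
field → N/A" and never classifies a patient whose outcome could depend on
the unobserved value.

Two structural rules:

* **Structurally absent ≠ missing.** Fields outside the mode's
  `available_fields` (the severity flags and gait in `paper_adapted` mode)
  are treated as criterion-not-met and never enumerated. Without this,
  every patient would be unclassifiable in a service that never asks those
  questions. Fall history must always be available (it is the tree's root).
* **Path disambiguation.** When the class is determinate but completions
  travel different legend paths (only possible for fall = yes, count
  missing, frailty high: two-plus-falls vs one-fall-plus-frailty, both
  high), the reported path is the one whose defining condition is actually
  observed — here `high_frailty` — preserving the invariant that
  `high_falls` implies an observed count of ≥2.

The enumeration space is bounded (≤ 2·2·2·2·2 complete assignments per
record), so classification is exact and fast. An independently written
brute-force oracle (separate complete-case tree × `itertools.product`)
cross-checks the engine property-wise in the tests.

Cohort-level percentages are computed over the *full* cohort including the
unclassifiable group, at full precision, and rounded (default one decimal)
only at serialisation.

## Association models

Each sensory variable and FRID use is tested one at a time (never jointly
with the other sensory variables) against (a) any fall in the past year
and (b) high- vs low-risk group membership, in a binomial logistic model
with fixed adjustment for age (years, uncentred), sex (female = 0,
male = 1) and frailty (dichotomised CFS by default; the raw score is
available via `frailty_as="cfs"`). The risk-group outcome excludes
intermediate and unclassifiable patients by default (`high_vs_low`); a
`high_vs_rest` contrast is available. The odds ratio of the sensory term
is invariant to the age/sex codings chosen.

Fitting is Newton-type maximum likelihood (statsmodels `Logit` behind the
module surface) with relative tolerance 1e-8 and a 50-iteration cap.
Failure modes are explicit, never silent: constant or collinear columns
raise a degenerate-design error before fitting; perfect or
quasi-separation (statsmodels' detection, a singular observed information
matrix, or |b| > 15 with a non-vanishing score) raises a separation error;
hitting the iteration cap raises a convergence error. The intercept-only
log-likelihood uses its closed form ℓ0 = k·log(k/n) + (n−k)·log(1−k/n).

Complete-case analysis throughout: a record missing the outcome, the
predictor, or an adjustment variable is dropped from that model only; each
model reports n used and n dropped (the pipeline aggregates these into a
complete-case audit). Fewer than 25 usable records (configurable) is an
insufficient-data error. Wald z = b/SE with two-sided normal p-values;
model fit via Nagelkerke's pseudo-R²,
R² = (1 − exp((2/n)(ℓ0 − ℓ1))) / (1 − exp((2/n)ℓ0)) ∈ [0, 1].
An optional predictor×age interaction adds a likelihood-ratio test (df 1)
against the main-effects model.

No multiple-testing correction is applied, matching the analysis design
this package operationalises.

## Synthetic cohorts

### Random generator

`generate_cohort` samples the model the association analysis assumes:

| parameter | default | units / note |
|---|---|---|
| n | 392 | study scale |
| age | truncated normal, mean 82.2, sd 8, bounds 65–103 | sd not observable from range statistics; 8 y respects the bounds |
| % female | 57.8 | |
| CFS | categorical over 1..9, mean ≈ 5.1 | mode 5 (mildly frail) |
| prevalences | vision 0.70, hearing 0.45, dizziness 0.20, balance 0.72 | vision/balance are the common impairments in this setting |
| sensory log-odds on falls | hearing 0.68, dizziness 0.81, vision 0.33, balance 0.34 | the adjusted coefficients the analysis estimates |
| age / male / frailty log-odds | 0.02 / −0.10 / 0.50 | plausible nuisance effects; ORs of interest are insensitive to them |
| marginal fall rate | 0.569 | intercept calibrated numerically (Brent root-find on the sampled covariates) |
| P(≥2 falls \| faller) | 0.47 | matches the fixture's 104/223 split |
| FRID | P = 0.65 for non-fallers, log-odds +1.15 for fallers | reconciliation available for ~24% |
| aid probabilities | P(aid \| impaired, intact): glasses 0.60/0.30, hearing aid 0.70/0.02, mobility aid 0.72/0.25 | |
| missingness (MCAR) | falls 0.08, cfs 0.04, glasses 0.69, hearing aid 0.37, mobility aid 0.01, sensory 0.01–0.03, FRID 0.76 | applied last |

Missingness is missing-completely-at-random; the `apply_missingness` hook
accepts arbitrary per-variable rates so outcome-dependent (MNAR) masks can
be layered on for sensitivity studies, but none is on by default. The
falls mask blanks history *and* count together, and the FRID mask blanks
use and count together — otherwise the classifier could re-infer the
masked half from its partner. Generation is vectorised and reproducible:
one `numpy` Generator seeded per call drives everything, including the
missingness sub-seed.

What the generator does **not** emulate: correlations between sensory
impairments (they are drawn independently), informative missingness,
within-patient longitudinal structure, and any direct dependence of risk
path on sensory status beyond what the falls model induces. Passing
parameter-recovery tests therefore shows the estimator chain is unbiased
and calibrated *under this generating model*, not that real CGA data meet
its assumptions.

### Deterministic fixture

`generate_fixture` builds 392 records with **no randomness**. The deciding
fields realise the path counts 139 (no fall), 10 (one fall, low frailty,
no balance issue), 19 (one fall, low frailty, balance issue), 66 (one
fall, high frailty), 104 (two-plus falls) and 54 unclassifiable — the
latter split as 24 one-fall patients with unrecorded CFS (completions high
vs low/intermediate disagree) and 30 with fall history itself unrecorded.
That split also realises 223 observed fallers. The available count
summaries are mutually inconsistent by one record (139 + 223 + 31 > 392),
so the fixture realises the path counts and the faller total exactly and
carries 30 rather than 31 missing-falls records.

Non-deciding fields are filled from fixed modular cycles approximating the
cohort's marginals (227 female; ages as inner quantiles of the age
distribution, permuted so age is uncorrelated with path; sensory
prevalence cycles; aid coverage with the study-level missing-data burden).
FRID reconciliation covers 94 records spread across each risk class —
17/23 low, 2/8 intermediate, 52/63 high, four patients on ≥5 FRIDs. The
joint distribution of sensory status with risk path is not constrained
beyond these marginals.

## Numerical and design choices

* Percentages and odds ratios are computed at full precision and rounded
  only in reports (1 dp for percentages, 2 dp for ORs).
* The CSV boundary accepts `N/A`, `NA` and empty cells as missing and
  always writes `NA`; strict parsing raises on any uncodable cell, lenient
  parsing coerces to missing with a logged warning. Sex and tri-states are
  labels/enums in memory; numeric codes exist only at I/O.
* Record validation returns violation descriptors (inclusion age ≥ 65,
  CFS range, fall-history/count consistency, FRID count sanity) rather
  than raising, so flagged records are visible but not silently dropped.
* The pipeline treats data-driven fit failures (insufficient n,
  degenerate design, separation) as reported skips, and everything else as
  a fatal stage error. Reports are pure functions of (input, config,
  seed) apart from the provenance timestamp.
* Analysis drivers use n = 392 for study-scale illustration and n = 20,000
  for large-sample recovery; the repeated-cohort calibration check uses
  200 replicates at n = 2,000, sizes at which Monte-Carlo error on a
  log-odds mean is ≈ 0.007–0.015 and Wald coverage is estimable to ±1.5%.

## Known limitations

* One-at-a-time sensory models are non-collapsible: marginal adjusted
  estimates at the study scale sit slightly below the generator's joint
  log-odds even with independent predictors. The calibration suite
  therefore checks recovery with the joint model; the single-predictor
  recovery test uses a generator in which the other sensory effects are
  zero.
* Determinate-completion classification can disagree with an unknown
  upstream rule a clinical service actually used for partially missing
  charts; the unclassifiable category makes the ambiguity explicit rather
  than resolving it.
* The generator's prevalences for hearing and dizziness, and the joint
  sensory/path distribution in the fixture, are plausible defaults, not
  observed quantities.
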