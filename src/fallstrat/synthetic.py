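"""Synthetic ED frailty cohorts: a parameterised generator and a fixed fixture.

The study's patient-level data are not public, so two stand-ins make every
stage of the pipeline testable:

* :func:`generate_cohort` draws random cohorts from the data-generating
  model the association analysis assumes — marginal demographics (age
  truncated-normal 65-103 around a mean of 82.2 years, ~58% female, CFS
  with mean ~5.1), sensory prevalences, and a logistic model for a fall in
  the past year whose sensory log-odds default to the adjusted coefficients
  the analysis estimates (hearing 0.68, dizziness 0.81, vision 0.33,
  balance 0.34). The intercept is calibrated numerically per cohort so the
  marginal fall rate hits its target (~0.57). Missingness is applied last,
  MCAR, at per-variable rates (falls history 8%, glasses 69%, hearing aids
  37%, mobility aids 1%, FRID reconciliation unavailable for ~76%).

* :func:`generate_fixture` builds, with no randomness at all, a 392-record
  cohort whose stratification-deciding fields realise the study's printed
  decision-path counts exactly (139 no-fall; 104 two-plus falls; 66 one
  fall + high frailty; 19 one fall, low frailty, balance issue; 10 one
  fall, low frailty, no balance issue; 54 with missing deciding data whose
  completions disagree), plus its printed faller total (223) and FRID
  exposure by risk group (17/23 low, 2/8 intermediate, 52/63 high, four
  patients on five or more FRIDs). Non-deciding fields are filled from
  deterministic cycles that approximate the printed marginals.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np
from scipy import optimize, special, stats

from .cohort_model import FallsCount, PatientRecord, TriState

_TRI = {True: TriState.YES, False: TriState.NO}


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration (raised before any sampling)."""


def _default_cfs_probs() -> tuple:
    # mean 5.11, mode 5; mild right tail up to 9 (terminally ill is rare in ED)
    return (0.02, 0.06, 0.12, 0.18, 0.20, 0.18, 0.14, 0.07, 0.03)


def _default_prevalence() -> dict:
    # vision loss and balance issues are the common impairments in this
    # setting (~2/3-3/4 of those assessed); hearing and dizziness rarer
    return {"vision": 0.70, "hearing": 0.45, "dizziness": 0.20, "balance": 0.72}


def _default_effects() -> dict:
    # adjusted log-odds of each sensory issue on a fall in the past year
    return {"hearing": 0.68, "dizziness": 0.81, "vision": 0.33, "balance": 0.34}


def _default_aid_probs() -> dict:
    # P(aid | impaired), P(aid | intact)
    return {"glasses": (0.60, 0.30), "hearing_aid": (0.70, 0.02),
            "mobility_aid": (0.72, 0.25)}


def _default_missingness() -> dict:
    # falls masks history and count jointly; frid masks use and count
    return {"falls": 0.08, "cfs": 0.04, "presented_with_fall": 0.008,
            "vision": 0.03, "hearing": 0.03, "dizziness": 0.03, "balance": 0.01,
            "glasses": 0.69, "hearing_aid": 0.37, "mobility_aid": 0.01,
            "frid": 0.76}


@dataclass
class SyntheticConfig:
    """Parameters of the cohort-generating model. Defaults are the study conditions."""

    n: int = 392
    seed: int = 0
    age_mean: float = 82.2
    age_sd: float = 8.0
    age_min: int = 65
    age_max: int = 103
    p_female: float = 0.578
    cfs_probs: tuple = field(default_factory=_default_cfs_probs)
    prevalence: dict = field(default_factory=_default_prevalence)
    effects: dict = field(default_factory=_default_effects)
    b_age: float = 0.02  # per year
    b_sex_male: float = -0.10
    b_frailty_high: float = 0.50
    target_fall_rate: float = 0.569
    p_two_plus_given_fall: float = 0.47
    p_frid: float = 0.65  # among non-fallers
    frid_effect: float = 1.15  # log-odds shift for fallers
    aid_probs: dict = field(default_factory=_default_aid_probs)
    missingness: dict = field(default_factory=_default_missingness)

    def validate(self) -> None:
        props = [self.p_female, self.target_fall_rate, self.p_two_plus_given_fall,
                 self.p_frid, *self.prevalence.values(), *self.missingness.values()]
        for pair in self.aid_probs.values():
            props.extend(pair)
        if any(not (0.0 <= p <= 1.0) for p in props):
            raise ConfigError("all proportions must lie in [0, 1]")
        if self.n < 0:
            raise ConfigError("cohort size must be non-negative")
        if len(self.cfs_probs) != 9 or abs(sum(self.cfs_probs) - 1.0) > 1e-9 \
                or any(p < 0 for p in self.cfs_probs):
            raise ConfigError("cfs_probs must be 9 non-negative values summing to 1")
        if not (self.age_min <= self.age_mean <= self.age_max) or self.age_sd <= 0:
            raise ConfigError("age bounds must be ordered around the mean, sd > 0")


# mask name -> record attributes it blanks; falls/frid mask coupled fields
# jointly so a masked value cannot be re-inferred from its partner
_MASKABLE = {
    "falls": ("fall_past_year", "falls_count_category"),
    "cfs": ("cfs",),
    "presented_with_fall": ("presented_with_fall",),
    "vision": ("vision_impaired",),
    "hearing": ("hearing_impaired",),
    "dizziness": ("dizziness",),
    "balance": ("balance_issue",),
    "glasses": ("glasses",),
    "hearing_aid": ("hearing_aid",),
    "mobility_aid": ("mobility_aid",),
    "frid": ("frid_use", "frid_count"),
}

_MISSING_VALUE = {
    "fall_past_year": TriState.MISSING, "falls_count_category": FallsCount.MISSING,
    "cfs": None, "presented_with_fall": TriState.MISSING,
    "vision_impaired": TriState.MISSING, "hearing_impaired": TriState.MISSING,
    "dizziness": TriState.MISSING, "balance_issue": TriState.MISSING,
    "glasses": TriState.MISSING, "hearing_aid": TriState.MISSING,
    "mobility_aid": TriState.MISSING, "frid_use": TriState.MISSING,
    "frid_count": None,
}


def apply_missingness(records: Sequence[PatientRecord], rates: dict,
                      seed: int) -> list:
    """Blank each maskable variable independently (MCAR) at its rate.

    Returns new records; the inputs are not modified. Reproducible by seed.
    """
    for name, rate in rates.items():
        if name not in _MASKABLE:
            raise ConfigError(f"unknown missingness variable {name!r}")
        if not (0.0 <= rate <= 1.0):
            raise ConfigError(f"missingness rate for {name!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(records)
    masks = {name: rng.random(n) < rate for name, rate in rates.items()}
    out = []
    for i, rec in enumerate(records):
        updates = {}
        for name, mask in masks.items():
            if mask[i]:
                for attr in _MASKABLE[name]:
                    updates[attr] = _MISSING_VALUE[attr]
        out.append(replace(rec, **updates) if updates else rec)
    return out


def _calibrate_intercept(linpred: np.ndarray, target: float) -> float:
    """Solve mean(expit(c + linpred)) = target for the intercept c."""
    def gap(c):
        return special.expit(c + linpred).mean() - target
    return float(optimize.brentq(gap, -30.0, 30.0, xtol=1e-10))


def generate_cohort(config: SyntheticConfig, seed: Union[int, None] = None) -> list:
    """Draw one random cohort from the configured data-generating model."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n

    a, b = ((config.age_min - config.age_mean) / config.age_sd,
            (config.age_max - config.age_mean) / config.age_sd)
    ages = stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                               size=n, random_state=rng)
    ages = np.clip(np.rint(ages), config.age_min, config.age_max).astype(int)
    female = rng.random(n) < config.p_female
    cfs = rng.choice(np.arange(1, 10), size=n, p=np.asarray(config.cfs_probs))

    sens = {k: rng.random(n) < p for k, p in config.prevalence.items()}
    frail_high = cfs >= 5

    linpred = (config.effects["hearing"] * sens["hearing"]
               + config.effects["dizziness"] * sens["dizziness"]
               + config.effects["vision"] * sens["vision"]
               + config.effects["balance"] * sens["balance"]
               + config.b_age * (ages - config.age_mean)
               + config.b_sex_male * (~female).astype(float)
               + config.b_frailty_high * frail_high.astype(float))
    if n > 0:
        intercept = _calibrate_intercept(linpred, config.target_fall_rate)
    else:
        intercept = 0.0
    fell = rng.random(n) < special.expit(intercept + linpred)
    two_plus = fell & (rng.random(n) < config.p_two_plus_given_fall)

    frid_p = special.expit(special.logit(np.clip(config.p_frid, 1e-9, 1 - 1e-9))
                           + config.frid_effect * fell.astype(float))
    frid = rng.random(n) < frid_p
    frid_counts = np.where(frid, rng.integers(1, 5, size=n), 0)

    aid_draw = {k: rng.random(n) for k in config.aid_probs}
    impair_for_aid = {"glasses": "vision", "hearing_aid": "hearing",
                      "mobility_aid": "balance"}

    records = []
    for i in range(n):
        aids = {}
        for aid, (p_imp, p_int) in config.aid_probs.items():
            p = p_imp if sens[impair_for_aid[aid]][i] else p_int
            aids[aid] = _TRI[bool(aid_draw[aid][i] < p)]
        records.append(PatientRecord(
            patient_id=f"s{i + 1:05d}",
            age=int(ages[i]),
            sex="female" if female[i] else "male",
            presented_with_fall=_TRI[bool(fell[i] and rng.random() < 0.55)],
            fall_past_year=_TRI[bool(fell[i])],
            falls_count_category=(FallsCount.TWO_PLUS if two_plus[i]
                                  else FallsCount.ONE if fell[i] else FallsCount.ZERO),
            cfs=int(cfs[i]),
            vision_impaired=_TRI[bool(sens["vision"][i])],
            hearing_impaired=_TRI[bool(sens["hearing"][i])],
            dizziness=_TRI[bool(sens["dizziness"][i])],
            balance_issue=_TRI[bool(sens["balance"][i])],
            glasses=aids["glasses"],
            hearing_aid=aids["hearing_aid"],
            mobility_aid=aids["mobility_aid"],
            frid_use=_TRI[bool(frid[i])],
            frid_count=int(frid_counts[i]),
        ))
    mask_seed = int(rng.integers(0, 2**31 - 1))
    return apply_missingness(records, config.missingness, mask_seed)


# ---------------------------------------------------------------------------
# Deterministic fixture

@dataclass(frozen=True)
class FixtureSpec:
    """The printed decision-path counts the fixture realises (sum 392)."""

    no_falls: int = 139
    one_fall_lowfrail_nobalance: int = 10
    one_fall_lowfrail_balance: int = 19
    one_fall_highfrail: int = 66
    two_plus_falls: int = 104
    undeterminable: int = 54

    @property
    def total(self) -> int:
        return (self.no_falls + self.one_fall_lowfrail_nobalance
                + self.one_fall_lowfrail_balance + self.one_fall_highfrail
                + self.two_plus_falls + self.undeterminable)


def _bresenham_flags(n: int, k: int, phase: int = 0) -> list:
    """Deterministic spread of exactly k True values over n slots."""
    return [((i + phase) * k) % n < k for i in range(n)] if n else []


def _cycle(values, i):
    return values[i % len(values)]


def _fixture_ages(n: int) -> list:
    """Deterministic ages: inner quantiles of the study's truncated normal."""
    a, b = (65 - 82.2) / 8.0, (103 - 82.2) / 8.0
    qs = (np.arange(n) + 0.5) / n
    ages = stats.truncnorm.ppf(qs, a, b, loc=82.2, scale=8.0)
    ages = np.clip(np.rint(ages), 65, 103).astype(int)
    ages[0], ages[-1] = 65, 103  # realise the printed range exactly
    return list(ages)


def generate_fixture(spec: FixtureSpec = FixtureSpec()) -> list:
    """Build the deterministic 392-record cohort matching the printed counts.

    Deciding fields are exact per decision path; the 54 undeterminable
    records split into 24 fallers with one fall but an unrecorded CFS
    (completions high vs low/intermediate disagree) and 30 with fall
    history itself unrecorded — which also realises the printed 223
    fallers. Non-deciding fields come from fixed cycles approximating the
    printed marginals; FRID data covers 94 records with the printed
    per-group exposure. No randomness anywhere.
    """
    if spec.total != 392:
        raise ConfigError(f"fixture path counts must sum to 392, got {spec.total}")

    # per-record deciding-field plans: (fall, count, cfs_pool, balance)
    plans = []
    lowfrail_cfs = (3, 4, 2, 4, 1, 3)
    highfrail_cfs = (5, 6, 7, 6, 5, 8, 6, 9, 5, 7)
    free_cfs = (4, 5, 6, 3, 7, 5, 6, 4, 8, 5, 2, 6)
    for _ in range(spec.no_falls):
        plans.append(("no", FallsCount.ZERO, free_cfs, None))
    for _ in range(spec.one_fall_lowfrail_nobalance):
        plans.append(("yes", FallsCount.ONE, lowfrail_cfs, TriState.NO))
    for _ in range(spec.one_fall_lowfrail_balance):
        plans.append(("yes", FallsCount.ONE, lowfrail_cfs, TriState.YES))
    for _ in range(spec.one_fall_highfrail):
        plans.append(("yes", FallsCount.ONE, highfrail_cfs, None))
    for _ in range(spec.two_plus_falls):
        plans.append(("yes", FallsCount.TWO_PLUS, free_cfs, None))
    n_na = spec.undeterminable
    n_na_fallers = min(24, n_na)  # one fall, CFS unrecorded -> completions disagree
    for _ in range(n_na_fallers):
        plans.append(("yes", FallsCount.ONE, None, TriState.NO))
    for _ in range(n_na - n_na_fallers):  # fall history itself unrecorded
        plans.append(("missing", FallsCount.MISSING, free_cfs, None))

    n = len(plans)
    ages_sorted = _fixture_ages(n)
    perm = [(i * 181) % n for i in range(n)]  # decorrelate age from path
    female_flags = _bresenham_flags(n, 227)
    vision_flags = _bresenham_flags(n, 274, phase=3)   # ~70% vision loss
    hearing_flags = _bresenham_flags(n, 176, phase=5)  # ~45% hearing loss
    dizzy_flags = _bresenham_flags(n, 78, phase=7)     # ~20% dizziness
    presented = [False] * n

    records = []
    balance_cycle = (TriState.YES, TriState.YES, TriState.NO)  # ~2/3 where free
    for i, (fall, count, cfs_pool, balance) in enumerate(plans):
        if balance is None:
            balance = _cycle(balance_cycle, i)
        cfs = None if cfs_pool is None else _cycle(cfs_pool, i)
        fall_tri = {"yes": TriState.YES, "no": TriState.NO,
                    "missing": TriState.MISSING}[fall]
        vision = _TRI[vision_flags[i]]
        hearing = _TRI[hearing_flags[i]]
        # aid coverage where impaired, with the study's missing-data burden:
        # glasses mostly unrecorded (69%), hearing aids 37%, mobility aids 1%
        if vision is TriState.YES:
            glasses = (TriState.MISSING if i % 10 < 7
                       else TriState.YES if i % 2 == 0 else TriState.NO)
        else:
            glasses = TriState.MISSING if i % 10 < 7 else TriState.NO
        if hearing is TriState.YES:
            hearing_aid = (TriState.MISSING if i % 8 < 3
                           else TriState.YES if i % 4 != 0 else TriState.NO)
        else:
            hearing_aid = TriState.MISSING if i % 8 < 3 else TriState.NO
        if balance is TriState.YES:
            mobility_aid = (TriState.MISSING if i % 100 == 50
                            else TriState.YES if i % 10 < 7 else TriState.NO)
        else:
            mobility_aid = TriState.MISSING if i % 100 == 50 else TriState.NO
        records.append(PatientRecord(
            patient_id=f"f{i + 1:03d}",
            age=int(ages_sorted[perm[i]]),
            sex="female" if female_flags[i] else "male",
            presented_with_fall=TriState.NO,  # overwritten below
            fall_past_year=fall_tri,
            falls_count_category=count,
            cfs=cfs,
            vision_impaired=vision,
            hearing_impaired=hearing,
            dizziness=_TRI[dizzy_flags[i]],
            balance_issue=balance,
            glasses=glasses,
            hearing_aid=hearing_aid,
            mobility_aid=mobility_aid,
            frid_use=TriState.MISSING,
            frid_count=None,
        ))

    records = _assign_presentation(records, spec)
    records = _assign_frid(records, spec)
    return records


def _assign_presentation(records: list, spec: FixtureSpec) -> list:
    """134 presented with a fall, 255 did not, 3 missing (printed totals)."""
    out = list(records)
    n_yes = 0
    # all two-plus fallers, then one-fall high-frailty records, presented with a fall
    for i, rec in enumerate(out):
        if n_yes >= 134:
            break
        if rec.falls_count_category is FallsCount.TWO_PLUS or (
                rec.falls_count_category is FallsCount.ONE
                and rec.cfs is not None and rec.cfs >= 5):
            out[i] = replace(rec, presented_with_fall=TriState.YES)
            n_yes += 1
    # three missing-presentation records among the undeterminable block
    n_missing = 0
    for i in range(len(out) - 1, -1, -1):
        if n_missing == 3:
            break
        if out[i].fall_past_year is TriState.MISSING:
            out[i] = replace(out[i], presented_with_fall=TriState.MISSING)
            n_missing += 1
    return out


def _assign_frid(records: list, spec: FixtureSpec) -> list:
    """FRID reconciliation for 94 records: 17/23 low, 2/8 intermediate, 52/63 high.

    Four patients (one low, three high, all FRID takers) are on five or more
    FRIDs.
    """
    from .stratification import PAPER_ADAPTED, RiskClass, classify

    out = list(records)
    targets = {  # risk class -> (n with data, n taking)
        RiskClass.LOW: (23, 17), RiskClass.INTERMEDIATE: (8, 2),
        RiskClass.HIGH: (63, 52)}
    five_plus_quota = {RiskClass.LOW: 1, RiskClass.HIGH: 3,
                       RiskClass.INTERMEDIATE: 0}
    by_class: dict = {}
    for i, rec in enumerate(out):
        by_class.setdefault(classify(rec, PAPER_ADAPTED).risk, []).append(i)
    for risk, (n_data, n_taking) in targets.items():
        idx = by_class.get(risk, [])
        if len(idx) < n_data:
            raise ConfigError(f"not enough {risk.value} records for FRID targets")
        # spread the reconciliation subsample across the class (and hence across
        # decision-path blocks) rather than taking a leading run
        flags = _bresenham_flags(len(idx), n_data)
        chosen = [i for i, keep in zip(idx, flags) if keep]
        counts = (1, 2, 3, 2, 1, 4)
        remaining_five_plus = five_plus_quota[risk]
        for j, i in enumerate(chosen):
            taking = j < n_taking
            if taking and remaining_five_plus > 0:
                count = 5 + (j % 2)
                remaining_five_plus -= 1
            elif taking:
                count = _cycle(counts, j)
            else:
                count = 0
            out[i] = replace(out[i], frid_use=_TRI[taking], frid_count=count)
    return out
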