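"""Adjusted logistic-regression associations between sensory variables and falls.

Each sensory variable (vision loss, hearing loss, dizziness, balance issues)
and FRID use is tested one at a time against a binary outcome — any fall in
the past year, or membership of the high- vs low-risk stratification group —
in a binomial logistic model that controls for age (years), sex and frailty
(CFS dichotomised low/high by default). Models are fitted by Newton-type
maximum likelihood; the per-term report carries the log-odds coefficient b,
its standard error, Wald z = b/SE with a two-sided normal p-value, and the
odds ratio exp(b). Model fit is summarised by Nagelkerke's pseudo-R².

Complete-case analysis throughout: a record missing the outcome, the
predictor, or any adjustment variable is dropped from that model only, and
the number dropped is reported (and logged) per model.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .cohort_model import FrailtyLevel, PatientRecord, TriState
from .stratification import (
    PAPER_ADAPTED,
    RiskAssignment,
    RiskClass,
    StratificationMode,
    stratify_cohort,
)

logger = logging.getLogger(__name__)

#: |coefficient| beyond which a fit is treated as (quasi-)separated
_SEPARATION_BOUND = 15.0
_MAX_ITER = 50
_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """Newton iterations did not converge within the iteration cap."""


class SeparationError(RuntimeError):
    """Outcome is (quasi-)perfectly separated; the MLE does not exist."""


class DegenerateDesignError(ValueError):
    """Design matrix rank-deficient after dropping constant columns."""


class InsufficientDataError(ValueError):
    """Complete-case sample smaller than the configured minimum."""


@dataclass(frozen=True)
class RegressionResult:
    """One fitted binomial logistic model.

    Arrays are aligned with ``terms``; ``ll1``/``ll0`` are the fitted and
    intercept-only log-likelihoods on the same complete-case sample.
    """

    terms: tuple
    coef: tuple
    se: tuple
    z: tuple
    p: tuple
    odds_ratio: tuple
    n_used: int
    ll1: float
    ll0: float
    nagelkerke_r2: float
    n_dropped: int = 0
    predictor: Union[str, None] = None
    lr_p_interaction: Union[float, None] = None

    def term(self, name: str) -> dict:
        i = self.terms.index(name)
        return {
            "term": name,
            "b": self.coef[i],
            "se": self.se[i],
            "z": self.z[i],
            "p": self.p[i],
            "or": self.odds_ratio[i],
            "or_2dp": round(self.odds_ratio[i], 2),
        }

    def predictor_row(self) -> dict:
        row = self.term(self.predictor)
        row.update(n_used=self.n_used, n_dropped=self.n_dropped,
                   nagelkerke_r2=self.nagelkerke_r2)
        return row


@dataclass(frozen=True)
class AssociationSpec:
    """One predictor-vs-outcome analysis, always adjusted for age, sex, frailty."""

    predictor: str  # vision | hearing | dizziness | balance | frid_use
    outcome: str  # fall_past_year | high_vs_low_risk
    adjustment: tuple = ("age", "sex", "frailty")
    interaction_with_age: bool = False
    frailty_as: str = "binary"  # "binary" (CFS 1-4 vs 5-9) or "cfs" (raw score)
    risk_contrast: str = "high_vs_low"  # or "high_vs_rest"
    min_n: int = 25

    def __post_init__(self):
        if self.predictor not in PREDICTOR_FIELDS:
            raise ValueError(f"unknown predictor {self.predictor!r}")
        if self.outcome not in ("fall_past_year", "high_vs_low_risk"):
            raise ValueError(f"unknown outcome {self.outcome!r}")


PREDICTOR_FIELDS = {
    "vision": "vision_impaired",
    "hearing": "hearing_impaired",
    "dizziness": "dizziness",
    "balance": "balance_issue",
    "frid_use": "frid_use",
}


def odds_ratio(b: float) -> float:
    """Odds ratio for a log-odds coefficient: exp(b)."""
    if not math.isfinite(b):
        raise ValueError(f"coefficient must be finite, got {b!r}")
    return math.exp(b)


def nagelkerke_r2(ll0: float, ll1: float, n: int) -> float:
    """Nagelkerke's pseudo-R²: Cox–Snell R² rescaled to a [0, 1] range.

    R²_CS = 1 − exp((2/n)(ℓ0 − ℓ1)); Nagelkerke divides by its maximum
    1 − exp((2/n) ℓ0), which is < 1 for a discrete outcome.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if ll1 < ll0 - 1e-8:
        raise ValueError(f"fitted log-likelihood {ll1} below null {ll0}")
    cox_snell = 1.0 - math.exp((2.0 / n) * (ll0 - ll1))
    max_cs = 1.0 - math.exp((2.0 / n) * ll0)
    if max_cs <= 0:  # degenerate outcome (all 0s or all 1s): ll0 == 0
        return 0.0
    return cox_snell / max_cs


def _null_loglik(y: np.ndarray) -> float:
    """Closed-form intercept-only binomial log-likelihood."""
    n, k = y.size, y.sum()
    if k == 0 or k == n:
        return 0.0
    p = k / n
    return float(k * math.log(p) + (n - k) * math.log(1.0 - p))


def fit_logistic(y, X) -> RegressionResult:
    """Fit a binomial logistic model by Newton-type maximum likelihood.

    ``X`` is a DataFrame of predictors that must include an intercept column
    named ``const``. Raises :class:`DegenerateDesignError` for constant or
    collinear columns, :class:`SeparationError` when the MLE diverges, and
    :class:`ConvergenceError` if the iteration cap is hit; a silent bad fit
    is never returned.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("outcome and design row counts differ")
    if "const" not in X.columns:
        raise ValueError("design must include an intercept column named 'const'")

    constant = [c for c in X.columns if c != "const" and X[c].nunique() <= 1]
    if constant:
        raise DegenerateDesignError(f"constant predictor column(s): {constant}")
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        raise DegenerateDesignError(
            f"design rank {rank} < {X.shape[1]} columns (collinear predictors)")

    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=_MAX_ITER,
                                     tol=_TOL, warn_convergence=False)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(f"perfect separation detected: {exc}") from exc
        except np.linalg.LinAlgError as exc:
            # singular observed information: quasi-separation or a degenerate
            # outcome/predictor pattern the rank check cannot see
            raise SeparationError(f"singular information matrix: {exc}") from exc

    params = np.asarray(res.params, dtype=float)
    grad = np.abs(res.model.score(res.params)).max()
    if np.abs(params).max() > _SEPARATION_BOUND and grad > 1e-4:
        raise SeparationError(
            f"coefficients diverging (max |b| = {np.abs(params).max():.1f}, "
            f"max |score| = {grad:.2g})")
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"no convergence in {_MAX_ITER} iterations")

    se = np.asarray(res.bse, dtype=float)
    zvals = params / se
    pvals = 2.0 * stats.norm.sf(np.abs(zvals))
    ll1 = float(res.llf)
    ll0 = _null_loglik(y)
    return RegressionResult(
        terms=tuple(X.columns),
        coef=tuple(params),
        se=tuple(se),
        z=tuple(zvals),
        p=tuple(pvals),
        odds_ratio=tuple(np.exp(params)),
        n_used=int(y.size),
        ll1=ll1,
        ll0=ll0,
        nagelkerke_r2=nagelkerke_r2(ll0, ll1, y.size),
    )


def _tri_to_num(t: TriState) -> float:
    return {TriState.YES: 1.0, TriState.NO: 0.0, TriState.MISSING: np.nan}[t]


def build_design(records: Sequence[PatientRecord], spec: AssociationSpec,
                 assignments: Union[Sequence[RiskAssignment], None] = None,
                 mode: StratificationMode = PAPER_ADAPTED) -> pd.DataFrame:
    """Complete-case outcome + design frame for one association model.

    For the risk-group outcome the default contrast is high (1) vs low (0),
    with intermediate and unclassifiable records excluded; ``high_vs_rest``
    keeps every classifiable record.
    """
    if spec.outcome == "high_vs_low_risk":
        if assignments is None:
            assignments = stratify_cohort(records, mode).assignments
        if len(assignments) != len(records):
            raise ValueError("records and assignments are misaligned")

    rows = []
    for i, rec in enumerate(records):
        if spec.outcome == "fall_past_year":
            y = _tri_to_num(rec.fall_past_year)
        else:
            risk = assignments[i].risk
            if spec.risk_contrast == "high_vs_low":
                y = {RiskClass.HIGH: 1.0, RiskClass.LOW: 0.0}.get(risk, np.nan)
            else:
                y = (np.nan if risk is RiskClass.UNCLASSIFIABLE
                     else float(risk is RiskClass.HIGH))
        pred = _tri_to_num(getattr(rec, PREDICTOR_FIELDS[spec.predictor]))
        age = np.nan if rec.age is None else float(rec.age)
        sex = {"female": 0.0, "male": 1.0}.get(rec.sex, np.nan)
        if spec.frailty_as == "cfs":
            frailty = np.nan if rec.cfs is None else float(rec.cfs)
        else:
            frailty = {FrailtyLevel.LOW: 0.0, FrailtyLevel.HIGH: 1.0,
                       FrailtyLevel.MISSING: np.nan}[rec.frailty]
        rows.append((y, pred, age, sex, frailty))

    df = pd.DataFrame(rows, columns=["outcome", spec.predictor, "age", "sex", "frailty"])
    keep = ["outcome", spec.predictor] + [a for a in spec.adjustment]
    return df[keep].dropna()


def run_association(records: Sequence[PatientRecord], spec: AssociationSpec,
                    assignments: Union[Sequence[RiskAssignment], None] = None,
                    mode: StratificationMode = PAPER_ADAPTED) -> RegressionResult:
    """Fit one adjusted sensory-association model on complete cases.

    Returns the full :class:`RegressionResult` (use ``predictor_row()`` for
    the reporting row). With ``interaction_with_age`` set, a predictor×age
    term is added and a likelihood-ratio p-value against the main-effects
    model is attached as ``lr_p_interaction``.
    """
    df = build_design(records, spec, assignments, mode)
    n_dropped = len(records) - len(df)
    if len(df) < spec.min_n:
        raise InsufficientDataError(
            f"{len(df)} complete cases < minimum {spec.min_n} "
            f"(predictor={spec.predictor}, outcome={spec.outcome})")
    logger.info("association %s~%s: %d complete cases, %d dropped",
                spec.outcome, spec.predictor, len(df), n_dropped)

    y = df.pop("outcome").to_numpy()
    X = sm.add_constant(df, has_constant="add")
    base = fit_logistic(y, X)
    lr_p = None
    result = base
    if spec.interaction_with_age:
        Xi = X.copy()
        Xi[f"{spec.predictor}:age"] = Xi[spec.predictor] * Xi["age"]
        full = fit_logistic(y, Xi)
        lr_stat = 2.0 * (full.ll1 - base.ll1)
        lr_p = float(stats.chi2.sf(max(lr_stat, 0.0), df=1))
        result = full

    return RegressionResult(
        terms=result.terms, coef=result.coef, se=result.se, z=result.z, p=result.p,
        odds_ratio=result.odds_ratio, n_used=result.n_used, ll1=result.ll1,
        ll0=result.ll0, nagelkerke_r2=result.nagelkerke_r2,
        n_dropped=n_dropped, predictor=spec.predictor, lr_p_interaction=lr_p)
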