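"""End-to-end analysis driver: parse -> validate -> stratify -> associate -> report.

``run_pipeline`` is a pure function of (input data, config, seed): reruns
produce identical reports apart from the timestamp in the provenance block.
JSON is the canonical output; the CSVs written by ``write_report`` are
derived views. Percentages are rounded only at serialisation.
"""
from __future__ import annotations

import csv
import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Union

from . import __version__
from .association import (
    AssociationSpec,
    ConvergenceError,
    DegenerateDesignError,
    InsufficientDataError,
    SeparationError,
    run_association,
)
from .cohort_model import (
    EmptyCohortError,
    parse_cohort,
    summarize_cohort,
    validate_record,
)
from .interventions import frid_summary, intervention_coverage
from .stratification import FULL_GUIDELINE, PAPER_ADAPTED, stratify_cohort
from .synthetic import SyntheticConfig, generate_cohort, generate_fixture

logger = logging.getLogger(__name__)

_MODES = {"paper_adapted": PAPER_ADAPTED, "full_guideline": FULL_GUIDELINE}

#: the study's analysis set: each sensory variable against both outcomes,
#: FRID against the risk grouping
DEFAULT_ASSOCIATIONS = tuple(
    [AssociationSpec(p, "fall_past_year") for p in ("vision", "hearing", "dizziness", "balance")]
    + [AssociationSpec(p, "high_vs_low_risk") for p in ("vision", "hearing", "dizziness",
                                                        "balance", "frid_use")]
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """What to analyse and how to report it."""

    input_path: Union[str, None] = None  # cohort CSV; or use source below
    source: str = "csv"  # csv | fixture | simulate
    simulate: Union[SyntheticConfig, None] = None
    mode: str = "paper_adapted"
    associations: tuple = DEFAULT_ASSOCIATIONS
    seed: Union[int, None] = None
    pct_decimals: int = 1
    or_decimals: int = 2
    strict_parse: bool = True

    def validate(self) -> None:
        if self.mode not in _MODES:
            raise PipelineError(f"config: unknown stratification mode {self.mode!r}")
        if self.pct_decimals < 0 or self.or_decimals < 0:
            raise PipelineError("config: rounding decimals must be >= 0")
        if self.source == "csv" and not self.input_path:
            raise PipelineError("config: csv source requires input_path")
        if self.source == "simulate":
            cfg = self.simulate or SyntheticConfig()
            if cfg.n <= 0:
                raise PipelineError("config: simulate requires a positive cohort size")


@dataclass
class AnalysisReport:
    """Everything the pipeline computed, plus provenance."""

    cohort_summary: dict
    violations: list
    stratification: dict
    associations: list
    coverage: list
    frid: dict
    complete_case_audit: list
    provenance: dict

    def to_json(self, **kwargs) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, **kwargs)


def _load_records(config: PipelineConfig) -> list:
    if config.source == "fixture":
        return generate_fixture()
    if config.source == "simulate":
        sim = config.simulate or SyntheticConfig()
        return generate_cohort(sim, seed=config.seed)
    return parse_cohort(config.input_path, strict=config.strict_parse)


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute all stages in order; any stage failure aborts with its stage named."""
    config.validate()
    t0 = time.strftime("%Y-%m-%dT%H:%M:%S")

    try:
        records = _load_records(config)
    except Exception as exc:
        raise PipelineError(f"load: {exc}") from exc
    if not records:
        raise PipelineError("load: empty cohort")

    violations = [dataclasses.asdict(v) for rec in records for v in validate_record(rec)]
    if violations:
        logger.warning("validation: %d invariant violations flagged", len(violations))

    try:
        summary = summarize_cohort(records)
    except EmptyCohortError as exc:
        raise PipelineError(f"summarize: {exc}") from exc

    mode = _MODES[config.mode]
    strat = stratify_cohort(records, mode)

    assoc_rows, audit = [], []
    for spec in config.associations:
        key = f"{spec.predictor}~{spec.outcome}"
        try:
            res = run_association(records, spec, strat.assignments, mode)
        except (InsufficientDataError, DegenerateDesignError, SeparationError,
                ConvergenceError) as exc:
            # data-driven fit failures are reported, not fatal: a cohort with no
            # variation in one predictor should not sink the other analyses
            logger.warning("association %s skipped: %s", key, exc)
            assoc_rows.append({"predictor": spec.predictor, "outcome": spec.outcome,
                               "skipped": str(exc)})
            continue
        except Exception as exc:
            raise PipelineError(f"associate[{key}]: {exc}") from exc
        row = res.predictor_row()
        row.update(outcome=spec.outcome,
                   odds_ratio_rounded=round(row["or"], config.or_decimals))
        assoc_rows.append(row)
        audit.append({"analysis": key, "n_input": len(records),
                      "n_excluded": res.n_dropped, "n_analysed": res.n_used})

    coverage = [c.to_dict() for c in intervention_coverage(records, strat.assignments)]
    frid = frid_summary(records, strat.assignments)

    return AnalysisReport(
        cohort_summary=summary.to_dict(),
        violations=violations,
        stratification={
            "mode": config.mode,
            "n_total": strat.n_total,
            "class_counts": strat.class_counts,
            "path_counts": strat.path_counts,
            "class_percentages": strat.rounded_percentages(config.pct_decimals),
        },
        associations=assoc_rows,
        coverage=coverage,
        frid={"per_class": [c.to_dict() for c in frid.per_class],
              "n_with_frid_data": frid.n_with_frid_data,
              "n_on_five_plus_frids": frid.n_on_five_plus_frids},
        complete_case_audit=audit,
        provenance={"version": __version__, "seed": config.seed, "mode": config.mode,
                    "source": config.source, "input_path": config.input_path,
                    "timestamp": t0},
    )


def _write_csv(path: Path, rows: list, columns: list) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, extrasaction="ignore",
                                lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)


def write_report(report: AnalysisReport, directory: Union[str, Path]) -> list:
    """Serialise the report: report.json plus derived CSV views.

    Emits report.json, stratification.csv, associations.csv,
    interventions.csv and waffle_counts.csv (the count matrix behind a
    waffle-style stratification plot) and returns the paths written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []

    p = directory / "report.json"
    p.write_text(report.to_json(), encoding="utf-8")
    paths.append(p)

    p = directory / "stratification.csv"
    rows = [{"risk_class": k, "count": v,
             "percentage": report.stratification["class_percentages"].get(k)}
            for k, v in report.stratification["class_counts"].items()]
    _write_csv(p, rows, ["risk_class", "count", "percentage"])
    paths.append(p)

    p = directory / "associations.csv"
    cols = ["predictor", "outcome", "n_used", "n_dropped", "b", "se", "z", "p",
            "or", "or_2dp", "nagelkerke_r2", "skipped"]
    _write_csv(p, report.associations, cols)
    paths.append(p)

    p = directory / "interventions.csv"
    rows = list(report.coverage)
    if report.frid["n_with_frid_data"] == 0:
        frid_rows = [{"risk": "ALL", "condition": "frid", "n_with_condition": 0,
                      "pct_aided": "NO_FRID_DATA"}]
    else:
        frid_rows = [{"risk": c["risk"], "condition": "frid",
                      "n_with_condition": c["n_with_frid_data"],
                      "n_aided": c["n_taking_frid"],
                      "pct_aided": c["pct_taking_frid"]}
                     for c in report.frid["per_class"]]
    _write_csv(p, rows + frid_rows,
               ["risk", "condition", "n_with_condition", "n_aided", "n_unaided",
                "n_missing_aid_data", "pct_aided"])
    paths.append(p)

    p = directory / "waffle_counts.csv"
    rows = [{"path": k, "count": v}
            for k, v in report.stratification["path_counts"].items()]
    _write_csv(p, rows, ["path", "count"])
    paths.append(p)
    return paths
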