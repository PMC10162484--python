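"""End-to-end runs and result serialization.

This is the textual equivalent of a monitoring dashboard: an evaluation run
writes, per cohort and recommendation,

- ``series.csv`` — per-day counts of applicable and adherent patients and
  the adherence fraction (the two time-series panels a dashboard would plot),
- ``day_results.csv`` — the per-patient per-day verdicts,
- ``leaf_results.csv`` — every criterion leaf verdict (plus the
  ``/admitted`` encounter gate), sufficient to reconstruct each day result
  by re-applying the boolean tree; this is the audit trail that lets a
  clinician review the raw basis of every decision,
- ``report.json`` — run metadata, the series, and summary statistics.

All machine output goes to files; logging goes to stderr.  Fractions are
serialized with six decimal places, and undefined fractions (no applicable
patients) as null (empty CSV field).
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical_data import CohortData, load_cohort, write_cohort
from .errors import SchemaError
from .evaluator import (
    DEFAULT_DOSE_TOLERANCE,
    EvaluationResult,
    EvaluationWindow,
    ExecutablePlan,
    compile,
    evaluate_cohort,
)
from .model import Recommendation, parse_recommendation, serialize_recommendation
from .synthetic import (
    COURSE_DAYS,
    GroundTruth,
    ScenarioConfig,
    dexamethasone_recommendation,
    generate,
)
from .terminology import CodeMap, identity_codemap, load_codemap

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """In-memory form of one evaluation run's outputs."""

    recommendation_id: str
    recommendation_version: str
    window: EvaluationWindow
    result: EvaluationResult
    config: dict
    tool_version: str
    timestamp: str


def _fmt_fraction(x: float) -> str:
    return "" if pd.isna(x) else f"{x:.6f}"


def _fmt_bool(b: bool) -> str:
    return "true" if b else "false"


def series_to_csv(series: pd.DataFrame, path: Path) -> None:
    out = pd.DataFrame(
        {
            "date": [str(d) for d in series["date"]],
            "n_applicable": series["n_applicable"].astype(int),
            "n_adherent": series["n_adherent"].astype(int),
            "fraction": [_fmt_fraction(x) for x in series["fraction"]],
        }
    )
    out.to_csv(path, index=False, lineterminator="\n")


def day_results_to_csv(day_results: pd.DataFrame, path: Path) -> None:
    out = day_results.copy()
    out["date"] = out["date"].map(str)
    for col in ("population_applicable", "intervention_fulfilled", "adherent"):
        out[col] = out[col].map(_fmt_bool)
    out.to_csv(path, index=False, lineterminator="\n")


def leaf_results_to_csv(leaf_results: pd.DataFrame, path: Path) -> None:
    out = leaf_results.copy()
    out["date"] = out["date"].map(str)
    out["result"] = out["result"].map(_fmt_bool)
    out.to_csv(path, index=False, lineterminator="\n")


def series_from_day_results(day_results: pd.DataFrame) -> pd.DataFrame:
    """Recount the cohort series from per-patient day results (consistency
    check used by the run report)."""
    grouped = day_results.groupby("date", sort=True)
    series = pd.DataFrame(
        {
            "date": list(grouped.groups.keys()),
            "n_applicable": grouped["population_applicable"].sum().astype(int).values,
            "n_adherent": grouped["adherent"].sum().astype(int).values,
        }
    )
    series["fraction"] = np.where(
        series["n_applicable"] > 0,
        series["n_adherent"] / series["n_applicable"].replace(0, np.nan),
        np.nan,
    )
    return series.reset_index(drop=True)


def patient_adherence_summary(
    day_results: pd.DataFrame,
    switch_date: _dt.date,
    course_days: int = COURSE_DAYS,
) -> pd.DataFrame:
    """Patient-level adherence classification per regime.

    A patient is *applicable* if they have at least one applicable day, and
    counted *adherent* if their number of adherent days reaches
    ``min(course_days, number of applicable days)`` — i.e. the recommended
    course covered every day it should have, given the length of stay.
    Patients are assigned to the before/after regime by their first
    applicable day relative to ``switch_date``.

    Returns one row per regime with columns ``regime, n_applicable,
    n_adherent, fraction``.
    """
    applicable = day_results[day_results["population_applicable"]]
    rows = []
    per_patient = applicable.groupby("person_id")
    summary = pd.DataFrame(
        {
            "applicable_days": per_patient.size(),
            "adherent_days": per_patient["adherent"].sum().astype(int),
            "first_day": per_patient["date"].min(),
        }
    )
    summary["threshold"] = summary["applicable_days"].clip(upper=course_days)
    summary["adherent_patient"] = summary["adherent_days"] >= summary["threshold"]
    summary["regime"] = np.where(
        summary["first_day"] < switch_date, "before", "after"
    )
    for regime in ("before", "after"):
        sub = summary[summary["regime"] == regime]
        n = int(len(sub))
        x = int(sub["adherent_patient"].sum())
        rows.append(
            {
                "regime": regime,
                "n_applicable": n,
                "n_adherent": x,
                "fraction": (x / n) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _series_json(series: pd.DataFrame) -> list[dict]:
    return [
        {
            "date": str(row.date),
            "n_applicable": int(row.n_applicable),
            "n_adherent": int(row.n_adherent),
            "fraction": None if pd.isna(row.fraction) else round(float(row.fraction), 6),
        }
        for row in series.itertuples()
    ]


def run_evaluation(
    recommendation_path: str | Path,
    cohort_dir: str | Path,
    codemap_path: Optional[str | Path],
    window: EvaluationWindow,
    out_dir: str | Path,
    strict_codes: bool = True,
    dose_tolerance: float = DEFAULT_DOSE_TOLERANCE,
) -> RunReport:
    """Run a full evaluation: load inputs, compile, evaluate, write outputs.

    All inputs are loaded and validated before any output file is written,
    so a validation failure leaves no partial outputs behind.
    """
    rec_text = Path(recommendation_path).read_text(encoding="utf-8")
    rec = parse_recommendation(rec_text)
    cohort = load_cohort(cohort_dir)
    if codemap_path is None:
        codemap = identity_codemap(strict=False)
    else:
        codemap = load_codemap(codemap_path, strict=strict_codes)
    plan = compile(rec, codemap, dose_tolerance=dose_tolerance)
    result = evaluate_cohort(plan, cohort, window, collect_leaves=True)

    recount = series_from_day_results(result.day_results)
    if not _series_equal(recount, result.series):
        raise AssertionError("internal error: series/day-results recount mismatch")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series_to_csv(result.series, out / "series.csv")
    day_results_to_csv(result.day_results, out / "day_results.csv")
    leaf_results_to_csv(result.leaf_results, out / "leaf_results.csv")

    config = {
        "recommendation": str(recommendation_path),
        "cohort": str(cohort_dir),
        "codemap": None if codemap_path is None else str(codemap_path),
        "start": str(window.start_date),
        "end": str(window.end_date),
        "strict_codes": strict_codes,
        "dose_tolerance": dose_tolerance,
    }
    timestamp = _dt.datetime.now().isoformat(timespec="seconds")
    report = {
        "recommendation_id": rec.id,
        "recommendation_version": rec.version,
        "window": {"start": str(window.start_date), "end": str(window.end_date)},
        "config": config,
        "tool_version": __version__,
        "timestamp": timestamp,
        "n_patients": int(len(cohort.persons)),
        "series": _series_json(result.series),
    }
    (out / "report.json").write_text(
        json.dumps(report, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )
    return RunReport(
        recommendation_id=rec.id,
        recommendation_version=rec.version,
        window=window,
        result=result,
        config=config,
        tool_version=__version__,
        timestamp=timestamp,
    )


def _series_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    a = a.sort_values("date").reset_index(drop=True)
    b = b.sort_values("date").reset_index(drop=True)
    if list(a["date"]) != list(b["date"]):
        return False
    return (
        list(a["n_applicable"]) == list(b["n_applicable"])
        and list(a["n_adherent"]) == list(b["n_adherent"])
    )


# ---------------------------------------------------------------------------
# Synthetic scenario runs
# ---------------------------------------------------------------------------

_SCENARIO_KEYS = {
    "n_patients": int,
    "start_date": _dt.date,
    "end_date": _dt.date,
    "p_population": float,
    "adherence_before": float,
    "adherence_after": float,
    "switch_date": _dt.date,
    "mean_stay_days": float,
    "seed": int,
}


def _parse_date(value, path: str) -> _dt.date:
    if isinstance(value, _dt.date) and not isinstance(value, _dt.datetime):
        return value
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise SchemaError(path, f"not an ISO date: {value!r}") from exc


def scenario_from_dict(data: dict) -> ScenarioConfig:
    """Build a ScenarioConfig from a parsed YAML/JSON mapping; unknown keys
    are a schema error located by path."""
    if not isinstance(data, dict):
        raise SchemaError("/", "scenario config must be a mapping")
    unknown = set(data) - set(_SCENARIO_KEYS)
    if unknown:
        raise SchemaError(f"/{sorted(unknown)[0]}", "unknown scenario field")
    kwargs: dict = {}
    for key, value in data.items():
        expected = _SCENARIO_KEYS[key]
        path = f"/{key}"
        if expected is _dt.date:
            value = _parse_date(value, path)
        else:
            try:
                value = expected(value)
            except (TypeError, ValueError) as exc:
                raise SchemaError(path, f"expected {expected.__name__}: {value!r}") from exc
        kwargs[key] = value
    start = kwargs.pop("start_date", None)
    end = kwargs.pop("end_date", None)
    if (start is None) != (end is None):
        raise SchemaError("/start_date", "start_date and end_date must be given together")
    if start is not None:
        try:
            kwargs["window"] = EvaluationWindow(start, end)
        except ValueError as exc:
            raise SchemaError("/end_date", str(exc)) from exc
    try:
        return ScenarioConfig(**kwargs)
    except ValueError as exc:
        raise SchemaError("/", str(exc)) from exc


def load_scenario(config_path: str | Path) -> ScenarioConfig:
    text = Path(config_path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    return scenario_from_dict(data if data is not None else {})


def write_ground_truth(truth: GroundTruth, path: Path) -> None:
    out = truth.table.copy()
    for col in ("episode_start", "course_start"):
        out[col] = out[col].map(lambda v: "" if v is None or pd.isna(v) else str(v))
    for col in ("population_member", "conformant"):
        out[col] = out[col].map(_fmt_bool)
    out.to_csv(path, index=False, lineterminator="\n")


def run_synthetic(
    config_path: str | Path,
    out_dir: str | Path,
    evaluate: bool = False,
) -> tuple[CohortData, GroundTruth]:
    """Generate a synthetic cohort from a scenario config file and write it
    out; optionally run the bundled recommendation evaluation on it."""
    config = load_scenario(config_path)
    cohort, truth = generate(config)
    out = Path(out_dir)
    cohort_dir = out / "cohort"
    write_cohort(cohort, cohort_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ground_truth(truth, out / "ground_truth.csv")
    rec = dexamethasone_recommendation()
    (out / "recommendation.json").write_text(serialize_recommendation(rec), encoding="utf-8")
    if evaluate:
        report = run_evaluation(
            out / "recommendation.json",
            cohort_dir,
            None,
            config.window,
            out / "evaluation",
        )
        summary = patient_adherence_summary(
            report.result.day_results, config.switch_date
        )
        summary_json = {
            "switch_date": str(config.switch_date),
            "regimes": [
                {
                    "regime": row.regime,
                    "n_applicable": int(row.n_applicable),
                    "n_adherent": int(row.n_adherent),
                    "fraction": None if pd.isna(row.fraction) else round(float(row.fraction), 6),
                }
                for row in summary.itertuples()
            ],
        }
        (out / "evaluation" / "regime_summary.json").write_text(
            json.dumps(summary_json, indent=2) + "\n", encoding="utf-8"
        )
    return cohort, truth
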