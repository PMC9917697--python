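"""Tabular I/O, validation, correlation and the end-to-end run pipeline.

The CSV dialect carries one patient per row: ``patient_id``, ``sex``,
``age``, ``diagnosis``, the echocardiographic feature columns, the
``approach`` label (repair|replacement) and optional ``adverse_event`` and
repair-technique columns.  Boolean flags are written 0/1; enum fields use
their lowercase names.  Unknown columns are preserved on round trip.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .cohort import (
    Approach,
    CohortConfig,
    Etiology,
    PatientRecord,
    cohort_summary,
    default_config,
    generate_cohort,
    load_config,
)
from .errors import DegenerateInputError, ValidationError
from .model import ModelConfig, train_eval
from .roc import analyze as roc_analyze
from .scoring import (
    DEFAULT_WEIGHTS,
    EchoFeatures,
    RepairTechniques,
    WeightTable,
    assign_stratum,
    complexity_score,
    technique_score,
)

__all__ = [
    "REQUIRED_COLUMNS",
    "records_to_frame",
    "write_cohort_csv",
    "validate_table",
    "correlate_scores",
    "run_pipeline",
    "RunManifest",
]

_FEATURE_COLUMNS = EchoFeatures.field_names()
REQUIRED_COLUMNS = ("patient_id", "sex", "age", "diagnosis", "approach") + _FEATURE_COLUMNS
_TECHNIQUE_COLUMNS = (
    "annuloplasty",
    "chordal_segments_resuspended",
    "cleft_closures",
    "leaflet_resections",
    "vegetation_removals",
    "commissurotomies",
    "re_repair",
    "ring_revision",
)
_BOOL_FEATURES = {c for c in _FEATURE_COLUMNS if c not in (
    "leaflet_morphology", "leaflet_motion", "vegetation_class", "perforation_cleft_class")}


def records_to_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flatten records into the CSV dialect, with derived ``complexity_score``,
    ``stratum`` and ``technique_score`` columns appended."""
    rows = []
    for r in cohort:
        row: dict = {
            "patient_id": r.patient_id,
            "sex": r.sex,
            "age": r.age,
            "diagnosis": r.diagnosis.value,
        }
        for name in _FEATURE_COLUMNS:
            value = getattr(r.features, name)
            row[name] = value.value if hasattr(value, "value") else int(value)
        row["approach"] = r.approach.value
        row["adverse_event"] = int(r.adverse_event)
        for name in _TECHNIQUE_COLUMNS:
            row[name] = (
                int(getattr(r.techniques, name)) if r.techniques is not None else ""
            )
        row["complexity_score"] = r.complexity.total
        row["stratum"] = r.stratum.value
        row["technique_score"] = r.technique_score if r.technique_score is not None else ""
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(cohort: Sequence[PatientRecord], path) -> None:
    records_to_frame(cohort).to_csv(path, index=False)


def _parse_bool(value, row: int, col: str) -> bool:
    if isinstance(value, str):
        value = value.strip().lower()
    if value in (0, "0", False, "false", "no"):
        return False
    if value in (1, "1", True, "true", "yes"):
        return True
    try:
        f = float(value)
        if f in (0.0, 1.0):
            return bool(f)
    except (TypeError, ValueError):
        pass
    raise ValidationError(f"row {row}: {col}: expected 0/1 boolean, got {value!r}", field=col)


def _parse_count(value, row: int, col: str) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}: {col}: expected a non-negative integer, got {value!r}", field=col
        ) from None
    if not f.is_integer() or f < 0:
        raise ValidationError(
            f"row {row}: {col}: expected a non-negative integer, got {value!r}", field=col
        )
    return int(f)


def _row_to_record(
    row: pd.Series, idx: int, weights: WeightTable
) -> PatientRecord:
    kwargs = {}
    for name in _FEATURE_COLUMNS:
        value = row[name]
        if name in _BOOL_FEATURES:
            kwargs[name] = _parse_bool(value, idx, name)
        elif name in ("vegetation_class", "perforation_cleft_class"):
            kwargs[name] = _parse_count(value, idx, name)
        else:
            kwargs[name] = str(value).strip().lower()
    try:
        features = EchoFeatures(**kwargs)
    except ValidationError as err:
        raise ValidationError(f"row {idx}: {err}", field=err.field) from None
    try:
        diagnosis = Etiology(str(row["diagnosis"]).strip().lower())
    except ValueError:
        raise ValidationError(
            f"row {idx}: diagnosis: unknown value {row['diagnosis']!r}", field="diagnosis"
        ) from None
    try:
        approach = Approach(str(row["approach"]).strip().lower())
    except ValueError:
        raise ValidationError(
            f"row {idx}: approach: unknown value {row['approach']!r}", field="approach"
        ) from None
    breakdown = complexity_score(features, weights)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stratum = assign_stratum(breakdown.total)
    adverse = False
    if "adverse_event" in row.index and str(row["adverse_event"]).strip() not in ("", "nan"):
        adverse = _parse_bool(row["adverse_event"], idx, "adverse_event")
        if approach is Approach.REPLACEMENT:
            adverse = False
    techniques = None
    tscore = None
    if approach is Approach.REPAIR and all(c in row.index for c in _TECHNIQUE_COLUMNS):
        cells = {c: row[c] for c in _TECHNIQUE_COLUMNS}
        if all(str(v).strip() not in ("", "nan") for v in cells.values()):
            tkwargs = {}
            for c in ("annuloplasty", "re_repair", "ring_revision"):
                tkwargs[c] = _parse_bool(cells[c], idx, c)
            for c in _TECHNIQUE_COLUMNS:
                if c not in tkwargs:
                    tkwargs[c] = _parse_count(cells[c], idx, c)
            try:
                techniques = RepairTechniques(**tkwargs)
            except ValidationError as err:
                raise ValidationError(f"row {idx}: {err}", field=err.field) from None
            tscore = technique_score(techniques)
    return PatientRecord(
        patient_id=str(row["patient_id"]),
        sex=str(row["sex"]),
        age=float(row["age"]),
        diagnosis=diagnosis,
        features=features,
        complexity=breakdown,
        stratum=stratum,
        approach=approach,
        adverse_event=adverse,
        techniques=techniques,
        technique_score=tscore,
    )


def validate_table(
    path, weights: WeightTable = DEFAULT_WEIGHTS
) -> tuple[list[PatientRecord], list[dict]]:
    """Parse a patient CSV into records, collecting row-indexed errors.

    Missing required columns fail immediately with a named error; row-level
    problems are collected (``{"row", "field", "message"}``) rather than
    aborting, and no row is silently dropped — every input row lands either
    in the record list or in the error report.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}", field=missing[0])
    records: list[PatientRecord] = []
    errors: list[dict] = []
    for idx, row in df.iterrows():
        try:
            records.append(_row_to_record(row, int(idx), weights))
        except ValidationError as err:
            errors.append({"row": int(idx), "field": err.field, "message": str(err)})
    return records, errors


def correlate_scores(
    complexity: Sequence[float],
    technique: Sequence[float],
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation between complexity and technique scores: ``r`` and the
    two-sided p-value (Pearson by default, ``method="spearman"`` for ranks)."""
    x = np.asarray(complexity, dtype=float)
    y = np.asarray(technique, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValidationError("inputs must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValidationError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero-variance input: correlation undefined")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown method {method!r}", field="method")
    return float(res.statistic), float(res.pvalue)


@dataclass
class RunManifest:
    """Provenance of one pipeline run: tool version, input digests, every
    config value and seed, timestamps and the ordered stage list."""

    version: str = __version__
    created: str = ""
    seeds: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)

    def add_input(self, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.input_digests[str(path)] = digest


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "value"):
        return obj.value
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _cv_to_dict(cv) -> dict:
    return {
        "fold_assignment": cv.fold_assignment.tolist(),
        "confusion_matrices": [m.tolist() for m in cv.confusion_matrices],
        "confusion_matrix_layout": "rows=true, cols=predicted, order=(repair, replacement)",
        "fold_accuracies": cv.fold_accuracies,
        "mean_accuracy": cv.mean_accuracy,
        "pooled_accuracy": cv.pooled_accuracy,
        "fold_importance_pct": [v.tolist() for v in cv.fold_importance],
        "aggregate_importance_pct": cv.aggregate_importance.tolist(),
        "feature_names": list(cv.feature_names),
    }


def run_pipeline(
    outdir,
    n_patients: int = 143,
    seed: int = 0,
    cohort_config_path=None,
    input_csv=None,
    weights: WeightTable = DEFAULT_WEIGHTS,
    model_config: ModelConfig | None = None,
    n_boot: int = 2000,
) -> dict:
    """Run simulate/load -> score -> ROC -> cross-validated model -> report.

    Returns the report bundle (also written under ``outdir`` as
    ``manifest.json``, ``cohort.csv``, ``report.json`` and ``report.md``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(created=time.strftime("%Y-%m-%dT%H:%M:%S"))
    manifest.seeds = {"cohort": seed, "bootstrap": seed, "model": 0}

    if input_csv is not None:
        manifest.add_input(input_csv)
        cohort, errors = validate_table(input_csv, weights)
        if errors:
            raise ValidationError(
                f"input table has {len(errors)} invalid rows; first: {errors[0]['message']}"
            )
        manifest.stages.append("load")
    else:
        if cohort_config_path is not None:
            manifest.add_input(cohort_config_path)
            config = load_config(cohort_config_path, n_patients=n_patients, seed=seed)
        else:
            config = default_config(n_patients=n_patients, seed=seed)
        from .cohort import config_to_dict

        manifest.config["cohort"] = config_to_dict(config)
        cohort = generate_cohort(config, weights)
        manifest.stages.append("simulate")

    write_cohort_csv(cohort, outdir / "cohort.csv")
    manifest.stages.append("score")

    summary = cohort_summary(cohort)
    scores = [r.complexity.total for r in cohort]
    labels = [int(r.approach is Approach.REPLACEMENT) for r in cohort]
    roc = roc_analyze(scores, labels, n_boot=n_boot, seed=seed)
    manifest.stages.append("roc")

    model_config = model_config or ModelConfig()
    manifest.config["model"] = asdict(model_config)
    cv = train_eval(cohort, model_config)
    manifest.stages.append("evaluate")

    repairs = [r for r in cohort if r.technique_score is not None]
    correlation = None
    if len(repairs) >= 3:
        c = [r.complexity.total for r in repairs]
        t = [r.technique_score for r in repairs]
        if np.ptp(c) > 0 and np.ptp(t) > 0:
            r_p, p_p = correlate_scores(c, t, "pearson")
            r_s, p_s = correlate_scores(c, t, "spearman")
            correlation = {
                "n_repairs": len(repairs),
                "pearson": {"r": r_p, "p": p_p},
                "spearman": {"r": r_s, "p": p_s},
            }
    manifest.stages.append("report")

    report = {
        "n_patients": len(cohort),
        "strata": summary["strata"].reset_index().to_dict(orient="records"),
        "etiology_by_stratum": summary["etiology_by_stratum"].to_dict(),
        "approach_by_stratum": summary["approach_by_stratum"].to_dict(),
        "roc": {
            "auc": roc.auc,
            "auc_ci": list(roc.auc_ci),
            "best_cutoff": roc.best_cutoff,
            "sens_at_cutoff": roc.sens_at_cutoff,
            "spec_at_cutoff": roc.spec_at_cutoff,
            "thresholds": roc.thresholds.tolist(),
            "sensitivity": roc.sensitivity.tolist(),
            "one_minus_specificity": roc.one_minus_specificity.tolist(),
        },
        "cv": _cv_to_dict(cv),
        "correlation": correlation,
    }
    bundle = {"manifest": asdict(manifest), "report": report}

    (outdir / "manifest.json").write_text(
        json.dumps(asdict(manifest), indent=2, default=_json_default)
    )
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, default=_json_default)
    )
    (outdir / "report.md").write_text(_report_markdown(report))
    return bundle


def _report_markdown(report: dict) -> str:
    lines = ["# Pipeline report", ""]
    lines.append(f"Patients: {report['n_patients']}")
    lines.append("")
    lines.append("## Complexity strata")
    lines.append("")
    lines.append("| stratum | n | % |")
    lines.append("|---|---|---|")
    for row in report["strata"]:
        lines.append(f"| {row['stratum']} | {row['n']} | {row['percent']} |")
    roc = report["roc"]
    lines += [
        "",
        "## ROC (complexity score vs replacement)",
        "",
        f"AUC {roc['auc']:.3f} (95% CI {roc['auc_ci'][0]:.3f}-{roc['auc_ci'][1]:.3f}); "
        f"Youden cutoff {roc['best_cutoff']:.1f} "
        f"(sens {roc['sens_at_cutoff']:.2f}, spec {roc['spec_at_cutoff']:.2f})",
        "",
        "## Cross-validated boosted classifier",
        "",
    ]
    cv = report["cv"]
    accs = ", ".join(f"{a:.3f}" for a in cv["fold_accuracies"])
    lines.append(
        f"Fold accuracies: {accs}; mean {cv['mean_accuracy']:.4f}; "
        f"pooled {cv['pooled_accuracy']:.4f}"
    )
    lines.append("")
    lines.append("Top aggregate importances (%):")
    pairs = sorted(
        zip(cv["feature_names"], cv["aggregate_importance_pct"]),
        key=lambda kv: -kv[1],
    )[:5]
    for name, pct in pairs:
        lines.append(f"- {name}: {pct:.2f}")
    if report["correlation"]:
        corr = report["correlation"]
        lines += [
            "",
            "## Technique-vs-complexity correlation (repairs)",
            "",
            f"n = {corr['n_repairs']}; Pearson r = {corr['pearson']['r']:.4f} "
            f"(p = {corr['pearson']['p']:.2e}); Spearman rho = {corr['spearman']['r']:.4f}",
        ]
    lines.append("")
    return "\n".join(lines)
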