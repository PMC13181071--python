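"""End-to-end fusion runs and machine-readable reports.

:func:`run_fuse` executes a set of fusion methods on one panel, optionally
optimizes the decision threshold, and assembles a JSON-serializable report
holding, per method, the metric block, the threshold, the decision margin
and the calibration pattern — a machine-readable analogue of a published
ensemble-comparison table. :func:`report_table` ranks methods across one or
more such reports.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import calibration, evaluation, fusion
from .errors import DataError, InvalidInputError
from .fusion import FusedScores, WeightVector
from .panel import ScorePanel

__all__ = [
    "classifier_performance",
    "run_fuse",
    "fused_frame",
    "write_report",
    "read_report",
    "report_table",
]

WEIGHT_SOURCES = ("accuracy", "auc", "f1")
METRIC_COLUMNS = (
    "accuracy",
    "precision",
    "recall",
    "specificity",
    "f1",
    "balanced_accuracy",
    "auc",
)


def classifier_performance(
    panel: ScorePanel, labels, source: str = "accuracy"
) -> np.ndarray:
    """Per-classifier performance scores at the 0.5 cut (weight/density input)."""
    if source not in WEIGHT_SOURCES:
        raise InvalidInputError(f"unknown weight source {source!r}")
    out = np.empty(panel.n_classifiers)
    for j in range(panel.n_classifiers):
        col = panel.probs[:, j]
        if source == "auc":
            out[j] = evaluation.roc_auc(labels, col)
        else:
            cm = evaluation.confusion(labels, evaluation.apply_threshold(col, 0.5))
            out[j] = getattr(evaluation.metrics_from_confusion(cm), source)
    return out


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_fuse(
    panel: ScorePanel,
    labels=None,
    methods=fusion.FUSION_METHODS,
    *,
    weight_source: str = "accuracy",
    densities=None,
    density_kind: str = "sub-unit",
    density_sum: float = 0.8,
    optimize: bool = True,
    objective: str = "f1",
    step: float = 0.01,
    tau: float = 0.5,
    vote_cut: float = 0.5,
):
    """Run fusion methods and build a report.

    Returns ``(report_dict, {method: FusedScores})``. With labels, each
    method gets metrics at its threshold (optimized on the label set when
    ``optimize`` is true, the methodologically safer route being a separate
    tuning split chosen by the caller), plus ROC-AUC, decision margin and
    separation pattern. Fuzzy densities default to performance-derived
    presets when not supplied explicitly.
    """
    methods = tuple(methods)
    for mth in methods:
        if mth not in fusion.FUSION_METHODS:
            raise InvalidInputError(f"unknown fusion method {mth!r}")

    weights = WeightVector.uniform(panel.n_classifiers)
    perf = None
    if labels is not None:
        perf = classifier_performance(panel, labels, weight_source)
        if perf.sum() > 0:
            weights = fusion.derive_weights(perf)
    measure = None
    if "choquet" in methods or "sugeno" in methods:
        if densities is None:
            base = perf if perf is not None and perf.sum() > 0 else np.ones(panel.n_classifiers)
            densities = fusion.density_preset(base, density_kind, density_sum)
        measure = fusion.build_lambda_measure(densities)

    report = {
        "n_samples": panel.n_samples,
        "n_classifiers": panel.n_classifiers,
        "classifier_ids": list(panel.classifier_ids),
        "weight_source": weight_source,
        "weights": weights.weights.tolist(),
        "methods": {},
    }
    if measure is not None:
        report["fuzzy_densities"] = np.asarray(densities, dtype=float).tolist()
        report["lambda"] = measure.lam

    fused_by_method = {}
    for mth in methods:
        fused = fusion.fuse(
            panel, mth, weights=weights, measure=measure, vote_cut=vote_cut
        )
        entry = {"method": mth}
        if labels is not None:
            if optimize:
                res = evaluation.optimize_threshold(labels, fused, objective, step)
                entry["tau"] = res.tau_star
                entry["threshold_objective"] = objective
                entry["threshold_optimized"] = True
            else:
                entry["tau"] = float(tau)
                entry["threshold_optimized"] = False
            fused = fused.with_threshold(entry["tau"])
            preds = evaluation.apply_threshold(fused, entry["tau"])
            cm = evaluation.confusion(labels, preds)
            auc = evaluation.roc_auc(labels, fused)
            entry["confusion"] = cm.to_array().tolist()
            entry["metrics"] = evaluation.metrics_from_confusion(cm, auc=auc).as_dict()
            entry["metrics_2dp"] = {
                k: round(v, 2) for k, v in entry["metrics"].items()
            }
            margin = calibration.decision_margin(fused, labels)
            entry["margin"] = margin
            entry["pattern"] = calibration.classify_separation(margin)
        fused_by_method[mth] = fused
        report["methods"][mth] = entry
    return report, fused_by_method


def fused_frame(fused_by_method: dict) -> pd.DataFrame:
    """Long-format ``sample_id, score, method`` frame for all fused outputs."""
    parts = []
    for mth in sorted(fused_by_method):
        fused = fused_by_method[mth]
        ids = fused.sample_ids or [f"s{i:06d}" for i in range(len(fused))]
        parts.append(
            pd.DataFrame(
                {"sample_id": list(ids), "score": fused.scores, "method": fused.method}
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_report(path, report: dict) -> None:
    """Serialize a report with sorted keys and 6-decimal floats (reproducible)."""
    with open(path, "w") as fh:
        json.dump(_round_floats(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    try:
        with open(path) as fh:
            report = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise DataError(f"cannot read report {path}: {exc}") from exc
    if "methods" not in report:
        raise DataError(f"{path} is not a fusion report")
    return report


def report_table(reports, metric: str = "accuracy") -> pd.DataFrame:
    """Rank all methods across reports by a metric (descending, ties by name)."""
    if metric not in METRIC_COLUMNS:
        raise InvalidInputError(f"unknown ranking metric {metric!r}")
    reports = list(reports)
    if not reports:
        raise InvalidInputError("need at least one report")
    rows = []
    for rep in reports:
        for mth, entry in rep["methods"].items():
            if "metrics" not in entry:
                raise InvalidInputError(f"report entry {mth!r} has no metrics")
            row = {"method": mth}
            for col in METRIC_COLUMNS:
                row[col] = entry["metrics"].get(col)
            row["tau"] = entry.get("tau")
            row["margin"] = entry.get("margin")
            row["pattern"] = entry.get("pattern")
            rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        [metric, "method"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
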