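"""Yield binarisation, classification metrics and cross-temperature scoring.

The positive class is ``High`` (yield >= 0.2 at the evaluated temperature;
the boundary value itself is High).  MCC is evaluated from the closed-form
contingency formula, AUROC from the mid-rank (trapezoidal tie) statistic on
the continuous predicted yields, so both are first-principles computations
rather than library calls.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

LABELS = ("Low", "High")
DEFAULT_THRESHOLD = 0.2


def binarise(yields: Sequence[float], threshold: float = DEFAULT_THRESHOLD
             ) -> list[str]:
    """Map yields to labels: below ``threshold`` is Low, otherwise High."""
    out = []
    for y in yields:
        if not 0.0 <= y <= 1.0:
            raise ValueError(f"yield out of [0, 1]: {y}")
        out.append("Low" if y < threshold else "High")
    return out


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class EvaluationReport:
    """Classification and regression summary for one evaluated set."""

    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    per_class: dict[str, ClassMetrics]
    mcc: float
    auroc: float | None
    auroc_missing_reason: str | None
    mse: float | None
    temperature: float | None
    fp_ids: frozenset[str] = frozenset()
    fn_ids: frozenset[str] = frozenset()
    ids: frozenset[str] = frozenset()

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_json(self) -> str:
        payload = asdict(self)
        for key in ("fp_ids", "fn_ids", "ids"):
            payload[key] = sorted(payload[key])
        return json.dumps(payload, indent=2)


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def mcc_from_counts(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient from the 2x2 contingency table."""
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def auroc_from_scores(truth: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the mid-rank Mann-Whitney statistic
    (ties contribute trapezoidally)."""
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes in the truth")
    ranks = rankdata(scores, method="average")
    return float((ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def classification_report(y_true, y_score,
                          threshold: float = DEFAULT_THRESHOLD,
                          y_true_continuous: Sequence[float] | None = None,
                          ids: Sequence[str] | None = None,
                          temperature: float | None = None
                          ) -> EvaluationReport:
    """Score predicted yields against truth after binarisation.

    ``y_true`` may be labels (``Low``/``High``) or continuous yields, which
    are binarised with the same threshold.  AUROC uses the continuous
    ``y_score`` directly; precision/recall/F1/MCC use the binarised
    predictions with High as the positive class.  MSE is reported when
    continuous truth is available.  When ``ids`` are given, the FP and FN
    id-sets are retained for overlap analysis.
    """
    y_true = list(y_true)
    if not y_true:
        raise ValueError("empty truth")
    y_score = np.asarray(y_score, dtype=float)
    if y_true_continuous is None and not isinstance(y_true[0], str):
        y_true_continuous = list(y_true)
    if isinstance(y_true[0], str):
        truth_labels = list(y_true)
        bad = set(truth_labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")
    else:
        truth_labels = binarise(y_true, threshold)
    truth = np.array([1 if lab == "High" else 0 for lab in truth_labels])
    if len(truth) != len(y_score):
        raise ValueError("truth and scores length mismatch")
    pred = (y_score >= threshold).astype(int)

    tp = int(((truth == 1) & (pred == 1)).sum())
    fp = int(((truth == 0) & (pred == 1)).sum())
    fn = int(((truth == 1) & (pred == 0)).sum())
    tn = int(((truth == 0) & (pred == 0)).sum())

    per_class = {}
    # High is positive; Low metrics come from the mirrored table
    for name, (tp_, fp_, fn_) in (("High", (tp, fp, fn)),
                                  ("Low", (tn, fn, fp))):
        precision = _safe_div(tp_, tp_ + fp_)
        recall = _safe_div(tp_, tp_ + fn_)
        f1 = _safe_div(2 * precision * recall, precision + recall)
        per_class[name] = ClassMetrics(precision, recall, f1)

    try:
        auroc = auroc_from_scores(truth, y_score)
        reason = None
    except ValueError as exc:
        auroc, reason = None, str(exc)

    mse = None
    if y_true_continuous is not None:
        mse = float(np.mean((np.asarray(y_true_continuous, dtype=float)
                             - y_score) ** 2))

    fp_ids = fn_ids = frozenset()
    all_ids = frozenset()
    if ids is not None:
        ids = list(ids)
        if len(ids) != len(truth):
            raise ValueError("ids length mismatch")
        fp_ids = frozenset(i for i, t, p in zip(ids, truth, pred)
                           if t == 0 and p == 1)
        fn_ids = frozenset(i for i, t, p in zip(ids, truth, pred)
                           if t == 1 and p == 0)
        all_ids = frozenset(ids)

    return EvaluationReport(threshold=threshold, tp=tp, fp=fp, fn=fn, tn=tn,
                            per_class=per_class,
                            mcc=mcc_from_counts(tp, fp, fn, tn),
                            auroc=auroc, auroc_missing_reason=reason,
                            mse=mse, temperature=temperature,
                            fp_ids=fp_ids, fn_ids=fn_ids, ids=all_ids)


@dataclass(frozen=True)
class ErrorOverlap:
    shared_fp: frozenset[str]
    unique_fp_a: frozenset[str]
    unique_fp_b: frozenset[str]
    shared_fn: frozenset[str]
    unique_fn_a: frozenset[str]
    unique_fn_b: frozenset[str]


def error_overlap(report_a: EvaluationReport,
                  report_b: EvaluationReport) -> ErrorOverlap:
    """Shared and unique false-positive / false-negative id-sets of two
    models evaluated over the same records."""
    if not report_a.ids or not report_b.ids:
        raise ValueError("both reports must carry record ids")
    if report_a.ids != report_b.ids:
        raise ValueError("reports cover different id sets")
    return ErrorOverlap(
        shared_fp=report_a.fp_ids & report_b.fp_ids,
        unique_fp_a=report_a.fp_ids - report_b.fp_ids,
        unique_fp_b=report_b.fp_ids - report_a.fp_ids,
        shared_fn=report_a.fn_ids & report_b.fn_ids,
        unique_fn_a=report_a.fn_ids - report_b.fn_ids,
        unique_fn_b=report_b.fn_ids - report_a.fn_ids,
    )


def write_report_table(reports: Sequence[EvaluationReport], path) -> None:
    """Dump a list of reports (e.g. one per temperature) as a TSV table
    with confusion counts and summary metrics."""
    import csv
    fields = ["temperature", "threshold", "tp", "fp", "fn", "tn",
              "mcc", "auroc", "mse",
              "precision_high", "recall_high", "f1_high",
              "precision_low", "recall_low", "f1_low"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields, delimiter="\t")
        writer.writeheader()
        for r in reports:
            writer.writerow({
                "temperature": r.temperature, "threshold": r.threshold,
                "tp": r.tp, "fp": r.fp, "fn": r.fn, "tn": r.tn,
                "mcc": f"{r.mcc:.6f}",
                "auroc": "" if r.auroc is None else f"{r.auroc:.6f}",
                "mse": "" if r.mse is None else f"{r.mse:.6f}",
                "precision_high": f"{r.per_class['High'].precision:.6f}",
                "recall_high": f"{r.per_class['High'].recall:.6f}",
                "f1_high": f"{r.per_class['High'].f1:.6f}",
                "precision_low": f"{r.per_class['Low'].precision:.6f}",
                "recall_low": f"{r.per_class['Low'].recall:.6f}",
                "f1_low": f"{r.per_class['Low'].f1:.6f}",
            })


def cross_temperature_eval(predictor, ds, temps,
                           split: str = "test",
                           threshold: float = DEFAULT_THRESHOLD,
                           batch_size: int = 512) -> list[EvaluationReport]:
    """Score one frozen model against the ground truth of each temperature.

    The model predicts once; per temperature the truth labels are re-derived
    from that temperature's yields, so the reports show how a predictor
    trained at one temperature transfers across the range.
    """
    temps = [float(t) for t in temps]
    if not temps:
        raise ValueError("temperature list must be non-empty")
    sub = ds.subset(split) if split and ds.splits else ds
    for t in temps:
        sub._check_temperature(t)
    pairs = [(r.seq_a, r.seq_b) for r in sub.records]
    ids = [r.pair_id for r in sub.records]
    scores = predictor.predict(pairs, batch_size=batch_size)
    return [classification_report(sub.yields_at(t), scores,
                                  threshold=threshold,
                                  y_true_continuous=sub.yields_at(t),
                                  ids=ids, temperature=t)
            for t in temps]
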