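"""Three-fold assessment of an extracted Q&A matrix.

1. accuracy and precision against gold annotations on a random record
   subset — accuracy is (TP+TN)/annotated, precision TP/(TP+FP) over
   positive predictions; a null prediction is incorrect for accuracy
   and is never a positive prediction;
2. null ratio over every cell of the full matrix;
3. time consumption, summarized per question and per record (reported,
   never asserted — it is hardware-bound).

Percentages follow the report conventions: accuracy/precision rounded
half-up to one decimal, ratios to two.  Macro averages are unweighted
over question columns; columns with no positive predictions have
undefined precision and are excluded from the macro precision mean
(micro averaging is available behind ``averaging="micro"``).
"""

from __future__ import annotations

import csv
import math
import random
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from ._util import pct, round_half_up
from .qa import QAMatrix
from .questions import QuestionTemplate

__all__ = [
    "SampleTooLarge",
    "NoAnnotations",
    "QuestionScore",
    "MacroSummary",
    "sample_subset",
    "score_question",
    "null_ratio",
    "macro_summary",
    "timing_summary",
    "evaluate",
    "load_gold",
    "write_gold",
]

NUMERIC_TOL = 1e-6


class SampleTooLarge(ValueError):
    pass


class NoAnnotations(ValueError):
    pass


@dataclass(frozen=True)
class QuestionScore:
    question_id: str
    n_annotated: int
    n_correct: int
    tp: int
    fp: int
    tn: int
    fn: int
    n_null: int

    @property
    def accuracy_pct(self) -> float:
        return pct(self.n_correct, self.n_annotated, 1)

    @property
    def precision_pct(self) -> float | None:
        if self.tp + self.fp == 0:
            return None  # undefined: no positive predictions
        return pct(self.tp, self.tp + self.fp, 1)


@dataclass(frozen=True)
class MacroSummary:
    mean_accuracy_pct: float
    mean_precision_pct: float | None
    mean_null_pct: float | None
    n_questions: int
    n_precision_defined: int


def sample_subset(record_ids: Sequence[str], n: int, seed: int) -> list[str]:
    """Uniform sample of records without replacement, canonical order."""
    if n > len(record_ids):
        raise SampleTooLarge(f"asked for {n} of {len(record_ids)} records")
    ordered = sorted(record_ids)
    if n == len(ordered):
        return ordered
    return sorted(random.Random(seed).sample(ordered, n))


def _is_correct(pred: object, gold: object, answer_type: str) -> bool:
    if pred is None:
        return False
    if answer_type == "numeric":
        try:
            return abs(float(pred) - float(gold)) <= NUMERIC_TOL
        except (TypeError, ValueError):
            return False
    return str(pred) == str(gold)


def score_question(
    predictions: Mapping[str, object],
    gold: Mapping[str, object],
    question: QuestionTemplate,
) -> QuestionScore:
    """Confusion-style metrics for one column over the annotated records.

    ``predictions`` and ``gold`` map record_id → value; only records
    present in ``gold`` are scored.  For non-binary questions TP/FP/
    TN/FN stay zero apart from the correct count; their precision is
    undefined.
    """
    annotated = [r for r in gold if r in predictions]
    if not annotated:
        raise NoAnnotations(f"no annotated records for {question.question_id}")
    correct = tp = fp = tn = fn = n_null = 0
    for rid in annotated:
        pred, g = predictions[rid], gold[rid]
        if pred is None:
            n_null += 1
        if _is_correct(pred, g, question.answer_type):
            correct += 1
        if question.answer_type == "binary":
            if pred == "positive":
                tp += g == "positive"
                fp += g != "positive"
            elif g == "positive":
                fn += 1  # predicted negative or null on a gold positive
            elif pred == "negative":
                tn += 1
    return QuestionScore(
        question_id=question.question_id,
        n_annotated=len(annotated),
        n_correct=correct,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        n_null=n_null,
    )


def null_ratio(values: Sequence[object]) -> tuple[float, float]:
    """(fraction, percent) of null cells in one complete column."""
    if not len(values):
        raise ValueError("empty column")
    n_null = sum(1 for v in values if v is None or (isinstance(v, float) and math.isnan(v)))
    return n_null / len(values), pct(n_null, len(values), 2)


def macro_summary(
    scores: Sequence[QuestionScore],
    null_pcts: Sequence[float] | None = None,
    averaging: str = "macro",
) -> MacroSummary:
    """Unweighted means over question columns (or pooled micro counts).

    ``null_pcts`` are per-column null percentages over the *full*
    matrix (they come from a different denominator than the annotated
    subset, so they are passed in separately).
    """
    if not scores:
        raise ValueError("no question scores")
    if averaging == "macro":
        mean_acc = round_half_up(sum(s.accuracy_pct for s in scores) / len(scores), 2)
        defined = [s.precision_pct for s in scores if s.precision_pct is not None]
        mean_prec = round_half_up(sum(defined) / len(defined), 2) if defined else None
    elif averaging == "micro":
        mean_acc = pct(sum(s.n_correct for s in scores), sum(s.n_annotated for s in scores), 2)
        tp, fp = sum(s.tp for s in scores), sum(s.fp for s in scores)
        mean_prec = pct(tp, tp + fp, 2) if tp + fp else None
    else:
        raise ValueError("averaging must be 'macro' or 'micro'")
    mean_null = round_half_up(sum(null_pcts) / len(null_pcts), 2) if null_pcts else None
    defined_n = sum(1 for s in scores if s.precision_pct is not None)
    return MacroSummary(mean_acc, mean_prec, mean_null, len(scores), defined_n)


def timing_summary(latencies: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-question and per-record latency distributions (seconds)."""
    if latencies.empty:
        return {"per_question": pd.DataFrame(), "per_record": pd.DataFrame()}

    def describe(df: pd.DataFrame, axis: int) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": df.mean(axis=axis),
                "median": df.median(axis=axis),
                "q25": df.quantile(0.25, axis=axis),
                "q75": df.quantile(0.75, axis=axis),
            }
        )

    return {"per_question": describe(latencies, 0), "per_record": describe(latencies, 1)}


def evaluate(
    matrix: QAMatrix,
    gold: Mapping[tuple[str, str], object],
    subset_ids: Sequence[str] | None = None,
    averaging: str = "macro",
) -> dict:
    """Full three-fold report for one matrix against gold annotations.

    Returns per-question scores, per-question null percentages over the
    complete matrix, the macro summary, and timing distributions.
    """
    scores: list[QuestionScore] = []
    null_pcts: list[float] = []
    per_null: dict[str, float] = {}
    subset = set(subset_ids) if subset_ids is not None else None
    for q in matrix.questions:
        column = matrix.column(q.question_id)
        preds = {a.record_id: a.value for a in column}
        qgold = {
            rid: gold[(rid, q.question_id)]
            for rid in matrix.record_ids
            if (rid, q.question_id) in gold and (subset is None or rid in subset)
        }
        if qgold:
            scores.append(score_question(preds, qgold, q))
        _, npct = null_ratio([a.value for a in column])
        null_pcts.append(npct)
        per_null[q.question_id] = npct
    summary = macro_summary(scores, null_pcts, averaging=averaging) if scores else None
    return {
        "per_question": scores,
        "null_pct": per_null,
        "macro": summary,
        "timing": timing_summary(matrix.latency_frame()),
    }


def load_gold(path) -> dict[tuple[str, str], object]:
    """Gold CSV (record_id, question_id, gold_value); numeric strings
    are parsed to floats."""
    gold: dict[tuple[str, str], object] = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            key = (row["record_id"], row["question_id"])
            if key in gold:
                raise ValueError(f"duplicate gold annotation for {key}")
            v = row["gold_value"]
            if v in ("positive", "negative"):
                gold[key] = v
            else:
                try:
                    gold[key] = float(v)
                except ValueError:
                    gold[key] = v
    return gold


def write_gold(gold: Mapping[tuple[str, str], object], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "question_id", "gold_value"])
        for (rid, qid), v in gold.items():
            w.writerow([rid, qid, v])


def write_report(report: dict, metrics_path, table_path=None, matrix: QAMatrix | None = None) -> None:
    """Metrics CSV (per question: accuracy%, precision%, counts, null%)
    and optionally a ratio table mirroring the column summaries."""
    with open(metrics_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["question_id", "n_annotated", "accuracy_pct", "precision_pct",
             "tp", "fp", "tn", "fn", "n_null", "null_pct_full_matrix"]
        )
        for s in report["per_question"]:
            w.writerow(
                [s.question_id, s.n_annotated, s.accuracy_pct,
                 "" if s.precision_pct is None else s.precision_pct,
                 s.tp, s.fp, s.tn, s.fn, s.n_null,
                 report["null_pct"].get(s.question_id, "")]
            )
    if table_path is not None and matrix is not None:
        from .qa import column_summary

        with open(table_path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["question_id", "positive_or_mean", "negative_or_sd", "null_pct"])
            for qid in matrix.question_ids:
                a, b, c = column_summary(matrix, qid)
                w.writerow([qid, a, b, c])
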