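"""Q&A scale extraction: from snippets to the records × questions matrix.

Each matrix cell is one backend call: the Q&A prompt rendered over the
pre-extracted snippet (default max_tokens 20, concurrency 3).  The raw
completion is kept verbatim and normalized into the cell vocabulary —
``positive`` / ``negative`` / ``null`` for binary questions, a parsed
number for numeric questions, trimmed free text for categorical ones.
A cell is null when null-detection fires on the raw output (empty,
symbols-only, or gibberish) or when normalization finds no decisive
token.  The matrix is always complete: backend failures become null
cells carrying an error note, never an aborted run.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from ._util import pct, round_half_up
from .corpus import AdmissionRecord, Snippet
from .gateway import Backend, BatchFailure, ChatMessage, GenerationParams, chat_batch
from .prompts import PromptTemplate, default_templates, render
from .questions import QuestionTemplate

__all__ = [
    "QAnswer",
    "QAMatrix",
    "UnknownQuestion",
    "detect_null",
    "normalize",
    "run_matrix",
    "column_summary",
]

NULL = "null"

_MEANINGFUL = re.compile(r"[0-9A-Za-z一-鿿㐀-䶿]")
_REPEAT = re.compile(r"(.)\1{7,}")
_NUMBER = re.compile(r"[-+]?\d+(?:\.\d+)?")
_LATIN_TOKEN = re.compile(r"[a-z]+")


class UnknownQuestion(KeyError):
    pass


@dataclass(frozen=True)
class QAnswer:
    record_id: str
    question_id: str
    raw: str
    value: object  # "positive" | "negative" | float | str | None (null)
    latency: float
    error: str | None = None

    @property
    def is_null(self) -> bool:
        return self.value is None


def detect_null(raw: str, max_chars: int | None = None) -> bool:
    """Empty or meaningless output (symbols and gibberish) → null.

    Fires when the trimmed text is empty; contains no letter, digit or
    CJK character; a single character repeats eight or more times in a
    row; or the text overruns ``max_chars`` (a max_tokens-implied bound)
    without any recognizable content.
    """
    trimmed = (raw or "").strip()
    if not trimmed:
        return True
    if not _MEANINGFUL.search(trimmed):
        return True
    if _REPEAT.search(trimmed):
        return True
    if max_chars is not None and len(trimmed) > max_chars:
        return True
    return False


def _match_binary(raw: str, question: QuestionTemplate) -> str | None:
    """Decisive-token match: earliest occurrence wins, longer tokens
    beat shorter at the same position ("没有" before "有"), positive
    before negative as the final tie-break.  Latin tokens match on word
    boundaries, case-folded; CJK tokens as substrings."""
    hay = raw.casefold()
    best: tuple[int, int, int, str] | None = None
    for rank, (tokens, value) in enumerate(
        [(question.positive_tokens, "positive"), (question.negative_tokens, "negative")]
    ):
        for token in tokens:
            t = token.casefold()
            if _LATIN_TOKEN.fullmatch(t):
                m = re.search(rf"\b{re.escape(t)}\b", hay)
                pos = m.start() if m else -1
            else:
                pos = hay.find(t)
            if pos >= 0:
                cand = (pos, -len(t), rank, value)
                if best is None or cand < best:
                    best = cand
    return best[3] if best else None


def normalize(raw: str, question: QuestionTemplate) -> object:
    """Normalize a non-null raw answer into the cell vocabulary.

    binary      → positive/negative by decisive-token match, else null;
    numeric     → first decimal number, unit-stripped, else null;
    categorical → trimmed raw text (empty → null).
    """
    text = (raw or "").strip()
    if question.answer_type == "binary":
        return _match_binary(text, question)
    if question.answer_type == "numeric":
        m = _NUMBER.search(text)
        if not m:
            return None
        value = float(m.group())
        return value if math.isfinite(value) else None
    return text or None


@dataclass
class QAMatrix:
    """The 2-D Q&A scale: a complete (record × question) grid."""

    record_ids: list[str]
    questions: list[QuestionTemplate]
    cells: dict[tuple[str, str], QAnswer]

    def __post_init__(self):
        expected = {(r, q.question_id) for r in self.record_ids for q in self.questions}
        if set(self.cells) != expected:
            raise ValueError("matrix cells incomplete or carrying extra keys")

    @property
    def question_ids(self) -> list[str]:
        return [q.question_id for q in self.questions]

    def question(self, question_id: str) -> QuestionTemplate:
        for q in self.questions:
            if q.question_id == question_id:
                return q
        raise UnknownQuestion(question_id)

    def column(self, question_id: str) -> list[QAnswer]:
        self.question(question_id)
        return [self.cells[(r, question_id)] for r in self.record_ids]

    def values_frame(self) -> pd.DataFrame:
        """Normalized values, records × questions; null cells are None."""
        data = {
            qid: [self.cells[(r, qid)].value for r in self.record_ids]
            for qid in self.question_ids
        }
        return pd.DataFrame(data, index=pd.Index(self.record_ids, name="record_id"), dtype=object)

    def latency_frame(self) -> pd.DataFrame:
        data = {
            qid: [self.cells[(r, qid)].latency for r in self.record_ids]
            for qid in self.question_ids
        }
        return pd.DataFrame(data, index=pd.Index(self.record_ids, name="record_id"))

    def to_csv(self, path, latency_path=None) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["record_id"] + self.question_ids)
            for r in self.record_ids:
                row = [r]
                for qid in self.question_ids:
                    v = self.cells[(r, qid)].value
                    row.append(NULL if v is None else str(v))
                w.writerow(row)
        if latency_path is not None:
            self.latency_frame().to_csv(latency_path)


def _cell_messages(
    question: QuestionTemplate,
    context_text: str,
    template: PromptTemplate,
) -> list[ChatMessage]:
    return render(template, {"snippet": context_text, "question": question.question_text})


def run_matrix(
    records: Sequence[AdmissionRecord],
    questions: Sequence[QuestionTemplate],
    snippets: Mapping[tuple[str, str], Snippet] | None,
    backend: Backend,
    params: GenerationParams | None = None,
    concurrency: int = 3,
    template: PromptTemplate | None = None,
    empty_context_policy: str = "negative_by_absence",
    full_text: bool = False,
    existing: Mapping[tuple[str, str], QAnswer] | None = None,
    on_answer=None,
) -> QAMatrix:
    """Query the backend once per (record, question) cell.

    ``full_text=True`` skips pre-extraction and asks every question over
    the whole record — the ablation mode.  Empty-context cells follow
    ``empty_context_policy``: ``negative_by_absence`` answers binary
    questions negative without a call (unmentioned findings are absent
    by clinical convention) and nulls the rest; ``full_text`` falls back
    to asking over the complete record.  ``existing`` cells (from a
    resumed run) are reused verbatim.
    """
    params = params or GenerationParams(max_tokens=20)
    template = template or default_templates()["qa_extraction"]
    if snippets is None and not full_text:
        raise ValueError("snippets are required unless full_text=True")
    by_record = {r.record_id: r for r in records}
    existing = dict(existing or {})

    jobs: list[tuple[tuple[str, str], list[ChatMessage]]] = []
    direct: dict[tuple[str, str], QAnswer] = {}
    for r in records:
        for q in questions:
            cell = (r.record_id, q.question_id)
            if cell in existing:
                direct[cell] = existing[cell]
                continue
            if full_text:
                context = r.full_text()
            else:
                snip = snippets.get(cell)
                if snip is None:
                    raise KeyError(f"missing snippet for {cell}")
                context = snip.text()
                if snip.is_empty:
                    if empty_context_policy == "full_text":
                        context = r.full_text()
                    else:
                        value = "negative" if q.answer_type == "binary" else None
                        direct[cell] = QAnswer(r.record_id, q.question_id, raw="", value=value, latency=0.0)
                        continue
            jobs.append((cell, _cell_messages(q, context, template)))

    q_by_id = {q.question_id: q for q in questions}
    cells: dict[tuple[str, str], QAnswer] = dict(direct)

    def handle(cell, outcome) -> None:
        rid, qid = cell
        q = q_by_id[qid]
        if isinstance(outcome, BatchFailure):
            answer = QAnswer(rid, qid, raw="", value=None, latency=0.0, error=outcome.error)
        else:
            raw = outcome.text
            value = None if detect_null(raw) else normalize(raw, q)
            answer = QAnswer(rid, qid, raw=raw, value=value, latency=outcome.latency)
        cells[cell] = answer
        if on_answer is not None:
            on_answer(answer)  # streamed as completed, enabling resume files

    chat_batch(backend, jobs, params, concurrency=concurrency, on_result=handle)
    return QAMatrix([r.record_id for r in records], list(questions), cells)


def column_summary(matrix: QAMatrix, question_id: str):
    """Table-style column summary.

    Binary columns → (positive%, negative%, null%) over *all* records,
    rounded half-up to two decimals (they sum to 100 within rounding;
    null is exclusive of the other two).  Numeric columns → (mean, SD,
    null%) with mean/SD over non-null cells (sample SD).
    """
    q = matrix.question(question_id)
    answers = matrix.column(question_id)
    n = len(answers)
    n_null = sum(a.is_null for a in answers)
    if q.answer_type == "binary":
        n_pos = sum(a.value == "positive" for a in answers)
        n_neg = sum(a.value == "negative" for a in answers)
        return (pct(n_pos, n), pct(n_neg, n), pct(n_null, n))
    if q.answer_type == "numeric":
        values = [float(a.value) for a in answers if not a.is_null]
        if values:
            s = pd.Series(values, dtype=float)
            mean = round_half_up(float(s.mean()), 2)
            sd = round_half_up(float(s.std(ddof=1)), 2) if len(values) > 1 else 0.0
        else:
            mean = sd = float("nan")
        return (mean, sd, pct(n_null, n))
    # categorical: no ratio semantics beyond the null share
    return (None, None, pct(n_null, n))
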