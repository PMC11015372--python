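"""Question templates: concepts recast as per-record questions.

A backend drafts one question per retained concept; deterministic
expert-refinement overrides then fix wording, answer type and anchors.
The answer type is inferred from a concept category map rather than
from the model so the final matrix schema is deterministic: history /
symptom / intervention concepts become binary questions, quantity
concepts numeric, descriptive concepts categorical.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .concepts import ConceptTerm
from .gateway import Backend, BackendError, GenerationParams, chat
from .prompts import PromptTemplate, render

__all__ = [
    "QuestionTemplate",
    "UnknownQuestionId",
    "generate_questions",
    "apply_refinements",
    "questions_to_csv",
    "questions_from_csv",
]

ANSWER_TYPES = ("binary", "numeric", "categorical")

# default decisive tokens for binary answers; CJK tokens match as
# substrings, Latin tokens on word boundaries (see qa.normalize)
DEFAULT_POSITIVE_TOKENS = ("有", "是", "阳性", "yes", "y", "positive", "present")
DEFAULT_NEGATIVE_TOKENS = ("没有", "无", "否认", "否", "未", "不", "阴性", "no", "negative", "absent", "none")

CATEGORY_TO_ANSWER_TYPE = {
    "history": "binary",
    "symptom": "binary",
    "intervention": "binary",
    "examination": "binary",
    "quantity": "numeric",
    "descriptive": "categorical",
}

PLACEHOLDER_PREFIX = "[NEEDS CURATION]"


class UnknownQuestionId(KeyError):
    pass


@dataclass(frozen=True)
class QuestionTemplate:
    """One matrix column: a concept phrased as a question.

    anchors are section names or keywords driving position-based corpus
    pre-extraction; empty anchors fall back to concept-sentence matching
    only.  Binary questions always carry decisive positive/negative
    token lists.
    """

    question_id: str
    concept_label: str
    question_text: str
    answer_type: str = "binary"
    anchors: tuple[str, ...] = ()
    synonyms: tuple[str, ...] = ()
    positive_tokens: tuple[str, ...] = DEFAULT_POSITIVE_TOKENS
    negative_tokens: tuple[str, ...] = DEFAULT_NEGATIVE_TOKENS

    def __post_init__(self):
        if self.answer_type not in ANSWER_TYPES:
            raise ValueError(f"unknown answer_type {self.answer_type!r}")
        if not self.question_text:
            raise ValueError("question_text must be non-empty")
        if not self.synonyms:
            object.__setattr__(self, "synonyms", (self.concept_label,))
        if self.answer_type == "binary" and not (self.positive_tokens and self.negative_tokens):
            raise ValueError("binary questions need positive and negative token lists")


def _question_id(label: str, taken: set[str]) -> str:
    base = "q_" + "".join(ch if ch.isalnum() else "_" for ch in label.strip().lower()).strip("_")
    qid, i = base, 1
    while qid in taken:
        i += 1
        qid = f"{base}_{i}"
    taken.add(qid)
    return qid


def generate_questions(
    concepts: Sequence[ConceptTerm],
    backend: Backend,
    template: PromptTemplate,
    params: GenerationParams | None = None,
    category_map: Mapping[str, str] | None = None,
    anchors_map: Mapping[str, Sequence[str]] | None = None,
) -> list[QuestionTemplate]:
    """Draft one question per concept via the backend.

    A per-concept backend failure yields a placeholder draft flagged for
    curation instead of aborting the run.  ``category_map`` assigns each
    concept label a category (symptom/history/.../quantity/descriptive)
    which fixes the answer type; unlisted concepts default to binary.
    """
    params = params or GenerationParams(max_tokens=60)
    category_map = category_map or {}
    anchors_map = anchors_map or {}
    taken: set[str] = set()
    drafts: list[QuestionTemplate] = []
    for concept in concepts:
        messages = render(template, {"concept": concept.label})
        try:
            completion = chat(backend, messages, params, key=(concept.label, "__question__"))
            text = completion.text.strip() or f"{PLACEHOLDER_PREFIX} {concept.label}"
        except BackendError:
            text = f"{PLACEHOLDER_PREFIX} {concept.label}"
        category = category_map.get(concept.label, "symptom")
        drafts.append(
            QuestionTemplate(
                question_id=_question_id(concept.label, taken),
                concept_label=concept.label,
                question_text=text,
                answer_type=CATEGORY_TO_ANSWER_TYPE.get(category, "binary"),
                anchors=tuple(anchors_map.get(concept.label, ())),
                synonyms=concept.synonyms,
            )
        )
    return drafts


def apply_refinements(
    drafts: Sequence[QuestionTemplate],
    refinements: Mapping[str, Mapping[str, object]],
) -> list[QuestionTemplate]:
    """Deterministically overwrite drafts with curated refinements.

    ``refinements`` maps question_id → fields to replace
    (question_text / answer_type / anchors / synonyms / token lists).
    Unreferenced drafts pass through unchanged; a refinement naming an
    unknown id raises :class:`UnknownQuestionId`.
    """
    by_id = {d.question_id: d for d in drafts}
    unknown = set(refinements) - set(by_id)
    if unknown:
        raise UnknownQuestionId(", ".join(sorted(unknown)))
    out = []
    for d in drafts:
        fields = refinements.get(d.question_id)
        if fields:
            fields = {
                k: tuple(v) if isinstance(v, (list, tuple)) else v
                for k, v in fields.items()
            }
            d = replace(d, **fields)
        out.append(d)
    return out


def load_refinements(path) -> dict[str, dict[str, object]]:
    """Refinement file: JSON object question_id → field overrides."""
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def questions_to_csv(questions: Sequence[QuestionTemplate], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["question_id", "concept_label", "question_text", "answer_type",
             "anchors", "synonyms", "positive_tokens", "negative_tokens"]
        )
        for q in questions:
            w.writerow(
                [q.question_id, q.concept_label, q.question_text, q.answer_type,
                 "|".join(q.anchors), "|".join(q.synonyms),
                 "|".join(q.positive_tokens), "|".join(q.negative_tokens)]
            )


def questions_from_csv(path) -> list[QuestionTemplate]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                QuestionTemplate(
                    question_id=row["question_id"],
                    concept_label=row["concept_label"],
                    question_text=row["question_text"],
                    answer_type=row["answer_type"],
                    anchors=tuple(a for a in row["anchors"].split("|") if a),
                    synonyms=tuple(s for s in row["synonyms"].split("|") if s),
                    positive_tokens=tuple(t for t in row["positive_tokens"].split("|") if t) or DEFAULT_POSITIVE_TOKENS,
                    negative_tokens=tuple(t for t in row["negative_tokens"].split("|") if t) or DEFAULT_NEGATIVE_TOKENS,
                )
            )
    return out
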