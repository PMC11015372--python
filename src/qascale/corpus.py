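"""Corpus preparation: deidentification, sentence segmentation and
two-strategy snippet pre-extraction.

Admission notes are strongly sectioned (chief complaint plus present /
past / personal / family / menstrual-obstetric histories), and models
answering over the full note confuse contexts — mixing the patient's
history with a family member's, or a current complaint with a past one.
Pre-extraction narrows each (record, question) pair to the sentences
that can actually answer it, by two complementary strategies:

* position — the sections/regions named by the question's anchors
  (family-history questions read the family-history section, symptom
  questions the complaint and present history);
* concept — every sentence containing one of the concept's synonyms as
  a substring (whitespace-collapsed; case-folded for Latin text).

The union of the two, deduplicated in document order, is the snippet
handed to the Q&A stage.  Pre-extraction never fabricates text: every
snippet sentence is a verbatim substring of the record.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._util import normalize_term
from .questions import QuestionTemplate

__all__ = [
    "SECTION_NAMES",
    "SECTION_TITLES",
    "AdmissionRecord",
    "Sentence",
    "Snippet",
    "MismatchedKeys",
    "deidentify",
    "segment",
    "segment_record",
    "extract_by_position",
    "extract_by_concept",
    "combine",
    "preextract",
    "read_records",
    "write_records",
]

SECTION_NAMES = (
    "chief_complaint",
    "present_history",
    "past_history",
    "personal_history",
    "family_history",
    "menstrual_obstetric_history",
)

SECTION_TITLES = {
    "chief_complaint": "主诉",
    "present_history": "现病史",
    "past_history": "既往史",
    "personal_history": "个人史",
    "family_history": "家族史",
    "menstrual_obstetric_history": "月经婚育史",
}

_SENTENCE = re.compile(r"[^。！？!?;；\n]*[。！？!?;；\n]+|[^。！？!?;；\n]+")

# ordered: phones and dates first so the generic long-digit rule cannot
# swallow them
DEID_RULES: tuple[tuple[str, str], ...] = (
    (r"1[3-9]\d{9}", "[PHONE]"),
    (r"\d{4}年\d{1,2}月\d{1,2}日|\d{4}[-/]\d{1,2}[-/]\d{1,2}", "[DATE]"),
    (r"\d{8,}", "[ID]"),
    (r"[一-鿿]某{1,2}", "[NAME]"),
)


class MismatchedKeys(ValueError):
    pass


@dataclass(frozen=True)
class AdmissionRecord:
    """One patient's sectioned free-text admission note."""

    record_id: str
    sections: Mapping[str, str]

    def __post_init__(self):
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        unknown = set(self.sections) - set(SECTION_NAMES)
        if unknown:
            raise ValueError(f"unknown sections: {sorted(unknown)}")
        if not any(v.strip() for v in self.sections.values()):
            raise ValueError("at least one section must be non-empty")
        ordered = {name: self.sections.get(name, "") for name in SECTION_NAMES if name in self.sections}
        object.__setattr__(self, "sections", ordered)

    def full_text(self) -> str:
        return "".join(self.sections.values())


@dataclass(frozen=True)
class Sentence:
    section: str
    start: int  # 0-based, half-open offsets into the section text
    end: int
    text: str


@dataclass(frozen=True)
class Snippet:
    record_id: str
    question_id: str
    sentences: tuple[Sentence, ...]
    strategy: str  # position | concept | both

    @property
    def is_empty(self) -> bool:
        return not self.sentences

    def text(self) -> str:
        return "".join(s.text for s in self.sentences)


def deidentify(record: AdmissionRecord, rules: Sequence[tuple[str, str]] | None = None, return_map: bool = False):
    """Replace pattern-matched identifiers with typed placeholders.

    Returns the cleaned record, or ``(record, offset_map)`` when
    ``return_map`` is true; the offset map lists, per section, the
    original (start, end) span and the placeholder that replaced it, so
    downstream offsets can be reconciled with the raw text.
    """
    rules = rules if rules is not None else DEID_RULES
    compiled = [(re.compile(p), repl) for p, repl in rules]
    sections: dict[str, str] = {}
    offset_map: dict[str, list[tuple[int, int, str]]] = {}
    for name, text in record.sections.items():
        spans: list[tuple[int, int, str]] = []
        for pattern, repl in compiled:
            for m in pattern.finditer(text):
                if not any(m.start() < e and s < m.end() for s, e, _ in spans):
                    spans.append((m.start(), m.end(), repl))
        spans.sort()
        out, prev = [], 0
        for s, e, repl in spans:
            out.append(text[prev:s])
            out.append(repl)
            prev = e
        out.append(text[prev:])
        sections[name] = "".join(out)
        offset_map[name] = spans
    cleaned = AdmissionRecord(record.record_id, sections)
    return (cleaned, offset_map) if return_map else cleaned


def segment(section_text: str, section: str = "") -> list[Sentence]:
    """Split section text into sentences with half-open 0-based offsets.

    Terminators (。！？!?;；and newline) attach to the preceding
    sentence; text without a terminator forms a final sentence.  The
    split is lossless: concatenating the sentence texts reconstructs
    the section exactly.
    """
    return [
        Sentence(section=section, start=m.start(), end=m.end(), text=m.group())
        for m in _SENTENCE.finditer(section_text)
    ]


def segment_record(record: AdmissionRecord) -> dict[str, list[Sentence]]:
    return {name: segment(text, section=name) for name, text in record.sections.items()}


def _resolve_anchor_sections(anchor: str) -> list[str]:
    """An anchor names a section either by key or by (part of) its
    Chinese header."""
    hits = [name for name in SECTION_NAMES if anchor == name]
    if hits:
        return hits
    return [name for name, title in SECTION_TITLES.items() if anchor in title]


def extract_by_position(
    record: AdmissionRecord,
    question: QuestionTemplate,
    sentences: Mapping[str, Sequence[Sentence]] | None = None,
) -> Snippet:
    """Strategy 1: sentences from the sections/regions the question's
    anchors name.  Anchors that match no section act as keywords and
    select sentences containing them.  No anchors → empty snippet."""
    sentences = sentences if sentences is not None else segment_record(record)
    picked: list[Sentence] = []
    for anchor in question.anchors:
        section_hits = _resolve_anchor_sections(anchor)
        if section_hits:
            for name in section_hits:
                picked.extend(sentences.get(name, ()))
        else:
            needle = normalize_term(anchor)
            for name in record.sections:
                picked.extend(s for s in sentences.get(name, ()) if needle in normalize_term(s.text))
    return Snippet(record.record_id, question.question_id, _dedup(picked), "position")


def extract_by_concept(
    record: AdmissionRecord,
    question: QuestionTemplate,
    sentences: Mapping[str, Sequence[Sentence]] | None = None,
) -> Snippet:
    """Strategy 2: every sentence containing a concept synonym as a
    normalized substring."""
    if not question.synonyms:
        raise ValueError("question's concept has no synonyms")
    sentences = sentences if sentences is not None else segment_record(record)
    needles = [normalize_term(s) for s in question.synonyms if s.strip()]
    picked = [
        s
        for name in record.sections
        for s in sentences.get(name, ())
        if any(n in normalize_term(s.text) for n in needles)
    ]
    return Snippet(record.record_id, question.question_id, _dedup(picked), "concept")


def _dedup(sentences: Iterable[Sentence]) -> tuple[Sentence, ...]:
    order = {name: i for i, name in enumerate(SECTION_NAMES)}
    unique = {(s.section, s.start): s for s in sentences}
    return tuple(sorted(unique.values(), key=lambda s: (order.get(s.section, 99), s.start)))


def combine(position_snippet: Snippet, concept_snippet: Snippet) -> Snippet:
    """Union of the two strategies' sentences, document order, deduped
    by (section, start).  The strategy field records provenance; both
    snippets empty yields an empty-context snippet (the Q&A stage then
    applies its empty-context policy)."""
    if (position_snippet.record_id, position_snippet.question_id) != (
        concept_snippet.record_id,
        concept_snippet.question_id,
    ):
        raise MismatchedKeys("snippets come from different (record, question) pairs")
    merged = _dedup(position_snippet.sentences + concept_snippet.sentences)
    if position_snippet.sentences and concept_snippet.sentences:
        strategy = "both"
    elif position_snippet.sentences:
        strategy = "position"
    elif concept_snippet.sentences:
        strategy = "concept"
    else:
        strategy = "both"
    return Snippet(position_snippet.record_id, position_snippet.question_id, merged, strategy)


def preextract(
    records: Sequence[AdmissionRecord],
    questions: Sequence[QuestionTemplate],
) -> dict[tuple[str, str], Snippet]:
    """Both strategies combined for every (record, question) pair."""
    out: dict[tuple[str, str], Snippet] = {}
    for record in records:
        sentences = segment_record(record)
        for q in questions:
            snip = combine(
                extract_by_position(record, q, sentences),
                extract_by_concept(record, q, sentences),
            )
            out[(record.record_id, q.question_id)] = snip
    return out


def read_records(path) -> list[AdmissionRecord]:
    records = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            rid = str(obj["record_id"])
            if rid in seen:
                raise ValueError(f"duplicate record_id {rid!r}")
            seen.add(rid)
            records.append(AdmissionRecord(rid, obj["sections"]))
    return records


def write_records(records: Sequence[AdmissionRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps({"record_id": r.record_id, "sections": dict(r.sections)}, ensure_ascii=False) + "\n")


def write_snippets(snippets: Mapping[tuple[str, str], Snippet], path) -> None:
    """Audit dump: record_id, question_id, strategy, joined text."""
    with open(path, "w", encoding="utf-8") as fh:
        for (rid, qid), s in snippets.items():
            fh.write(
                json.dumps(
                    {"record_id": rid, "question_id": qid, "strategy": s.strategy, "text": s.text()},
                    ensure_ascii=False,
                )
                + "\n"
            )
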