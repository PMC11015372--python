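"""Concept aggregation and filtering.

Raw per-record concept lists (model output over the corpus) are merged
with guideline-derived terms, counted at the *record* level (a concept
mentioned twice in one note still counts once), and then pass three
filters:

1. frequency — corpus concepts are retained only when their record-level
   prevalence strictly exceeds the threshold (default 5%); guideline
   terms bypass this filter, since they are added precisely to cover
   concepts the corpus under-mentions;
2. vocabulary — rule-based exact matching against a term→domain table,
   keeping only terms found in the vocabulary with an allowed domain
   (default: Clinical finding / Observable entity);
3. structured-text exclusion — concepts embedded in structured content
   (dates, numbers) are dropped by configurable patterns, with an
   explicit keep/drop override file standing in for expert curation so
   that runs stay reproducible.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from ._util import normalize_term

__all__ = [
    "ConceptTerm",
    "VocabularyTable",
    "EmptyCorpus",
    "parse_concept_output",
    "aggregate",
    "merge_guideline_terms",
    "filter_by_frequency",
    "filter_by_vocabulary",
    "exclude_structured",
    "concepts_to_csv",
    "concepts_from_csv",
]

DEFAULT_ALLOWED_DOMAINS = frozenset({"Clinical finding", "Observable entity"})

# model list output separators: newlines, CJK/ASCII semicolons & commas, 、
_SPLIT = re.compile(r"[\n;；、，,]+")
_NUMBERING = re.compile(r"^\s*(?:[-*•·]|\(?\d{1,3}[.)、．]|\d{1,3}\s*[:：])\s*")

DEFAULT_STRUCTURED_PATTERNS = (
    r"\d",                                    # any digit (dates, dosages, counts)
    r"^[〇一二三四五六七八九十]+[年月日周]",  # CJK-numeral date shapes
)


class EmptyCorpus(ValueError):
    pass


@dataclass(frozen=True)
class ConceptTerm:
    """One candidate clinical concept after aggregation."""

    label: str
    synonyms: tuple[str, ...] = ()
    domain_tag: str = ""
    source: str = "corpus"  # corpus | guideline
    record_count: int = 0
    prevalence: float = 0.0

    def __post_init__(self):
        if self.label not in self.synonyms:
            object.__setattr__(self, "synonyms", (self.label,) + tuple(self.synonyms))
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")


@dataclass(frozen=True)
class VocabularyTable:
    """Exact-string term→domain lookup (whitespace-normalized, case-folded)."""

    entries: Mapping[str, str]
    allowed_domains: frozenset[str] = DEFAULT_ALLOWED_DOMAINS

    def __post_init__(self):
        object.__setattr__(self, "entries", {normalize_term(k): v for k, v in dict(self.entries).items()})

    def domain_of(self, term: str) -> str | None:
        return self.entries.get(normalize_term(term))

    @classmethod
    def from_csv(cls, path, allowed_domains: Iterable[str] | None = None) -> "VocabularyTable":
        entries: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                entries[row["term"]] = row["domain_tag"]
        return cls(entries, frozenset(allowed_domains) if allowed_domains else DEFAULT_ALLOWED_DOMAINS)


def parse_concept_output(completion_text: str) -> list[str]:
    """Split a model's delimited concept list into raw strings.

    Tolerant of numbering, bullets and stray delimiters; never raises.
    Duplicates are preserved (deduplication is aggregation's job).
    """
    out: list[str] = []
    for piece in _SPLIT.split(completion_text or ""):
        piece = _NUMBERING.sub("", piece).strip()
        if piece:
            out.append(piece)
    return out


def aggregate(
    per_record_concepts: Mapping[str, Sequence[str]],
    synonym_map: Mapping[str, str] | None = None,
    corpus_size: int | None = None,
) -> list[ConceptTerm]:
    """Merge raw per-record concept strings into counted concepts.

    Each concept counts at most once per record; surface forms are
    canonicalized through ``synonym_map`` (normalized exact lookup).
    Prevalence is record_count / corpus size.
    """
    if not per_record_concepts:
        raise EmptyCorpus("no records to aggregate")
    n = corpus_size if corpus_size is not None else len(per_record_concepts)
    if n < 1:
        raise EmptyCorpus("corpus size must be >= 1")
    canon = {normalize_term(k): v for k, v in (synonym_map or {}).items()}

    counts: dict[str, int] = {}
    surfaces: dict[str, set[str]] = {}
    for _, raw_list in sorted(per_record_concepts.items()):
        seen: set[str] = set()
        for raw in raw_list:
            raw = raw.strip()
            if not raw:
                continue
            label = canon.get(normalize_term(raw), raw)
            surfaces.setdefault(label, set()).add(raw)
            if label not in seen:
                seen.add(label)
                counts[label] = counts.get(label, 0) + 1
    return [
        ConceptTerm(
            label=label,
            synonyms=tuple(sorted(surfaces[label])),
            record_count=c,
            prevalence=c / n,
        )
        for label, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def merge_guideline_terms(concepts: Sequence[ConceptTerm], guideline_terms: Iterable[str]) -> list[ConceptTerm]:
    """Add guideline-derived terms not already present in the corpus list."""
    present = {normalize_term(c.label) for c in concepts}
    for c in concepts:
        present.update(normalize_term(s) for s in c.synonyms)
    merged = list(concepts)
    for term in guideline_terms:
        term = term.strip()
        if term and normalize_term(term) not in present:
            present.add(normalize_term(term))
            merged.append(ConceptTerm(label=term, source="guideline"))
    return merged


def filter_by_frequency(concepts: Sequence[ConceptTerm], threshold: float = 0.05) -> list[ConceptTerm]:
    """Keep concepts with prevalence strictly above `threshold`.

    Guideline-sourced terms bypass the filter: they exist to widen the
    concept range beyond what the corpus mentions often.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    return [c for c in concepts if c.source == "guideline" or c.prevalence > threshold]


def filter_by_vocabulary(
    concepts: Sequence[ConceptTerm],
    vocab: VocabularyTable,
) -> tuple[list[ConceptTerm], list[tuple[ConceptTerm, str]]]:
    """Rule-based vocabulary filter.

    A concept is kept when its label or any synonym is in the vocabulary
    *and* carries an allowed domain; the kept concept is annotated with
    that domain.  Rejections distinguish ``out-of-vocabulary`` from
    ``wrong-domain``.
    """
    if not vocab.entries:
        raise ValueError("vocabulary table is empty")
    kept: list[ConceptTerm] = []
    rejected: list[tuple[ConceptTerm, str]] = []
    for c in concepts:
        domains = [d for d in (vocab.domain_of(s) for s in c.synonyms) if d is not None]
        allowed = [d for d in domains if d in vocab.allowed_domains]
        if allowed:
            kept.append(replace(c, domain_tag=allowed[0]))
        elif domains:
            rejected.append((c, "wrong-domain"))
        else:
            rejected.append((c, "out-of-vocabulary"))
    return kept, rejected


def exclude_structured(
    concepts: Sequence[ConceptTerm],
    rules: Sequence[str] | None = None,
    overrides: Mapping[str, str] | None = None,
) -> list[ConceptTerm]:
    """Drop concepts embedded in structured text (dates, numbers).

    ``overrides`` maps label → {keep, drop} and wins over the patterns,
    modeling the expert-curation pass as reproducible configuration
    (e.g. force-keeping "G6PD" despite its digit).
    """
    patterns = [re.compile(p) for p in (rules if rules is not None else DEFAULT_STRUCTURED_PATTERNS)]
    overrides = {normalize_term(k): v for k, v in (overrides or {}).items()}
    out: list[ConceptTerm] = []
    for c in concepts:
        action = overrides.get(normalize_term(c.label))
        if action == "drop":
            continue
        if action != "keep" and any(p.search(c.label) for p in patterns):
            continue
        out.append(c)
    return out


def concepts_to_csv(concepts: Sequence[ConceptTerm], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "synonyms", "domain_tag", "source", "record_count", "prevalence"])
        for c in concepts:
            w.writerow([c.label, "|".join(c.synonyms), c.domain_tag, c.source, c.record_count, f"{c.prevalence:.6f}"])


def concepts_from_csv(path) -> list[ConceptTerm]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ConceptTerm(
                    label=row["label"],
                    synonyms=tuple(s for s in row["synonyms"].split("|") if s),
                    domain_tag=row["domain_tag"],
                    source=row["source"],
                    record_count=int(row["record_count"]),
                    prevalence=float(row["prevalence"]),
                )
            )
    return out


def load_overrides(path) -> dict[str, str]:
    """Read a label,action{keep,drop} override CSV."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            action = row["action"].strip().lower()
            if action not in ("keep", "drop"):
                raise ValueError(f"unknown override action {action!r} for {row['label']!r}")
            out[row["label"]] = action
    return out
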