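"""Synthetic sectioned admission records with known gold labels.

The generator emulates Chinese obstetric admission narratives: a chief
complaint plus sectioned histories, where each catalog concept is drawn
per record (Bernoulli at its prevalence for binary concepts, a
truncated normal for numeric ones) and written into its target section
as a short template sentence.  Every template contains the concept
synonym verbatim, so concept-sentence pre-extraction has perfect recall
on clean data.  Negative draws are written as explicit denials (无X /
否认X) by default — Chinese admission notes conventionally record
pertinent negatives — with an ``omission_ratio`` knob to leave a
fraction of negatives unmentioned instead.

Alongside the records the generator emits the aligned gold table and a
mock-backend script answering every pipeline task from gold (Q&A cells,
per-record concept lists, question drafts), which makes the whole
pipeline runnable and calibratable offline: an oracle run must score
100% accuracy with a 0% null ratio, and a noisy run must recover the
configured corruption rates.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from ._util import round_half_up, stable_seed
from .corpus import AdmissionRecord
from .gateway import MockBackend
from .questions import QuestionTemplate

__all__ = [
    "ConceptSpec",
    "SynthSpec",
    "SynthCorpus",
    "InvalidSpec",
    "default_catalog",
    "generate",
    "load_published_ratios",
    "published_ratio_fixture",
]


class InvalidSpec(ValueError):
    pass


@dataclass(frozen=True)
class ConceptSpec:
    """One catalog concept: how it manifests in a record and its truth."""

    label: str
    question_id: str
    question_text: str
    answer_type: str  # binary | numeric
    section: str
    category: str = "symptom"
    synonyms: tuple[str, ...] = ()
    prevalence: float = 0.0          # binary concepts
    mean: float = 0.0                # numeric concepts
    sd: float = 1.0
    positive_template: str = ""      # must contain a synonym verbatim
    negative_template: str = ""
    numeric_template: str = ""       # with {value}

    def __post_init__(self):
        if not self.synonyms:
            object.__setattr__(self, "synonyms", (self.label,))
        if not 0.0 <= self.prevalence <= 1.0:
            raise InvalidSpec(f"{self.label}: prevalence must be in [0, 1]")
        templates = (
            (self.positive_template, self.negative_template)
            if self.answer_type == "binary"
            else (self.numeric_template,)
        )
        for t in templates:
            if t and not any(s in t for s in self.synonyms):
                raise InvalidSpec(f"{self.label}: template {t!r} lacks the concept synonym")


@dataclass(frozen=True)
class SynthSpec:
    n_records: int
    concepts: tuple[ConceptSpec, ...]
    seed: int
    flip_rate: float = 0.0
    null_rate: float = 0.0
    gibberish_rate: float = 0.0
    omission_ratio: float = 0.0  # fraction of negatives left unmentioned

    def __post_init__(self):
        if self.n_records < 1:
            raise InvalidSpec("n_records must be >= 1")
        if not self.concepts:
            raise InvalidSpec("concept catalog is empty")
        if not 0.0 <= self.omission_ratio <= 1.0:
            raise InvalidSpec("omission_ratio must be in [0, 1]")


@dataclass
class SynthCorpus:
    records: list[AdmissionRecord]
    gold: dict[tuple[str, str], object]
    questions: list[QuestionTemplate]
    script: dict[tuple[str, str], tuple[str, str]]
    spec: SynthSpec

    def make_backend(self, **overrides) -> MockBackend:
        """Mock backend scripted from this corpus's gold answers."""
        opts = dict(
            flip_rate=self.spec.flip_rate,
            null_rate=self.spec.null_rate,
            gibberish_rate=self.spec.gibberish_rate,
            seed=stable_seed(self.spec.seed, "backend"),
        )
        opts.update(overrides)
        return MockBackend(self.script, **opts)


def default_catalog() -> tuple[ConceptSpec, ...]:
    """Ten concepts spanning the question types of an obstetric
    admission note: symptoms, personal/family histories, a menstrual
    item and one quantity."""
    return (
        ConceptSpec(
            "头痛", "q_头痛", "患者是否头痛？", "binary", "present_history",
            prevalence=0.10,
            positive_template="间断头痛1周。", negative_template="无头痛。",
        ),
        ConceptSpec(
            "腹痛", "q_腹痛", "患者是否腹痛？", "binary", "present_history",
            prevalence=0.45,
            positive_template="阵发性腹痛2天。", negative_template="无腹痛。",
        ),
        ConceptSpec(
            "阴道流血", "q_阴道流血", "患者是否阴道流血？", "binary", "present_history",
            synonyms=("阴道流血", "阴道出血"), prevalence=0.30,
            positive_template="少量阴道流血。", negative_template="无阴道流血。",
        ),
        ConceptSpec(
            "双下肢水肿", "q_双下肢水肿", "患者是否双下肢水肿？", "binary", "present_history",
            synonyms=("双下肢水肿", "水肿"), prevalence=0.15,
            positive_template="双下肢水肿1周。", negative_template="无双下肢水肿。",
        ),
        ConceptSpec(
            "头晕", "q_头晕", "患者是否头晕？", "binary", "present_history",
            prevalence=0.07,
            positive_template="头晕3天。", negative_template="无头晕。",
        ),
        ConceptSpec(
            "药物过敏", "q_药物过敏", "患者是否有药物过敏史？", "binary", "personal_history",
            category="history", prevalence=0.10,
            positive_template="有药物过敏史。", negative_template="否认药物过敏史。",
        ),
        ConceptSpec(
            "手术史", "q_手术史", "患者是否有手术史？", "binary", "past_history",
            category="history", synonyms=("手术史", "手术"), prevalence=0.35,
            positive_template="既往有手术史。", negative_template="否认手术史。",
        ),
        ConceptSpec(
            "家族高血压", "q_家族高血压", "患者家族中是否有高血压史？", "binary", "family_history",
            category="history", synonyms=("家族高血压", "高血压"), prevalence=0.04,
            positive_template="母亲患高血压。", negative_template="否认家族高血压史。",
        ),
        ConceptSpec(
            "痛经", "q_痛经", "患者平素是否痛经？", "binary", "menstrual_obstetric_history",
            category="history", prevalence=0.22,
            positive_template="平素痛经。", negative_template="无痛经。",
        ),
        ConceptSpec(
            "孕期增重", "q_孕期增重", "患者孕期增重多少公斤？", "numeric", "present_history",
            category="quantity", mean=13.7, sd=5.0,
            numeric_template="孕期增重{value}kg。",
        ),
    )


def _section_anchor(spec: ConceptSpec) -> tuple[str, ...]:
    # symptoms anchor to complaint + present history; everything else to
    # its own section
    if spec.category == "symptom":
        return ("chief_complaint", "present_history")
    return (spec.section,)


def _questions(catalog: tuple[ConceptSpec, ...]) -> list[QuestionTemplate]:
    return [
        QuestionTemplate(
            question_id=c.question_id,
            concept_label=c.label,
            question_text=c.question_text,
            answer_type=c.answer_type,
            anchors=_section_anchor(c),
            synonyms=c.synonyms,
        )
        for c in catalog
    ]


def generate(spec: SynthSpec) -> SynthCorpus:
    """Draw the corpus, gold table and mock script from one seed.

    Byte-identical for identical specs: every record uses its own
    sub-seed derived from (seed, index), independent of generation
    order.
    """
    records: list[AdmissionRecord] = []
    gold: dict[tuple[str, str], object] = {}
    script: dict[tuple[str, str], tuple[str, str]] = {}
    width = max(5, len(str(spec.n_records)))

    for i in range(spec.n_records):
        rid = f"r{i + 1:0{width}d}"
        rng = random.Random(stable_seed(spec.seed, "record", i))
        weeks = rng.randint(11, 40)
        sections: dict[str, list[str]] = {name: [] for name in (
            "chief_complaint", "present_history", "past_history",
            "personal_history", "family_history", "menstrual_obstetric_history")}
        sections["chief_complaint"].append(f"停经{weeks}周，要求产前检查。")
        mentioned: list[str] = []

        for c in spec.concepts:
            qid = c.question_id
            if c.answer_type == "numeric":
                value = round_half_up(max(0.0, rng.gauss(c.mean, c.sd)), 1)
                sections[c.section].append(c.numeric_template.format(value=value))
                mentioned.append(c.label)
                gold[(rid, qid)] = value
                script[(rid, qid)] = (str(value), str(round_half_up(value + 9.9, 1)))
                continue
            positive = rng.random() < c.prevalence
            gold[(rid, qid)] = "positive" if positive else "negative"
            script[(rid, qid)] = ("有", "无") if positive else ("无", "有")
            if positive:
                sections[c.section].append(c.positive_template)
                mentioned.append(c.label)
            elif rng.random() >= spec.omission_ratio:
                sections[c.section].append(c.negative_template)
                mentioned.append(c.label)

        records.append(AdmissionRecord(rid, {k: "".join(v) for k, v in sections.items()}))
        script[(rid, "__concepts__")] = ("\n".join(mentioned),) * 2

    for c in spec.concepts:
        script[(c.label, "__question__")] = (c.question_text,) * 2

    return SynthCorpus(records, gold, _questions(spec.concepts), script, spec)


# ---------------------------------------------------------------------------
# published-table fixture

def load_published_ratios() -> pd.DataFrame:
    """The published 68-question ratio table (percent columns per model)."""
    with resources.files("qascale.data").joinpath("published_qa_ratios.csv").open(encoding="utf-8") as fh:
        return pd.read_csv(fh)


def published_ratio_fixture(model: str = "qwen", concepts=None, n: int = 10000):
    """Rebuild value columns whose summaries reproduce printed rows.

    For each selected binary row the printed percentages are converted
    into exact cell counts at ``n`` (positive and null counts from the
    printed values, negatives filling the remainder) and expanded into
    a value column, for regression-testing the column-summary
    arithmetic.  Returns ``{concept: (values, (pos%, neg%, null%))}``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if model not in ("qwen", "baichuan"):
        raise ValueError("model must be 'qwen' or 'baichuan'")
    table = load_published_ratios()
    rows = table.dropna(subset=[f"{model}_positive"])
    if concepts is not None:
        rows = rows[rows["concept"].isin(list(concepts))]
        if not len(rows):
            raise ValueError("no matching binary rows")
    out = {}
    for _, row in rows.iterrows():
        pos_pct, neg_pct, null_pct = (
            float(row[f"{model}_positive"]),
            float(row[f"{model}_negative"]),
            float(row[f"{model}_null"]),
        )
        n_pos = round(pos_pct * n / 100)
        n_null = round(null_pct * n / 100)
        n_neg = n - n_pos - n_null
        if n_neg < 0:
            raise ValueError(f"row {row['concept']!r} does not fit n={n}")
        values = ["positive"] * n_pos + ["negative"] * n_neg + [None] * n_null
        out[row["concept"]] = (values, (pos_pct, neg_pct, null_pct))
    return out
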