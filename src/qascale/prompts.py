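"""Four-paragraph prompt templating.

Every task prompt follows the same structure: a *context* paragraph that
sets the role, an *instruction* paragraph carrying ordered
chain-of-thought steps plus few-shot examples, an *input data* paragraph
with named ``{slot}`` placeholders, and an *output indicator* paragraph
pinning the expected format.  Rendering is a pure function of
(template, bindings), and templates are backend-independent objects: the
same template is sent verbatim to every model so that prompt wording can
never bias a model comparison.

The shipped default wording is an editable reconstruction of the
published structure (the original templates are Chinese); the testable
contract is the four-section shape, not the exact phrasing.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, asdict
from typing import Mapping

import yaml

from .gateway import ChatMessage

__all__ = [
    "PromptTemplate",
    "MissingSlot",
    "UnknownSlot",
    "render",
    "validate_template",
    "default_templates",
    "load_templates",
    "save_templates",
]

TASKS = ("concept_extraction", "question_generation", "qa_extraction")

_EXAMPLE_MARKERS = ("例", "示例", "Example", "example", "e.g.")


class MissingSlot(KeyError):
    pass


class UnknownSlot(KeyError):
    pass


@dataclass(frozen=True)
class PromptTemplate:
    task: str
    context: str
    instruction: str
    input_template: str
    output_indicator: str

    @property
    def input_slots(self) -> tuple[str, ...]:
        """Placeholder names appearing in the input paragraph, in order."""
        seen = []
        for _, name, _, _ in string.Formatter().parse(self.input_template):
            if name is not None and name not in seen:
                seen.append(name)
        return tuple(seen)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, str]) -> "PromptTemplate":
        return cls(**{k: d[k] for k in ("task", "context", "instruction", "input_template", "output_indicator")})


def render(template: PromptTemplate, bindings: Mapping[str, str]) -> list[ChatMessage]:
    """Render to chat messages: context as the system turn, the three
    remaining paragraphs concatenated into one user turn.

    Deterministic; identical inputs yield byte-identical messages.
    """
    slots = set(template.input_slots)
    missing = slots - set(bindings)
    if missing:
        raise MissingSlot(", ".join(sorted(missing)))
    extra = set(bindings) - slots
    if extra:
        raise UnknownSlot(", ".join(sorted(extra)))
    input_section = template.input_template.format(**bindings)
    user = "\n\n".join(part for part in (template.instruction, input_section, template.output_indicator))
    return [ChatMessage("system", template.context), ChatMessage("user", user)]


def validate_template(template: PromptTemplate) -> list[str]:
    """Static well-formedness findings (empty list means clean).

    Checks the four-section contract: no empty sections, each slot
    referenced exactly once, a recognizable example block inside the
    instruction (warning only).
    """
    findings: list[str] = []
    if template.task not in TASKS:
        findings.append(f"unknown task {template.task!r}")
    for section in ("context", "instruction", "input_template", "output_indicator"):
        if not getattr(template, section).strip():
            findings.append(f"{section} empty")
    counts: dict[str, int] = {}
    for _, name, _, _ in string.Formatter().parse(template.input_template):
        if name is not None:
            counts[name] = counts.get(name, 0) + 1
    for name, n in counts.items():
        if n != 1:
            findings.append(f"slot {name!r} referenced {n} times (expected exactly once)")
    if not re.search("|".join(map(re.escape, _EXAMPLE_MARKERS)), template.instruction):
        findings.append("warning: instruction has no example block")
    return findings


def default_templates() -> dict[str, PromptTemplate]:
    """Shipped templates for the three pipeline tasks (Chinese wording,
    editable via the config format)."""
    concept = PromptTemplate(
        task="concept_extraction",
        context="你是一名临床信息抽取助手，负责从入院记录的主诉和病史中识别临床概念。",
        instruction=(
            "请按以下步骤抽取概念：\n"
            "1. 通读全文，逐句识别症状、病史、干预和检查相关的概念；\n"
            "2. 将概念规范为标准临床术语（临床发现与观察类）；\n"
            "3. 去除日期、数值等结构化内容。\n"
            "示例：输入“停经30周，头晕3天，无头痛。”，逐步思考：‘头晕’为症状概念，"
            "‘头痛’为被否定的症状概念，仍属临床发现；输出：头晕、头痛。"
        ),
        input_template="入院记录原文：\n{text}",
        output_indicator="请仅输出概念列表，每行一个概念，不要输出其他内容。",
    )
    question = PromptTemplate(
        task="question_generation",
        context="你是一名临床研究助手，负责把临床概念改写为针对单份入院记录的提问。",
        instruction=(
            "请按以下步骤生成问题：\n"
            "1. 判断概念属于症状、病史、干预还是数量描述；\n"
            "2. 将其改写为一个可以用“有/无”或数值回答的具体问题。\n"
            "示例：概念“阿司匹林使用”，逐步思考：属于干预，可用有无回答；"
            "输出：患者是否使用阿司匹林？"
        ),
        input_template="概念：{concept}",
        output_indicator="请仅输出一个问题，不要输出其他内容。",
    )
    qa = PromptTemplate(
        task="qa_extraction",
        context="你是一名临床信息抽取助手，依据给定的病历片段回答一个问题。",
        instruction=(
            "请按以下步骤作答：\n"
            "1. 仅依据片段内容判断，不要引入片段之外的信息；\n"
            "2. 判断问题涉及的概念在片段中是肯定、否定还是数值描述；\n"
            "3. 给出最简短的回答。\n"
            "示例：片段“无头痛。”，问题“患者是否头痛？”，逐步思考：片段明确否定头痛；输出：无。"
        ),
        input_template="病历片段：{snippet}\n问题：{question}",
        output_indicator="请仅输出答案本身（有/无/数值），不要输出其他内容。",
    )
    return {t.task: t for t in (concept, question, qa)}


def save_templates(templates: Mapping[str, PromptTemplate], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({k: t.to_dict() for k, t in templates.items()}, fh, allow_unicode=True, sort_keys=True)


def load_templates(path) -> dict[str, PromptTemplate]:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return {k: PromptTemplate.from_dict(v) for k, v in raw.items()}
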