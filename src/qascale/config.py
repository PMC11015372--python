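"""Pipeline configuration: one auditable YAML file.

Every scattered setting of the extraction protocol lives here —
decoding parameters per task, concurrency, the frequency threshold,
token lists, file locations, the seed, and the behavioral flags
(pre-extraction skip, empty-context policy, averaging mode).  The
config round-trips through YAML so a run is fully described by one
text file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .questions import DEFAULT_NEGATIVE_TOKENS, DEFAULT_POSITIVE_TOKENS

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    # backend: either an OpenAI-compatible endpoint or a mock script
    backend_url: str = ""
    backend_model: str = ""
    backend_api_key: str = ""
    mock_script: str = "mock_script.jsonl"
    mock_flip_rate: float = 0.0
    mock_null_rate: float = 0.0
    mock_gibberish_rate: float = 0.0

    # decoding per task
    temperature: float = 0.0
    qa_max_tokens: int = 20
    concept_max_tokens: int = 256
    question_max_tokens: int = 60
    timeout: float = 30.0
    retries: int = 3
    concurrency: int = 3

    # concept filtering
    frequency_threshold: float = 0.05
    vocabulary_csv: str = ""        # empty → packaged fixture
    overrides_csv: str = ""
    guideline_terms: list[str] = field(default_factory=list)

    # answer normalization
    positive_tokens: list[str] = field(default_factory=lambda: list(DEFAULT_POSITIVE_TOKENS))
    negative_tokens: list[str] = field(default_factory=lambda: list(DEFAULT_NEGATIVE_TOKENS))

    # question drafting: concept label → category / pre-extraction anchors
    category_map: dict = field(default_factory=dict)
    anchors_map: dict = field(default_factory=dict)

    # behavior flags
    seed: int = 0
    skip_preextract: bool = False
    empty_context_policy: str = "negative_by_absence"  # or "full_text"
    averaging: str = "macro"                            # or "micro"
    annotation_subset: int = 1500

    # artifact names inside the run directory
    records_file: str = "records.jsonl"
    gold_file: str = "gold.csv"
    questions_file: str = "questions.csv"
    concepts_raw_file: str = "concepts_raw.jsonl"
    concepts_file: str = "concepts.csv"
    snippets_file: str = "snippets.jsonl"
    matrix_file: str = "matrix.csv"
    latency_file: str = "latency.csv"
    answers_file: str = "answers.jsonl"
    metrics_file: str = "metrics.csv"
    table_file: str = "table.csv"

    def __post_init__(self):
        if not 0.0 <= self.frequency_threshold < 1.0:
            raise ValueError("frequency_threshold must be in [0, 1)")
        if self.concurrency < 1:
            raise ValueError("concurrency must be >= 1")
        if self.empty_context_policy not in ("negative_by_absence", "full_text"):
            raise ValueError("unknown empty_context_policy")
        if self.averaging not in ("macro", "micro"):
            raise ValueError("averaging must be macro or micro")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, allow_unicode=True, sort_keys=False)
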