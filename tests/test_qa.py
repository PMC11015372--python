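"""Null detection, answer normalization and matrix assembly."""

import math

import pytest

from qascale._util import pct
from qascale.corpus import preextract
from qascale.qa import QAMatrix, QAnswer, column_summary, detect_null, normalize, run_matrix
from qascale.questions import QuestionTemplate
from qascale.synthetic import SynthSpec, default_catalog, generate, published_ratio_fixture

BINARY_Q = QuestionTemplate("q1", "头痛", "患者是否头痛？", "binary")
NUMERIC_Q = QuestionTemplate("q2", "孕期增重", "孕期增重多少？", "numeric")
CAT_Q = QuestionTemplate("q3", "月经颜色", "月经颜色如何？", "categorical")


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("", True),
        ("   \n", True),
        ("@@@###!!", True),           # symbols only
        ("！！！……", True),
        ("aaaaaaaaaa", True),         # single char repeating >= 8
        ("无", False),
        ("有。", False),
        ("13.5", False),
        ("嗯嗯嗯没问题", False),
    ],
)
def test_detect_null(raw, expected):
    assert detect_null(raw) is expected


def test_detect_null_length_bound_applies_only_with_limit():
    long = "描述" * 100
    assert detect_null(long) is False
    assert detect_null(long, max_chars=40) is True


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("无。", "negative"),
        ("有", "positive"),
        ("没有", "negative"),          # longest-at-position beats the 有 inside
        ("否认头痛", "negative"),
        ("阳性", "positive"),
        ("未见异常", "negative"),
        ("yes, present", "positive"),
        ("normal findings", None),     # 'no' inside a word must not match
        ("患者可能存在相关症状", None),  # no decisive token
    ],
)
def test_normalize_binary(raw, expected):
    assert normalize(raw, BINARY_Q) == expected


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("孕期增重13.5kg", 13.5),
        ("13", 13.0),
        ("-2.5kg", -2.5),
        ("无法确定", None),
    ],
)
def test_normalize_numeric(raw, expected):
    assert normalize(raw, NUMERIC_Q) == expected


def test_normalize_categorical_trims_text():
    assert normalize("  暗红色 \n", CAT_Q) == "暗红色"
    assert normalize("   ", CAT_Q) is None


def _matrix_from_values(values, question=BINARY_Q):
    cells = {
        (f"r{i}", question.question_id): QAnswer(f"r{i}", question.question_id, "", v, 0.1)
        for i, v in enumerate(values)
    }
    return QAMatrix([f"r{i}" for i in range(len(values))], [question], cells)


def test_column_summary_counts_to_percentages():
    values = ["positive"] * 5 + ["negative"] * 3 + [None] * 2
    assert column_summary(_matrix_from_values(values), "q1") == (50.0, 30.0, 20.0)


def test_column_summary_all_negative():
    assert column_summary(_matrix_from_values(["negative"] * 7), "q1") == (0.0, 100.0, 0.0)


def test_column_summary_numeric_mean_sd_null():
    values = [10.0, 12.0, 14.0, None]
    mean, sd, nullp = column_summary(_matrix_from_values(values, NUMERIC_Q), "q2")
    assert mean == 12.0
    assert sd == 2.0
    assert nullp == 25.0


def test_published_ratio_rows_sum_to_100():
    """Reconstructed ratio columns reproduce the printed triple and its sum."""
    fixture = published_ratio_fixture("baichuan", concepts=["Abdominal pain"])
    values, printed = fixture["Abdominal pain"]
    matrix = _matrix_from_values(values)
    summary = column_summary(matrix, "q1")
    assert summary == printed == (43.13, 52.00, 4.87)
    assert sum(summary) == pytest.approx(100.0, abs=0.02)


def test_matrix_dimensions_and_completeness(small_corpus):
    records = small_corpus.records[:3]
    questions = small_corpus.questions[:2]
    snippets = preextract(records, questions)
    matrix = run_matrix(records, questions, snippets, small_corpus.make_backend())
    assert len(matrix.cells) == 6
    assert matrix.values_frame().shape == (3, 2)


def test_matrix_rejects_incomplete_cells():
    with pytest.raises(ValueError, match="incomplete"):
        QAMatrix(["r1", "r2"], [BINARY_Q], {("r1", "q1"): QAnswer("r1", "q1", "", None, 0.0)})


def test_oracle_matrix_reproduces_gold_binary_cells(small_corpus, oracle_matrix):
    for (rid, qid), gold in small_corpus.gold.items():
        value = oracle_matrix.cells[(rid, qid)].value
        if gold in ("positive", "negative"):
            assert value == gold
        else:
            assert value == pytest.approx(gold)


def test_binary_ratio_sum_invariant(oracle_matrix):
    for q in oracle_matrix.questions:
        if q.answer_type != "binary":
            continue
        pos, neg, nul = column_summary(oracle_matrix, q.question_id)
        assert pos + neg + nul == pytest.approx(100.0, abs=0.02)


def test_null_injection_rate_recovered_within_3_sigma():
    spec = SynthSpec(n_records=200, concepts=default_catalog(), seed=23, null_rate=0.05)
    corpus = generate(spec)
    snippets = preextract(corpus.records, corpus.questions)
    matrix = run_matrix(corpus.records, corpus.questions, snippets, corpus.make_backend())
    n = len(matrix.cells)
    observed = sum(a.is_null for a in matrix.cells.values()) / n
    sigma = math.sqrt(0.05 * 0.95 / n)
    assert abs(observed - 0.05) < 3 * sigma


def test_matrix_identical_across_runs_and_concurrency(small_corpus):
    spec_kwargs = dict(records=small_corpus.records[:20], questions=small_corpus.questions)
    snippets = preextract(spec_kwargs["records"], spec_kwargs["questions"])

    def run(concurrency):
        backend = small_corpus.make_backend(flip_rate=0.2, null_rate=0.05)
        m = run_matrix(spec_kwargs["records"], spec_kwargs["questions"], snippets, backend,
                       concurrency=concurrency)
        return [(a.record_id, a.question_id, a.raw, a.value) for a in
                (m.cells[k] for k in sorted(m.cells))]

    assert run(1) == run(3) == run(3)


def test_backend_failures_become_null_cells_with_notes(small_corpus):
    records = small_corpus.records[:2]
    questions = small_corpus.questions[:2]
    bad_key = (records[0].record_id, questions[0].question_id)
    backend = small_corpus.make_backend(fail_always=[bad_key])
    from qascale.gateway import GenerationParams

    snippets = preextract(records, questions)
    matrix = run_matrix(records, questions, snippets, backend,
                        GenerationParams(retries=1, backoff=0.0))
    failed = matrix.cells[bad_key]
    assert failed.is_null and "BackendUnavailable" in failed.error
    ok = [a for k, a in matrix.cells.items() if k != bad_key]
    assert all(a.error is None for a in ok)
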