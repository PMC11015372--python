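"""Accuracy/precision scoring, null ratios, macro means, timing."""

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from qascale._util import round_half_up
from qascale.evaluation import (
    MacroSummary,
    NoAnnotations,
    QuestionScore,
    SampleTooLarge,
    macro_summary,
    null_ratio,
    sample_subset,
    score_question,
    timing_summary,
)
from qascale.questions import QuestionTemplate
from qascale.synthetic import load_published_ratios

Q = QuestionTemplate("q1", "头痛", "患者是否头痛？", "binary")


class TestSampleSubset:
    def test_full_sample_is_canonical_order(self):
        ids = ["r3", "r1", "r2"]
        assert sample_subset(ids, 3, seed=0) == ["r1", "r2", "r3"]

    def test_same_seed_same_subset(self):
        ids = [f"r{i}" for i in range(100)]
        assert sample_subset(ids, 30, seed=7) == sample_subset(ids, 30, seed=7)
        assert sample_subset(ids, 30, seed=7) != sample_subset(ids, 30, seed=8)

    def test_sample_is_unique_and_uniform_size(self):
        ids = [f"r{i}" for i in range(2000)]
        subset = sample_subset(ids, 1500, seed=3)
        assert len(subset) == len(set(subset)) == 1500

    def test_oversized_sample_rejected(self):
        with pytest.raises(SampleTooLarge):
            sample_subset(["r1"], 2, seed=0)


def _score(n_correct_pos, n_wrong_pos, n_correct_neg, n_wrong_neg, n_null_on_pos=0):
    """Build prediction/gold maps with the given confusion counts."""
    preds, gold = {}, {}
    i = 0
    for _ in range(n_correct_pos):
        preds[f"r{i}"], gold[f"r{i}"] = "positive", "positive"; i += 1
    for _ in range(n_wrong_pos):
        preds[f"r{i}"], gold[f"r{i}"] = "positive", "negative"; i += 1
    for _ in range(n_correct_neg):
        preds[f"r{i}"], gold[f"r{i}"] = "negative", "negative"; i += 1
    for _ in range(n_wrong_neg):
        preds[f"r{i}"], gold[f"r{i}"] = "negative", "positive"; i += 1
    for _ in range(n_null_on_pos):
        preds[f"r{i}"], gold[f"r{i}"] = None, "positive"; i += 1
    return score_question(preds, gold, Q)


class TestScoreQuestion:
    def test_1000_of_1500_rounds_to_66_7(self):
        s = _score(500, 0, 500, 500)
        assert s.n_annotated == 1500 and s.n_correct == 1000
        assert s.accuracy_pct == 66.7

    def test_593_of_1500_rounds_to_39_5(self):
        s = _score(93, 0, 500, 907)
        assert s.n_correct == 593
        assert s.accuracy_pct == 39.5

    def test_precision_one_of_two_positive_predictions(self):
        s = _score(1, 1, 5, 0)
        assert (s.tp, s.fp) == (1, 1)
        assert s.precision_pct == 50.0

    def test_precision_zero_when_all_positives_wrong(self):
        s = _score(0, 2, 5, 0)
        assert s.precision_pct == 0.0

    def test_precision_undefined_without_positive_predictions(self):
        s = _score(0, 0, 5, 1)
        assert s.precision_pct is None

    def test_null_predictions_incorrect_and_not_positive(self):
        s = _score(2, 0, 2, 0, n_null_on_pos=2)
        assert s.n_null == 2
        assert s.n_correct == 4
        assert s.fn == 2          # nulls on gold positives are misses
        assert (s.tp, s.fp) == (2, 0)

    def test_no_annotations_raises(self):
        with pytest.raises(NoAnnotations):
            score_question({"r1": "positive"}, {}, Q)


class TestNullRatio:
    def test_411_of_25709_is_1_60_pct(self):
        values = [None] * 411 + ["negative"] * (25709 - 411)
        frac, p = null_ratio(values)
        assert p == 1.60
        assert frac == pytest.approx(411 / 25709)

    def test_1252_of_25707_is_4_87_pct(self):
        values = [None] * 1252 + ["positive"] * (25707 - 1252)
        assert null_ratio(values)[1] == 4.87

    def test_zero_nulls(self):
        assert null_ratio(["negative"] * 10) == (0.0, 0.0)


class TestMacroSummary:
    def test_single_hot_null_column_averages_to_0_02(self):
        scores = [QuestionScore(f"q{i}", 10, 10, 1, 0, 9, 0, 0) for i in range(68)]
        nulls = [1.60] + [0.0] * 67
        assert macro_summary(scores, nulls).mean_null_pct == 0.02

    def test_published_null_columns_reproduce_printed_means(self):
        table = load_published_ratios()
        scores = [QuestionScore("q", 1, 1, 1, 0, 0, 0, 0)]
        assert macro_summary(scores, list(table["qwen_null"])).mean_null_pct == 0.02
        assert macro_summary(scores, list(table["baichuan_null"])).mean_null_pct == 0.21

    def test_single_question_macro_equals_its_metrics(self):
        s = _score(3, 1, 5, 1)
        m = macro_summary([s], [0.0])
        assert m.mean_accuracy_pct == s.accuracy_pct
        assert m.mean_precision_pct == s.precision_pct

    def test_undefined_precision_excluded_from_macro_mean(self):
        defined = _score(4, 0, 4, 0)       # precision 100
        undefined = _score(0, 0, 8, 0)     # no positive predictions
        m = macro_summary([defined, undefined], [0.0, 0.0])
        assert m.mean_precision_pct == 100.0
        assert m.n_precision_defined == 1

    def test_micro_pools_counts(self):
        a = _score(9, 1, 0, 0)   # 10 annotated, 9 correct
        b = _score(0, 0, 1, 1)   # 2 annotated, 1 correct
        m = macro_summary([a, b], averaging="micro")
        assert m.mean_accuracy_pct == round_half_up(100 * 10 / 12, 2)


class TestTiming:
    def test_constant_latencies(self):
        df = pd.DataFrame({"q1": [1.0, 1.0], "q2": [1.0, 1.0]})
        out = timing_summary(df)
        assert (out["per_question"]["mean"] == 1.0).all()

    def test_scripted_latencies_mean(self):
        df = pd.DataFrame({"q1": [1.0, 2.0, 3.0]})
        assert out_mean(timing_summary(df)) == 2.0

    def test_empty_matrix(self):
        out = timing_summary(pd.DataFrame())
        assert out["per_question"].empty and out["per_record"].empty


def out_mean(summary):
    return float(summary["per_question"]["mean"].iloc[0])


@given(
    st.lists(
        st.tuples(st.sampled_from(["positive", "negative", None]),
                  st.sampled_from(["positive", "negative"])),
        min_size=1,
        max_size=40,
    )
)
def test_score_matches_bruteforce_confusion_recount(pairs):
    preds = {f"r{i}": p for i, (p, _) in enumerate(pairs)}
    gold = {f"r{i}": g for i, (_, g) in enumerate(pairs)}
    s = score_question(preds, gold, Q)
    # independent recount
    tp = sum(1 for p, g in pairs if p == "positive" and g == "positive")
    fp = sum(1 for p, g in pairs if p == "positive" and g == "negative")
    tn = sum(1 for p, g in pairs if p == "negative" and g == "negative")
    fn = sum(1 for p, g in pairs if p != "positive" and g == "positive")
    correct = sum(1 for p, g in pairs if p == g)
    nulls = sum(1 for p, _ in pairs if p is None)
    assert (s.tp, s.fp, s.tn, s.fn, s.n_correct, s.n_null) == (tp, fp, tn, fn, correct, nulls)
    assert 0.0 <= s.accuracy_pct <= 100.0
    if s.precision_pct is not None:
        assert 0.0 <= s.precision_pct <= 100.0
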