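"""Deidentification, segmentation and two-strategy snippet pre-extraction."""

import pytest
from hypothesis import given, strategies as st

from qascale.corpus import (
    AdmissionRecord,
    MismatchedKeys,
    Snippet,
    combine,
    deidentify,
    extract_by_concept,
    extract_by_position,
    preextract,
    segment,
)
from qascale.questions import QuestionTemplate


def _record(**sections):
    return AdmissionRecord("r1", sections)


def _question(qid="q1", anchors=(), synonyms=("头痛",)):
    return QuestionTemplate(qid, synonyms[0], "患者是否%s？" % synonyms[0], anchors=tuple(anchors), synonyms=tuple(synonyms))


class TestDeidentify:
    def test_phone_replaced_with_placeholder(self):
        rec = _record(present_history="患者张某某，电话13812345678。")
        out = deidentify(rec)
        assert "[PHONE]" in out.sections["present_history"]
        assert "13812345678" not in out.sections["present_history"]
        assert "[NAME]" in out.sections["present_history"]

    def test_record_without_identifiers_unchanged(self):
        rec = _record(chief_complaint="停经30周。", present_history="无头痛。")
        assert deidentify(rec).sections == rec.sections

    @pytest.mark.parametrize("raw", ["2021-09-01", "2021/9/1", "2021年9月1日"])
    def test_date_shapes_replaced(self, raw):
        out = deidentify(_record(present_history=f"{raw}起病。"))
        assert out.sections["present_history"] == "[DATE]起病。"

    def test_long_digit_runs_become_id(self):
        out = deidentify(_record(present_history="住院号12345678。"))
        assert "[ID]" in out.sections["present_history"]

    def test_offset_map_points_at_original_spans(self):
        text = "电话13812345678。"
        out, offsets = deidentify(_record(present_history=text), return_map=True)
        ((start, end, repl),) = offsets["present_history"]
        assert text[start:end] == "13812345678" and repl == "[PHONE]"


class TestSegment:
    def test_offsets_are_half_open_and_cover_text(self):
        sentences = segment("头晕3天。无头痛。")
        assert [(s.start, s.end) for s in sentences] == [(0, 5), (5, 9)]
        assert [s.text for s in sentences] == ["头晕3天。", "无头痛。"]

    def test_empty_text_yields_no_sentences(self):
        assert segment("") == []

    def test_text_without_terminator_is_one_sentence(self):
        (s,) = segment("无腹痛")
        assert (s.start, s.end, s.text) == (0, 3, "无腹痛")

    @given(st.text(alphabet="无头痛晕腹胀。！？!?;；\n abc", max_size=80))
    def test_segmentation_is_lossless(self, text):
        sentences = segment(text)
        assert "".join(s.text for s in sentences) == text
        # non-overlapping, ordered
        for a, b in zip(sentences, sentences[1:]):
            assert a.end == b.start


class TestPositionStrategy:
    def test_section_anchor_selects_that_section(self):
        rec = _record(present_history="无头痛。", family_history="父亲有高血压。")
        q = _question(anchors=("family_history",), synonyms=("高血压",))
        snip = extract_by_position(rec, q)
        assert [s.text for s in snip.sentences] == ["父亲有高血压。"]
        assert snip.strategy == "position"

    def test_no_anchors_gives_empty_snippet(self):
        snip = extract_by_position(_record(present_history="无头痛。"), _question())
        assert snip.is_empty

    def test_keyword_anchor_matches_section_title(self):
        rec = _record(present_history="无头痛。", menstrual_obstetric_history="平素月经规律。")
        q = _question(anchors=("月经",), synonyms=("痛经",))
        assert [s.text for s in extract_by_position(rec, q).sentences] == ["平素月经规律。"]


class TestConceptStrategy:
    def test_sentence_containing_concept_selected(self):
        rec = _record(present_history="头晕3天。无头痛。")
        snip = extract_by_concept(rec, _question())
        assert [s.text for s in snip.sentences] == ["无头痛。"]
        assert snip.strategy == "concept"

    def test_absent_concept_gives_empty_snippet(self):
        assert extract_by_concept(_record(present_history="无腹痛。"), _question()).is_empty

    def test_any_synonym_matches(self):
        rec = _record(present_history="少量出血。")
        q = _question(synonyms=("流血", "出血"))
        assert [s.text for s in extract_by_concept(rec, q).sentences] == ["少量出血。"]

    def test_latin_matching_is_case_folded(self):
        rec = _record(past_history="G6PD deficiency screening done.")
        q = _question(synonyms=("g6pd",))
        assert not extract_by_concept(rec, q).is_empty


class TestCombine:
    def _snips(self, rec, q):
        return extract_by_position(rec, q), extract_by_concept(rec, q)

    def test_disjoint_union_has_both_sentences(self):
        rec = _record(chief_complaint="待产。", present_history="无头痛。")
        q = _question(anchors=("chief_complaint",))
        merged = combine(*self._snips(rec, q))
        assert [s.text for s in merged.sentences] == ["待产。", "无头痛。"]
        assert merged.strategy == "both"

    def test_identical_sentences_deduplicate(self):
        rec = _record(present_history="无头痛。")
        q = _question(anchors=("present_history",))
        merged = combine(*self._snips(rec, q))
        assert len(merged.sentences) == 1

    def test_empty_nonempty_cases(self):
        rec = _record(present_history="无头痛。")
        pos = Snippet("r1", "q1", (), "position")
        con = extract_by_concept(rec, _question())
        assert combine(pos, con).strategy == "concept"
        assert combine(pos, con).sentences == con.sentences
        empty = combine(pos, Snippet("r1", "q1", (), "concept"))
        assert empty.is_empty

    def test_commutative_and_idempotent(self):
        rec = _record(chief_complaint="头痛待查。", present_history="无头晕。间断头痛。")
        q = _question(anchors=("chief_complaint",))
        a, b = self._snips(rec, q)
        assert combine(a, b).sentences == combine(b, a).sentences
        merged = combine(a, b)
        assert combine(merged, merged).sentences == merged.sentences

    def test_mismatched_keys_rejected(self):
        with pytest.raises(MismatchedKeys):
            combine(Snippet("r1", "q1", (), "position"), Snippet("r2", "q1", (), "concept"))


def test_snippets_never_fabricate_text(small_corpus):
    """Anti-hallucination guard: every snippet substring occurs verbatim
    in its record, and concept-strategy sentences contain a synonym."""
    by_id = {r.record_id: r for r in small_corpus.records}
    questions = {q.question_id: q for q in small_corpus.questions}
    snippets = preextract(small_corpus.records, small_corpus.questions)
    for (rid, qid), snip in snippets.items():
        record = by_id[rid]
        assert len(snip.text()) <= len(record.full_text())
        for s in snip.sentences:
            assert s.text in record.sections[s.section]
    for record in small_corpus.records:
        for q in small_corpus.questions:
            concept_snip = extract_by_concept(record, q)
            for s in concept_snip.sentences:
                assert any(syn in s.text for syn in q.synonyms)


def test_record_invariants_enforced():
    with pytest.raises(ValueError):
        AdmissionRecord("", {"chief_complaint": "x"})
    with pytest.raises(ValueError):
        AdmissionRecord("r1", {"not_a_section": "x"})
    with pytest.raises(ValueError):
        AdmissionRecord("r1", {"chief_complaint": "  "})
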