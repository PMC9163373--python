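"""Rule annotator: segmentation, section location, event extraction, negation."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from famhist.annotate import (
    annotate_note,
    events_to_label,
    extract_events,
    kinship_degree,
    locate_family_history,
    segment,
)
from famhist.synth import LengthModel, render_note
from famhist.types import FamilyHistoryEvent, FamilyHistoryLabel


# ----------------------------------------------------------------- segment
def test_segment_empty_text(zh_lexicon):
    assert segment("", zh_lexicon) == []


def test_segment_single_lexicon_term(zh_lexicon):
    toks = segment("精神分裂症", zh_lexicon)
    assert len(toks) == 1
    assert (toks[0].start, toks[0].end) == (0, 5)


def test_segment_unknown_tokenizer(zh_lexicon):
    with pytest.raises(KeyError, match="tokenizer_id"):
        segment("x", zh_lexicon, tokenizer_id="nope")


@settings(max_examples=60, derandomize=True)
@given(
    st.lists(
        st.sampled_from(
            ["父亲", "精神分裂症", "否认", "家族史", "，", "。", "既", "往", "体", "健"]
        ),
        max_size=30,
    )
)
def test_segment_reconstructs_and_offsets_disjoint(pieces):
    lexicon = _zh()
    text = "".join(pieces)
    toks = segment(text, lexicon)
    assert "".join(t.surface for t in toks) == text
    # offsets sorted, non-overlapping, consistent with surfaces
    pos = 0
    for t in toks:
        assert t.start == pos and t.end - t.start == len(t.surface)
        pos = t.end
    assert pos == len(text)


def _zh():
    from famhist.lexicon import load_lexicon

    return load_lexicon("zh")


def test_segment_longest_match_wins(zh_lexicon):
    # 外祖父 must be one second-degree token, not 外 + 祖父
    toks = segment("外祖父", zh_lexicon)
    assert [t.surface for t in toks] == ["外祖父"]


# ------------------------------------------------------------------ locate
def test_locate_family_history_covers_rendered_sentence(zh_lexicon):
    rng = np.random.default_rng(0)
    rendered = render_note(
        rng, zh_lexicon, [("F20", "父亲")], False, [], 250, LengthModel()
    )
    span = locate_family_history(rendered.text, zh_lexicon)
    assert span is not None
    start, end = span
    # located span sits inside the rendered family-history sentence
    assert rendered.fh_span[0] <= start < end <= rendered.fh_span[1]
    assert "父亲" in rendered.text[start:end]


def test_locate_without_cue_returns_none(zh_lexicon):
    assert locate_family_history("既往体健。", zh_lexicon) is None


def test_locate_cue_at_end_of_text(zh_lexicon):
    text = "既往体健。家族史"
    assert locate_family_history(text, zh_lexicon) == (5, len(text))


# ----------------------------------------------------------------- extract
def test_sister_major_depression_yields_f32_event(debug_lexicon):
    text = (
        "Past history: unremarkable. Family history: the patient's sister was "
        "diagnosed with major depressive disorder. Physical exam: normal."
    )
    events = extract_events(text, debug_lexicon)
    assert len(events) == 1
    e = events[0]
    assert (e.disease_code, e.relation_term, e.kinship_degree) == ("F32", "sister", "first")
    assert text[e.span[0] : e.span[1]] == "major depressive disorder"


def test_denial_phrase_yields_no_events(zh_lexicon):
    text = "现病史：情绪低落。家族史：否认家族中有精神分裂症等精神疾病史。"
    assert extract_events(text, zh_lexicon) == []


def test_distractor_outside_section_ignored_with_section_scope(zh_lexicon):
    text = "既往史：曾因精神分裂症样症状就诊。家族史无特殊。个人史：无异常。"
    assert extract_events(text, zh_lexicon, scope="section") == []
    # full-text scope does see the mention
    assert len(extract_events(text, zh_lexicon, scope="full")) == 1


def test_nearest_preceding_kinship_attachment(zh_lexicon):
    text = "家族史：父亲体健，母亲患抑郁症。"
    events = extract_events(text, zh_lexicon)
    assert len(events) == 1
    assert events[0].relation_term == "母亲"
    assert events[0].kinship_degree == "first"


def test_multiple_events_in_one_sentence(zh_lexicon):
    text = "家族史：祖父患精神分裂症，表妹患双相情感障碍。"
    events = extract_events(text, zh_lexicon)
    assert [(e.disease_code, e.kinship_degree) for e in events] == [
        ("F20", "second"),
        ("F31", "third"),
    ]
    assert events[0].span[0] < events[1].span[0]


def test_disease_without_kinship_gets_unknown_relation(debug_lexicon):
    text = "Family history: there is schizophrenia in the family."
    events = extract_events(text, debug_lexicon)
    assert len(events) == 1
    assert events[0].kinship_degree == "unknown"


# ---------------------------------------------------------- events_to_label
def test_events_to_label_worked_example():
    e = FamilyHistoryEvent("F32", "sister", "first", (0, 5))
    assert events_to_label([e]).to_dict() == {
        "F20": 0, "F32": 1, "F31": 0, "F28": 0, "F29": 0
    }


def test_events_to_label_empty_and_union():
    assert events_to_label([]).indicators == (0, 0, 0, 0, 0)
    es = [
        FamilyHistoryEvent("F20", "father", "first", (0, 2)),
        FamilyHistoryEvent("F28", "aunt", "second", (5, 8)),
    ]
    assert events_to_label(es).indicators == (1, 0, 0, 1, 0)


@settings(max_examples=50, derandomize=True)
@given(
    st.lists(
        st.sampled_from(["F20", "F32", "F31", "F28", "F29"]), max_size=10
    )
)
def test_events_to_label_idempotent_and_order_invariant(codes):
    events = [
        FamilyHistoryEvent(c, "father", "first", (i, i + 1)) for i, c in enumerate(codes)
    ]
    base = events_to_label(events)
    assert events_to_label(events + events) == base
    assert events_to_label(list(reversed(events))) == base


# ------------------------------------------------------------------ kinship
@pytest.mark.parametrize(
    "term,degree",
    [("sister", "first"), ("cousin", "third"), ("uncle", "second"), ("lawyer", "unknown")],
)
def test_kinship_degree_map(debug_lexicon, term, degree):
    assert kinship_degree(term, debug_lexicon) == degree


# ------------------------------------------------------------- whole corpus
def test_rule_labels_equal_gold_on_clean_corpus(clean_cohort, zh_lexicon):
    notes, _ = clean_cohort
    for note in notes:
        label, events = annotate_note(note, zh_lexicon)
        assert label == note.gold.label, note.text
        assert {(e.disease_code, e.span) for e in events} == {
            (e.disease_code, e.span) for e in note.gold.events
        }


def test_annotation_deterministic(noisy_cohort, zh_lexicon):
    notes, _ = noisy_cohort
    for note in notes[:40]:
        a = extract_events(note.text, zh_lexicon)
        b = extract_events(note.text, zh_lexicon)
        assert a == b
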