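"""Synthetic-corpus generator: determinism, calibration, gold consistency, IO."""
import dataclasses
import json

import numpy as np
import pytest

from famhist.corpus import CorpusParseError, read_corpus, write_corpus
from famhist.lexicon import load_lexicon
from famhist.synth import (
    ConfigError,
    LengthModel,
    SyntheticCorpusConfig,
    generate_cohort,
    render_note,
    sample_lengths,
    template_fillers_are_term_free,
)
from famhist.types import LABEL_ORDER


def test_seeded_determinism():
    cfg = SyntheticCorpusConfig(n_patients=40, seed=9)
    notes_a, truths_a = generate_cohort(cfg)
    notes_b, truths_b = generate_cohort(cfg)
    dump = lambda notes: json.dumps([n.to_dict() for n in notes], ensure_ascii=False)
    assert dump(notes_a) == dump(notes_b)
    assert {p: t.label for p, t in truths_a.items()} == {
        p: t.label for p, t in truths_b.items()
    }


def test_no_signal_config_yields_all_negative_gold():
    rates = {d: {c: 0.0 for c in LABEL_ORDER} for d in ("F31", "F32", "F33")}
    cfg = SyntheticCorpusConfig(n_patients=30, fh_category_rates=rates, seed=1)
    notes, truths = generate_cohort(cfg)
    assert all(n.gold.label.indicators == (0, 0, 0, 0, 0) for n in notes)
    assert all(t.label.indicators == (0, 0, 0, 0, 0) for t in truths.values())


def test_patient_truth_is_or_of_note_quintets(noisy_cohort):
    notes, truths = noisy_cohort
    by_patient: dict[str, list] = {}
    for n in notes:
        by_patient.setdefault(n.patient_id, []).append(n.gold.label.indicators)
    assert set(by_patient) == set(truths)
    for pid, quints in by_patient.items():
        expected = tuple(int(any(q[i] for q in quints)) for i in range(5))
        assert truths[pid].label.indicators == expected
        assert truths[pid].n_notes == len(quints)


def test_diagnosis_group_counts_follow_multinomial():
    cfg = SyntheticCorpusConfig(n_patients=12006, seed=4)
    _, truths = generate_cohort(cfg)
    counts = {d: 0 for d in ("F31", "F32", "F33")}
    for t in truths.values():
        counts[t.diagnosis_code] += 1
    for diag, p in cfg.diagnosis_mix.items():
        expected = 12006 * p
        sd = np.sqrt(12006 * p * (1 - p))
        assert abs(counts[diag] - expected) < 3 * sd


def test_family_history_prevalence_calibrated():
    cfg = SyntheticCorpusConfig(n_patients=4000, seed=13)
    _, truths = generate_cohort(cfg)
    by_diag: dict[str, list] = {}
    for t in truths.values():
        by_diag.setdefault(t.diagnosis_code, []).append(t.label.indicators)
    for diag, quints in by_diag.items():
        arr = np.array(quints)
        for j, code in enumerate(LABEL_ORDER):
            p = cfg.fh_category_rates[diag][code]
            sd = np.sqrt(p * (1 - p) / len(arr))
            assert abs(arr[:, j].mean() - p) <= 3 * sd + 1e-12


def test_length_model_calibration():
    model = LengthModel()
    rng = np.random.default_rng(3)
    lengths = sample_lengths(model, 12006, rng)
    se_mean = model.sd / np.sqrt(len(lengths))
    se_sd = model.sd / np.sqrt(2 * len(lengths))
    assert abs(lengths.mean() - model.mean) < 3 * se_mean
    assert abs(lengths.std(ddof=1) - model.sd) < 3 * se_sd
    assert lengths.min() >= model.min and lengths.max() <= model.max


def test_generated_note_lengths_within_bounds(noisy_cohort):
    notes, _ = noisy_cohort
    model = LengthModel()
    assert all(model.min <= len(n.text) <= model.max for n in notes)


@pytest.mark.parametrize("lexicon_id", ["zh", "debug"])
def test_render_note_realizes_events_with_correct_spans(lexicon_id):
    lexicon = load_lexicon(lexicon_id)
    rng = np.random.default_rng(0)
    kin = lexicon.kinship_surfaces("first")[0]
    rendered = render_note(
        rng, lexicon, [("F32", kin)], negation=False, distractor_codes=[],
        target_length=200, length_model=LengthModel(),
    )
    assert len(rendered.text) == 200
    (event,) = rendered.events
    assert event.disease_code == "F32"
    surface = rendered.text[event.span[0] : event.span[1]]
    assert lexicon.disease_terms[surface] == "F32"
    fh = rendered.text[rendered.fh_span[0] : rendered.fh_span[1]]
    assert kin in fh and surface in fh


def test_render_negation_note_has_denial_and_no_events(debug_lexicon):
    rng = np.random.default_rng(1)
    rendered = render_note(
        rng, debug_lexicon, [], negation=True, distractor_codes=[],
        target_length=150, length_model=LengthModel(),
    )
    assert rendered.events == []
    fh = rendered.text[rendered.fh_span[0] : rendered.fh_span[1]]
    assert any(cue in fh for cue in debug_lexicon.negation_cues)


def test_render_distractor_note_mentions_disease_outside_family_history(zh_lexicon):
    rng = np.random.default_rng(2)
    rendered = render_note(
        rng, zh_lexicon, [], negation=False, distractor_codes=["F20"],
        target_length=250, length_model=LengthModel(),
    )
    assert rendered.events == []
    surfaces = zh_lexicon.disease_surfaces("F20")
    pre = rendered.text[: rendered.fh_span[0]]
    assert any(s in pre for s in surfaces)
    fh = rendered.text[rendered.fh_span[0] : rendered.fh_span[1]]
    assert not any(s in fh for s in surfaces)


def test_render_rejects_unknown_disease_category(zh_lexicon):
    rng = np.random.default_rng(0)
    with pytest.raises(ConfigError, match="F99"):
        render_note(rng, zh_lexicon, [("F99", "父亲")], False, [], 200, LengthModel())


@pytest.mark.parametrize("lexicon_id", ["zh", "debug"])
def test_filler_templates_contain_no_lexicon_terms(lexicon_id):
    assert template_fillers_are_term_free(load_lexicon(lexicon_id))


@pytest.mark.parametrize(
    "field,value,match",
    [
        ("n_patients", 0, "n_patients"),
        ("negation_rate", 1.5, "negation_rate"),
        ("diagnosis_mix", {"F31": 0.5, "F32": 0.6, "F33": -0.1}, "diagnosis_mix"),
        ("kinship_mix", {"first": 0.5, "second": 0.5}, "kinship_mix"),
        ("length_model", LengthModel(mean=10, min=60), "length_model"),
    ],
)
def test_config_validation_names_offending_field(field, value, match):
    cfg = dataclasses.replace(SyntheticCorpusConfig(), **{field: value})
    with pytest.raises(ConfigError, match=match):
        cfg.validate()


def test_corpus_round_trip(tmp_path, noisy_cohort):
    notes, _ = noisy_cohort
    path = tmp_path / "corpus.jsonl"
    write_corpus(notes[:100], path)
    back = read_corpus(path)
    assert [n.to_dict() for n in back] == [n.to_dict() for n in notes[:100]]


def test_empty_corpus_round_trip(tmp_path):
    path = tmp_path / "empty.jsonl"
    write_corpus([], path)
    assert path.read_text() == ""
    assert read_corpus(path) == []


def test_truncated_line_reports_line_number(tmp_path):
    path = tmp_path / "bad.jsonl"
    path.write_text('{"note_id": "N1", "patient_id"\n', encoding="utf-8")
    with pytest.raises(CorpusParseError, match="line 1"):
        read_corpus(path)
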