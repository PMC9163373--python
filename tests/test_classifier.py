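"""Classifier training, inference contracts, grid search and hybrid mode."""
import dataclasses

import numpy as np
import pytest

from famhist.classifier import (
    ClassifierConfig,
    TrainedModel,
    evaluate_on,
    grid_search,
    hybrid_postfilter,
    train,
)
from famhist.pipeline import split_dataset
from famhist.types import AdmissionNote, FamilyHistoryEvent, FamilyHistoryLabel, GoldAnnotation

LABEL_CODES = ("F20", "F32", "F31", "F28", "F29")
KEYWORDS = {
    "F20": "schizophrenia",
    "F32": "major depressive disorder",
    "F31": "bipolar disorder",
    "F28": "other nonorganic mental disorder",
    "F29": "unspecified nonorganic psychosis",
}


def _toy_corpus(n_per_label=12, n_negative=24, seed=0):
    """Linearly separable toy notes: one distinctive keyword per label."""
    rng = np.random.default_rng(seed)
    notes = []
    i = 0
    for code, word in KEYWORDS.items():
        for _ in range(n_per_label):
            kin = ["father", "mother", "sister"][int(rng.integers(3))]
            text = f"Family history: the {kin} has {word}."
            notes.append(_note(i, text, [code]))
            i += 1
    for _ in range(n_negative):
        text = "Family history: unremarkable. Exam normal."
        notes.append(_note(i, text, []))
        i += 1
    return notes


def _note(i, text, codes):
    return AdmissionNote(
        note_id=f"n{i}", patient_id=f"p{i}", admission_year=2015, age_years=40,
        gender="female", marital_status="married", profession="retiree",
        first_diagnosis="F32", text=text,
        gold=GoldAnnotation(label=FamilyHistoryLabel.from_codes(codes)),
    )


TINY = ClassifierConfig(
    encoder="static_vectors", encoder_dim=16, kernel_widths=(2, 3),
    filters_per_width=16, learning_rate=5e-3, batch_size=8, epochs=25,
    max_text_length=64, seed=0,
)


def test_split_sizes_64_16_20():
    notes = _toy_corpus(n_per_label=12, n_negative=40)  # 100 notes
    splits = split_dataset(notes, (0.64, 0.16, 0.20), seed=1)
    assert (len(splits["train"]), len(splits["val"]), len(splits["test"])) == (64, 16, 20)


def test_training_reaches_perfect_fit_on_separable_corpus():
    notes = _toy_corpus()
    model, splits = train(notes, TINY)
    report = evaluate_on(model, splits["train"])
    assert report.micro["f1"] == pytest.approx(1.0)


def test_seeded_training_is_reproducible():
    notes = _toy_corpus()
    cfg = dataclasses.replace(TINY, epochs=4)
    model_a, _ = train(notes, cfg)
    model_b, _ = train(notes, cfg)
    assert model_a.training_log == model_b.training_log
    for k in model_a.parameters:
        assert np.array_equal(model_a.parameters[k], model_b.parameters[k])
    texts = [n.text for n in notes[:5]]
    assert np.array_equal(model_a.predict_proba(texts), model_b.predict_proba(texts))


def test_inference_contracts():
    notes = _toy_corpus()
    model, _ = train(notes, dataclasses.replace(TINY, epochs=3))
    # determinism: identical texts give identical probabilities in (0, 1)
    p = model.predict_proba([notes[0].text, notes[0].text])
    assert np.array_equal(p[0], p[1])
    assert np.all((p > 0) & (p < 1))
    # truncation: token matrix has at most max_text_length rows
    long_text = notes[0].text * 10
    (mat,) = model.encode([long_text])
    assert mat.shape == (model.config.max_text_length, model.config.encoder_dim)
    # OOV characters map to the unknown-token row
    net = model._network()
    oov_mat = model.encode(["☃☃"])[0]  # snowman: not in training text
    unk_row = net.encoder.tok.weight.data[1]
    assert np.allclose(oov_mat[0], unk_row)
    # empty text names the offending note
    with pytest.raises(ValueError, match="note7"):
        model.encode([""], note_ids=["note7"])


def test_thresholding_of_probabilities():
    probs = np.array([[0.9, 0.2, 0.6, 0.1, 0.4]])
    assert hybrid_postfilter(probs, [[]], "model_only").tolist() == [[1, 0, 1, 0, 0]]


def test_untrained_model_refuses_prediction():
    from famhist.nn import Vocabulary

    model = TrainedModel(config=TINY, vocab=Vocabulary(["a"]), parameters={})
    with pytest.raises(RuntimeError, match="trained"):
        model.predict_proba(["aa"])


def test_save_load_round_trip(tmp_path):
    notes = _toy_corpus()
    model, _ = train(notes, dataclasses.replace(TINY, epochs=2))
    model.save(tmp_path / "model")
    back = TrainedModel.load(tmp_path / "model")
    texts = [n.text for n in notes[:8]]
    assert np.array_equal(model.predict_proba(texts), back.predict_proba(texts))
    assert back.config == model.config


def test_grid_search_cardinality_and_ranking():
    notes = _toy_corpus(n_per_label=6, n_negative=10)
    cfg = dataclasses.replace(TINY, epochs=2)
    results = grid_search(
        notes, {"learning_rate": [1e-2, 1e-3], "batch_size": [8, 16]},
        base_config=cfg, runs=2,
    )
    assert len(results) == 4
    f1s = [r["mean_test_micro_f1"] for r in results]
    assert f1s == sorted(f1s, reverse=True)
    single = grid_search(notes, {"batch_size": [8]}, base_config=cfg, runs=2)
    assert len(single) == 1


def test_grid_search_tie_break_is_stable():
    notes = _toy_corpus(n_per_label=6, n_negative=10)
    cfg = dataclasses.replace(TINY, epochs=1)
    # identical configs twice: identical metrics, grid order preserved
    results = grid_search(notes, {"decision_threshold": [0.5, 0.5]}, base_config=cfg, runs=2)
    assert [r["order"] for r in results] == [0, 1]


def test_hybrid_postfilter_policies():
    probs = np.array([[0.9, 0.1, 0.1, 0.1, 0.1], [0.2, 0.2, 0.2, 0.2, 0.2]])
    ev = FamilyHistoryEvent("F32", "sister", "first", (0, 3))
    events = [[], [ev]]
    assert hybrid_postfilter(probs, events, "rule_and").tolist() == [
        [0, 0, 0, 0, 0],  # model positive but no rule event -> vetoed
        [0, 0, 0, 0, 0],
    ]
    assert hybrid_postfilter(probs, events, "rule_or").tolist() == [
        [1, 0, 0, 0, 0],
        [0, 1, 0, 0, 0],  # rule event promotes the negative model output
    ]
    assert hybrid_postfilter(probs, events, "model_only").tolist() == [
        [1, 0, 0, 0, 0],
        [0, 0, 0, 0, 0],
    ]
    with pytest.raises(ValueError, match="policy"):
        hybrid_postfilter(probs, events, "majority")


def test_config_validation():
    with pytest.raises(ValueError, match="encoder"):
        ClassifierConfig(encoder="giant_llm").validate()
    with pytest.raises(ValueError, match="learning_rate"):
        dataclasses.replace(TINY, learning_rate=0.0).validate()
    with pytest.raises(ValueError, match="encoder_weights"):
        ClassifierConfig(encoder="pretrained_contextual").validate()
    with pytest.raises(ValueError, match="width"):
        dataclasses.replace(TINY, kernel_widths=(0,)).validate()


def test_empty_corpus_and_missing_gold_errors():
    with pytest.raises(ValueError, match="empty"):
        train([], TINY)
    bare = _note(0, "Family history: unremarkable.", [])
    bare.gold = None
    with pytest.raises(ValueError, match="gold"):
        train([bare] * 10, TINY)
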