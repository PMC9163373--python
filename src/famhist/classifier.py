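"""Neural multi-label classifier: training, inference, grid search, hybrid mode.

The model projects a note's characters into a dense matrix with a pluggable
encoder, extracts features with multi-width convolutions (ReLU, stride one,
per-filter max pooling, concatenation in ascending width order) and maps them
through a fully connected sigmoid layer to five per-category probabilities.
Encoder x head combinations also instantiate the two baselines: static word
vectors + CNN, and a contextual encoder + single fully connected layer.

Training minimizes mean per-label binary cross-entropy with Adam; after each
epoch the validation micro-F1 is recorded and the returned parameters are
those of the best validation epoch.  Everything is reproducible from the
config seed.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import metrics
from .nn import (
    Adam,
    CNNHead,
    ContextualEncoder,
    FamilyHistoryNet,
    FCHead,
    StaticVectorEncoder,
    Tensor,
    Vocabulary,
    batch_ids,
    bce_with_logits,
)
from .pipeline import derive_seed, split_dataset
from .types import AdmissionNote, FamilyHistoryEvent, LABEL_ORDER

logger = logging.getLogger(__name__)

ENCODERS = ("small_contextual", "static_vectors", "pretrained_contextual")
HEADS = ("cnn", "fc")

#: Hyper-parameter grid searched by default: learning rate x batch size.
DEFAULT_GRID = {"learning_rate": [1e-4, 1e-5], "batch_size": [16, 32]}


@dataclass(frozen=True)
class ClassifierConfig:
    encoder: str = "small_contextual"
    encoder_dim: int = 32
    encoder_layers: int = 2
    encoder_heads: int = 2
    encoder_weights: Optional[str] = None  # npz archive for pretrained_contextual
    freeze_encoder: bool = False
    kernel_widths: tuple[int, ...] = (2, 3, 4)
    filters_per_width: int = 128
    head: str = "cnn"
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 100
    early_stopping_patience: Optional[int] = None
    decision_threshold: float = 0.5
    max_text_length: int = 256
    split_fractions: tuple[float, float, float] = (0.64, 0.16, 0.20)
    group_by_patient: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.encoder not in ENCODERS:
            raise ValueError(f"encoder must be one of {ENCODERS}")
        if self.head not in HEADS:
            raise ValueError(f"head must be one of {HEADS}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 < self.decision_threshold < 1.0):
            raise ValueError("decision_threshold must lie in (0, 1)")
        if any(w < 1 or w > self.max_text_length for w in self.kernel_widths):
            raise ValueError("kernel widths must be >= 1 and <= max_text_length")
        if self.encoder == "pretrained_contextual" and not self.encoder_weights:
            raise ValueError(
                "pretrained_contextual requires encoder_weights (npz archive); "
                "use the small_contextual encoder for a self-contained model"
            )


def build_network(config: ClassifierConfig, vocab_size: int, rng: np.random.Generator) -> FamilyHistoryNet:
    if config.encoder in ("small_contextual", "pretrained_contextual"):
        encoder = ContextualEncoder(
            rng, vocab_size, config.encoder_dim, config.encoder_layers,
            config.encoder_heads, config.max_text_length,
        )
        if config.encoder == "pretrained_contextual":
            state = dict(np.load(config.encoder_weights))
            encoder.load_state_dict({k.removeprefix("encoder."): v for k, v in state.items()
                                     if k.startswith("encoder.")} or state)
    else:
        encoder = StaticVectorEncoder(rng, vocab_size, config.encoder_dim)
    if config.head == "cnn":
        head = CNNHead(rng, config.encoder_dim, config.kernel_widths,
                       config.filters_per_width, len(LABEL_ORDER))
    else:
        head = FCHead(rng, config.encoder_dim, len(LABEL_ORDER))
    return FamilyHistoryNet(encoder, head)


@dataclass
class TrainedModel:
    """Learned parameters plus everything needed to reproduce inference."""

    config: ClassifierConfig
    vocab: Vocabulary
    parameters: dict[str, np.ndarray]
    label_order: tuple[str, ...] = LABEL_ORDER
    training_log: list[dict] = field(default_factory=list)

    def _network(self) -> FamilyHistoryNet:
        net = build_network(self.config, len(self.vocab), np.random.default_rng(0))
        net.load_state_dict(self.parameters)
        return net

    def encode(self, texts: Sequence[str], note_ids: Optional[Sequence[str]] = None) -> list[np.ndarray]:
        """Dense (tokens x dim) matrix per text (deterministic inference)."""
        net = self._network()
        out = []
        for i, text in enumerate(texts):
            if not text:
                nid = note_ids[i] if note_ids else f"#{i}"
                raise ValueError(f"empty text for note {nid}")
            ids, mask = batch_ids([self.vocab.encode(text, self.config.max_text_length)],
                                  self.config.max_text_length)
            out.append(net.encoder(ids, mask).data[0])
        return out

    def predict_proba(self, texts: Sequence[str], batch_size: int = 64) -> np.ndarray:
        """Per-category probabilities, shape (n_texts, 5), order = label_order."""
        if not self.parameters:
            raise RuntimeError("model has no trained parameters")
        net = self._network()
        probs = np.empty((len(texts), len(LABEL_ORDER)))
        for start in range(0, len(texts), batch_size):
            chunk = texts[start : start + batch_size]
            enc = [self.vocab.encode(t, self.config.max_text_length) for t in chunk]
            if any(len(e) == 0 for e in enc):
                bad = [i for i, e in enumerate(enc) if not e]
                raise ValueError(f"empty text at positions {bad} in batch starting {start}")
            ids, mask = batch_ids(enc, self.config.max_text_length)
            probs[start : start + len(chunk)] = net(ids, mask).sigmoid().data
        return probs

    def predict(self, texts: Sequence[str]) -> np.ndarray:
        return (self.predict_proba(texts) >= self.config.decision_threshold).astype(int)

    # ------------------------------------------------------------------- io
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        cfg["kernel_widths"] = list(self.config.kernel_widths)
        cfg["split_fractions"] = list(self.config.split_fractions)
        (directory / "config.json").write_text(json.dumps(cfg, indent=1))
        (directory / "vocab.json").write_text(
            json.dumps(self.vocab.to_dict(), ensure_ascii=False)
        )
        (directory / "training_log.json").write_text(json.dumps(self.training_log, indent=1))
        np.savez(directory / "parameters.npz", **self.parameters)

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        cfg = json.loads((directory / "config.json").read_text())
        cfg["kernel_widths"] = tuple(cfg["kernel_widths"])
        cfg["split_fractions"] = tuple(cfg["split_fractions"])
        config = ClassifierConfig(**cfg)
        vocab = Vocabulary.from_dict(json.loads((directory / "vocab.json").read_text()))
        params = dict(np.load(directory / "parameters.npz"))
        log = json.loads((directory / "training_log.json").read_text())
        return cls(config=config, vocab=vocab, parameters=params, training_log=log)


def conv_pool(
    matrix: np.ndarray,
    kernel_widths: Sequence[int],
    filters_per_width: int,
    weights: Optional[Sequence[np.ndarray]] = None,
    biases: Optional[Sequence[np.ndarray]] = None,
    seed: int = 0,
) -> np.ndarray:
    """Multi-width convolution + ReLU + per-filter max pooling on one matrix.

    ``matrix`` is (tokens x dim).  Each output component is the maximum over
    valid positions of ReLU(conv); per-width blocks are concatenated in
    ascending width order, giving a vector of length
    ``len(kernel_widths) * filters_per_width``.  Widths exceeding the number
    of rows are skipped with a warning.  When ``weights``/``biases`` are not
    given, Glorot-uniform filters from ``seed`` are used (order follows the
    sorted widths).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D (tokens x dim)")
    L, D = matrix.shape
    widths = sorted(kernel_widths)
    rng = np.random.default_rng(seed)
    feats = []
    for i, w in enumerate(widths):
        if weights is not None:
            wt = np.asarray(weights[i], dtype=float).reshape(w * D, filters_per_width)
        else:
            scale = np.sqrt(6.0 / (w * D + filters_per_width))
            wt = rng.uniform(-scale, scale, size=(w * D, filters_per_width))
        b = np.asarray(biases[i], dtype=float) if biases is not None else np.zeros(filters_per_width)
        if L < w:
            warnings.warn(f"kernel width {w} skipped: matrix has only {L} rows")
            continue
        windows = np.lib.stride_tricks.sliding_window_view(matrix, w, axis=0)
        flat = windows.transpose(0, 2, 1).reshape(L - w + 1, w * D)
        feats.append(np.maximum(flat @ wt + b, 0.0).max(axis=0))
    if not feats:
        raise ValueError("matrix shorter than every kernel width")
    return np.concatenate(feats)


def _labels_matrix(notes: Sequence[AdmissionNote]) -> np.ndarray:
    missing = [n.note_id for n in notes if n.gold is None]
    if missing:
        raise ValueError(f"notes without gold labels: {missing[:5]}")
    return np.array([n.gold.label.indicators for n in notes], dtype=float)


def train(
    notes: Sequence[AdmissionNote],
    config: ClassifierConfig = ClassifierConfig(),
    verbose: bool = False,
) -> tuple[TrainedModel, dict[str, list[AdmissionNote]]]:
    """Train on a gold-labelled corpus; returns the model and the splits used.

    The corpus is divided into train/validation/test sets by the configured
    fractions (default 64/16/20).  Parameters from the epoch with the best
    validation micro-F1 are returned.
    """
    config.validate()
    if not notes:
        raise ValueError("empty corpus")
    y_all = _labels_matrix(notes)
    if y_all.sum() == 0:
        raise ValueError("corpus has no positive note for any label")
    for j, lab in enumerate(LABEL_ORDER):
        if y_all[:, j].sum() == 0:
            logger.warning("label %s has zero positives in the corpus", lab)

    splits = split_dataset(
        notes, config.split_fractions, derive_seed(config.seed, "split"),
        group_by_patient=config.group_by_patient,
    )
    train_notes, val_notes = splits["train"], splits["val"]
    rng = np.random.default_rng(derive_seed(config.seed, "init"))
    vocab = Vocabulary.build([n.text for n in train_notes])
    net = build_network(config, len(vocab), rng)

    trainable = net.named_parameters()
    if config.freeze_encoder:
        trainable = {k: v for k, v in trainable.items() if not k.startswith("encoder.")}
    opt = Adam(list(trainable.values()), lr=config.learning_rate)

    def encode_batch(batch: Sequence[AdmissionNote]):
        return batch_ids([vocab.encode(n.text, config.max_text_length) for n in batch],
                         config.max_text_length)

    def val_micro_f1() -> float:
        preds, golds = {}, {}
        for start in range(0, len(val_notes), 64):
            chunk = val_notes[start : start + 64]
            ids, mask = encode_batch(chunk)
            p = (net(ids, mask).sigmoid().data >= config.decision_threshold).astype(int)
            for n, row in zip(chunk, p):
                preds[n.note_id] = row.tolist()
                golds[n.note_id] = list(n.gold.label.indicators)
        counts = metrics.confusion(preds, golds)
        return float(metrics.aggregate(counts, "micro")[2])

    shuffle_rng = np.random.default_rng(derive_seed(config.seed, "shuffle"))
    y_train = _labels_matrix(train_notes)
    best_f1, best_state, best_epoch = -1.0, net.state_dict(), -1
    log: list[dict] = []
    stale = 0
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(train_notes))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = [train_notes[i] for i in idx]
            ids, mask = encode_batch(batch)
            logits = net(ids, mask)
            loss = bce_with_logits(logits, y_train[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        f1 = val_micro_f1()
        log.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_micro_f1": f1})
        if verbose:
            logger.info("epoch %d loss %.4f val micro-F1 %.4f", epoch, np.mean(losses), f1)
        if f1 > best_f1:
            best_f1, best_state, best_epoch = f1, net.state_dict(), epoch
            stale = 0
        else:
            stale += 1
        if config.early_stopping_patience is not None and stale >= config.early_stopping_patience:
            break

    model = TrainedModel(config=config, vocab=vocab, parameters=best_state, training_log=log)
    model.training_log.append({"best_epoch": best_epoch, "best_val_micro_f1": best_f1})
    return model, splits


def evaluate_on(model: TrainedModel, notes: Sequence[AdmissionNote]) -> metrics.MetricReport:
    probs = model.predict_proba([n.text for n in notes])
    labels = (probs >= model.config.decision_threshold).astype(int)
    pred = {n.note_id: row.tolist() for n, row in zip(notes, labels)}
    gold = {n.note_id: list(n.gold.label.indicators) for n in notes}
    scores = {n.note_id: row.tolist() for n, row in zip(notes, probs)}
    return metrics.evaluate(pred, gold, scores)


def grid_search(
    notes: Sequence[AdmissionNote],
    grid: Mapping[str, Sequence] = DEFAULT_GRID,
    base_config: ClassifierConfig = ClassifierConfig(),
    runs: int = 5,
    verbose: bool = False,
) -> list[dict]:
    """Evaluate every config in the grid over ``runs`` seeded repetitions.

    Returns configs ranked by mean test micro-F1 (ties keep grid order).
    Each entry carries the per-run reports and mean +/- sd summaries.
    """
    import itertools

    keys = list(grid)
    combos = list(itertools.product(*(grid[k] for k in keys)))
    if not combos:
        raise ValueError("empty grid")
    results = []
    for order_idx, combo in enumerate(combos):
        cfg = replace(base_config, **dict(zip(keys, combo)))
        reports = []
        for r in range(runs):
            run_cfg = replace(cfg, seed=derive_seed(cfg.seed, f"run{r}"))
            model, splits = train(notes, run_cfg, verbose=verbose)
            reports.append(evaluate_on(model, splits["test"]))
        f1s = [rep.micro["f1"] for rep in reports]
        entry = {
            "config": {k: v for k, v in zip(keys, combo)},
            "order": order_idx,
            "mean_test_micro_f1": float(np.mean(f1s)),
            "runs": [rep.to_dict() for rep in reports],
        }
        if runs >= 2:
            entry["summary"] = metrics.summarize_runs(reports)
        results.append(entry)
    results.sort(key=lambda e: (-e["mean_test_micro_f1"], e["order"]))
    return results


def hybrid_postfilter(
    probabilities: np.ndarray,
    rule_events: Sequence[Sequence[FamilyHistoryEvent]],
    policy: str = "model_only",
    threshold: float = 0.5,
) -> np.ndarray:
    """Combine model probabilities with rule-extracted events per note.

    ``rule_and``: positive only where the thresholded model and the rules
    agree; ``rule_or``: positive where either fires; ``model_only``: the
    thresholded model labels unchanged.
    """
    if policy not in ("rule_and", "rule_or", "model_only"):
        raise ValueError(f"unknown policy {policy!r}")
    model_labels = (np.asarray(probabilities, dtype=float) >= threshold).astype(int)
    if policy == "model_only":
        return model_labels
    rule_labels = np.zeros_like(model_labels)
    for i, events in enumerate(rule_events):
        for e in events:
            rule_labels[i, LABEL_ORDER.index(e.disease_code)] = 1
    if policy == "rule_and":
        return model_labels & rule_labels
    return model_labels | rule_labels
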