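"""Multi-label evaluation protocol.

Per-label confusion counts; precision/recall/F1 under micro averaging
(pool counts across labels, then compute) and macro averaging (compute per
label, then unweighted mean) — the two diverge under label imbalance, which
is why both are reported.  Accuracy defaults to the per-decision convention
(correct (note, label) decisions over n_notes x n_labels); subset accuracy
(exact quintet match) is available for comparison.  ROC/AUC per label, mean
+/- sd over repeated runs, and a Welch t-test between configurations round
out the protocol.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .types import LABEL_ORDER

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """Per-label TP/FP/FN/TN over a fixed set of scored notes."""

    labels: tuple[str, ...]
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n_notes(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])


def _as_matrix(d: Mapping[str, Sequence[int]] | np.ndarray, ids: Sequence[str]) -> np.ndarray:
    if isinstance(d, np.ndarray):
        return d
    return np.array([d[i] for i in ids], dtype=int)


def confusion(
    pred: Mapping[str, Sequence[int]],
    gold: Mapping[str, Sequence[int]],
    labels: tuple[str, ...] = LABEL_ORDER,
) -> ConfusionCounts:
    """Exact per-label confusion counts; pred and gold map note_id -> quintet."""
    only_pred = sorted(set(pred) - set(gold))
    only_gold = sorted(set(gold) - set(pred))
    if only_pred or only_gold:
        raise KeyError(
            f"note id mismatch: only in pred {only_pred[:5]}, only in gold {only_gold[:5]}"
        )
    ids = sorted(pred)
    P = _as_matrix(pred, ids)
    G = _as_matrix(gold, ids)
    if P.shape != G.shape or P.shape[1] != len(labels):
        raise ValueError(f"quintet shape mismatch: pred {P.shape}, gold {G.shape}")
    tp = ((P == 1) & (G == 1)).sum(axis=0)
    fp = ((P == 1) & (G == 0)).sum(axis=0)
    fn = ((P == 0) & (G == 1)).sum(axis=0)
    tn = ((P == 0) & (G == 0)).sum(axis=0)
    return ConfusionCounts(tuple(labels), tp, fp, fn, tn)


def _prf(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    # zero-denominator convention: the metric is 0 (logged by callers)
    p = float(tp / (tp + fp)) if tp + fp > 0 else 0.0
    r = float(tp / (tp + fn)) if tp + fn > 0 else 0.0
    f = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f


def aggregate(counts: ConfusionCounts, mode: str) -> tuple[float, float, float]:
    """(precision, recall, F1) under 'micro' or 'macro' averaging."""
    if mode == "micro":
        res = _prf(counts.tp.sum(), counts.fp.sum(), counts.fn.sum())
    elif mode == "macro":
        per = [
            _prf(counts.tp[i], counts.fp[i], counts.fn[i])
            for i in range(len(counts.labels))
        ]
        res = tuple(float(np.mean([x[k] for x in per])) for k in range(3))  # type: ignore[assignment]
    else:
        raise ValueError(f"mode must be 'micro' or 'macro', got {mode!r}")
    if 0.0 in res:
        logger.debug("zero-valued metric under %s averaging (zero-denominator convention)", mode)
    return res  # type: ignore[return-value]


def per_label_metrics(counts: ConfusionCounts) -> dict[str, dict[str, float]]:
    out = {}
    for i, lab in enumerate(counts.labels):
        p, r, f = _prf(counts.tp[i], counts.fp[i], counts.fn[i])
        n = counts.tp[i] + counts.fp[i] + counts.fn[i] + counts.tn[i]
        acc = (counts.tp[i] + counts.tn[i]) / n if n else 0.0
        out[lab] = {"precision": p, "recall": r, "f1": f, "accuracy": float(acc)}
    return out


def accuracy(
    pred: Mapping[str, Sequence[int]],
    gold: Mapping[str, Sequence[int]],
    mode: str = "per_decision",
) -> float:
    """Per-decision accuracy (flattened note x label grid) or subset accuracy."""
    ids = sorted(pred)
    if sorted(gold) != ids:
        raise KeyError("pred and gold must cover the same note ids")
    P, G = _as_matrix(pred, ids), _as_matrix(gold, ids)
    if mode == "per_decision":
        return float((P == G).mean())
    if mode == "subset":
        return float((P == G).all(axis=1).mean())
    raise ValueError(f"mode must be 'per_decision' or 'subset', got {mode!r}")


def roc(scores: Sequence[float], gold: Sequence[int]) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over all score thresholds and the trapezoid AUC.

    Requires at least one positive and one negative; the trapezoid AUC equals
    the pairwise concordance probability (ties counted half).
    """
    s = np.asarray(scores, dtype=float)
    g = np.asarray(gold, dtype=int)
    n_pos, n_neg = int(g.sum()), int((1 - g).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: need at least one positive and one negative")
    order = np.argsort(-s, kind="stable")
    s_sorted, g_sorted = s[order], g[order]
    tps = np.cumsum(g_sorted)
    fps = np.cumsum(1 - g_sorted)
    # collapse runs of equal scores to threshold points
    distinct = np.where(np.diff(s_sorted))[0]
    idx = np.concatenate([distinct, [len(s_sorted) - 1]])
    tpr = np.concatenate([[0.0], tps[idx] / n_pos])
    fpr = np.concatenate([[0.0], fps[idx] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class MetricReport:
    """Full evaluation of one prediction set against gold."""

    per_label: dict[str, dict[str, float]]
    micro: dict[str, float]
    macro: dict[str, float]
    accuracy: float
    subset_accuracy: float
    auc: dict[str, Optional[float]] = field(default_factory=dict)
    roc_points: dict[str, list[list[float]]] = field(default_factory=dict)
    n_notes: int = 0

    def to_dict(self) -> dict:
        return {
            "per_label": self.per_label,
            "micro": self.micro,
            "macro": self.macro,
            "accuracy": self.accuracy,
            "subset_accuracy": self.subset_accuracy,
            "auc": self.auc,
            "n_notes": self.n_notes,
        }


def evaluate(
    pred: Mapping[str, Sequence[int]],
    gold: Mapping[str, Sequence[int]],
    scores: Optional[Mapping[str, Sequence[float]]] = None,
    labels: tuple[str, ...] = LABEL_ORDER,
    keep_roc_points: bool = False,
) -> MetricReport:
    counts = confusion(pred, gold, labels)
    micro = dict(zip(("precision", "recall", "f1"), aggregate(counts, "micro")))
    macro = dict(zip(("precision", "recall", "f1"), aggregate(counts, "macro")))
    report = MetricReport(
        per_label=per_label_metrics(counts),
        micro=micro,
        macro=macro,
        accuracy=accuracy(pred, gold, "per_decision"),
        subset_accuracy=accuracy(pred, gold, "subset"),
        n_notes=counts.n_notes,
    )
    if scores is not None:
        ids = sorted(pred)
        S = np.array([scores[i] for i in ids], dtype=float)
        G = _as_matrix(gold, ids)
        for j, lab in enumerate(labels):
            if G[:, j].min() == G[:, j].max():
                report.auc[lab] = None  # degenerate label: AUC undefined
                continue
            points, auc_val = roc(S[:, j], G[:, j])
            report.auc[lab] = auc_val
            if keep_roc_points:
                report.roc_points[lab] = points.tolist()
    return report


def aggregate_runs(values: Sequence[float]) -> tuple[float, float]:
    """Sample mean and sample sd (n-1 denominator) over repeated runs."""
    if len(values) < 2:
        raise ValueError("aggregate_runs requires at least 2 runs")
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))


def summarize_runs(reports: Sequence[MetricReport]) -> dict[str, dict[str, float]]:
    """Mean +/- sd of the headline metrics across runs."""
    if len(reports) < 2:
        raise ValueError("summarize_runs requires at least 2 reports")
    out: dict[str, dict[str, float]] = {}
    flat = {
        "accuracy": [r.accuracy for r in reports],
        "micro_f1": [r.micro["f1"] for r in reports],
        "micro_precision": [r.micro["precision"] for r in reports],
        "micro_recall": [r.micro["recall"] for r in reports],
        "macro_f1": [r.macro["f1"] for r in reports],
        "macro_precision": [r.macro["precision"] for r in reports],
        "macro_recall": [r.macro["recall"] for r in reports],
    }
    for name, vals in flat.items():
        m, sd = aggregate_runs(vals)
        out[name] = {"mean": m, "sd": sd, "n_runs": len(vals)}
    return out


def compare_configs(samples_a: Sequence[float], samples_b: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t-test between run-level metric values.

    Degenerate case: both samples constant with equal means -> (0, 1).
    """
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("compare_configs requires at least 2 samples per side")
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    from scipy import stats

    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
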