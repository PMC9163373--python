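"""Pipeline orchestration: dataset splitting, seed derivation, end-to-end runs.

A single global seed fans out to per-stage seeds through a stable hash of the
stage name, so any stage can be rerun in isolation with the same randomness.
An end-to-end run writes a self-describing run directory: corpus, note
labels, patient table, metric report, association results and a manifest
with the config hash.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .types import AdmissionNote, FamilyHistoryLabel

logger = logging.getLogger(__name__)


def derive_seed(master: int, stage: str) -> int:
    """Per-stage seed: stable digest of (master seed, stage name), below 2^31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _largest_remainder_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [n * f for f in fractions]
    sizes = [int(x) for x in raw]
    for i in sorted(range(len(raw)), key=lambda i: raw[i] - sizes[i], reverse=True):
        if sum(sizes) == n:
            break
        sizes[i] += 1
    return sizes


def split_dataset(
    notes: Sequence[AdmissionNote],
    fractions: Sequence[float] = (0.64, 0.16, 0.20),
    seed: int = 0,
    group_by_patient: bool = False,
) -> dict[str, list[AdmissionNote]]:
    """Random train/val/test partition with largest-remainder rounded sizes.

    With ``group_by_patient`` no patient's notes span two splits (sizes are
    then approximate: whole patients are assigned greedily to the split whose
    quota has the most room left).
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three positive values summing to 1")
    if len(notes) < 3:
        raise ValueError("need at least 3 notes to split")
    rng = np.random.default_rng(seed)
    names = ("train", "val", "test")
    if not group_by_patient:
        order = rng.permutation(len(notes))
        sizes = _largest_remainder_sizes(len(notes), fractions)
        out, pos = {}, 0
        for name, size in zip(names, sizes):
            out[name] = [notes[i] for i in order[pos : pos + size]]
            pos += size
        return out
    patients: dict[str, list[AdmissionNote]] = {}
    for n in notes:
        patients.setdefault(n.patient_id, []).append(n)
    pids = list(patients)
    order = rng.permutation(len(pids))
    targets = _largest_remainder_sizes(len(notes), fractions)
    out = {name: [] for name in names}
    counts = {name: 0 for name in names}
    for i in order:
        group = patients[pids[i]]
        name = max(names, key=lambda s: targets[names.index(s)] - counts[s])
        out[name].extend(group)
        counts[name] += len(group)
    return out


@dataclass
class PipelineConfig:
    """Configuration for an end-to-end run."""

    engine: str = "annotator"  # annotator | classifier | hybrid
    lexicon_id: str = "zh"
    scope: str = "section"
    hybrid_policy: str = "rule_and"
    split_fractions: tuple[float, float, float] = (0.64, 0.16, 0.20)
    n_runs: int = 5
    seed: int = 0
    n_patients: int = 500  # used when synthesizing the corpus
    corpus_path: Optional[str] = None  # read instead of synthesizing when set
    classifier_overrides: dict = field(default_factory=dict)
    synth_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "engine": self.engine,
            "lexicon_id": self.lexicon_id,
            "scope": self.scope,
            "hybrid_policy": self.hybrid_policy,
            "split_fractions": list(self.split_fractions),
            "n_runs": self.n_runs,
            "seed": self.seed,
            "n_patients": self.n_patients,
            "corpus_path": self.corpus_path,
            "classifier_overrides": self.classifier_overrides,
            "synth_overrides": self.synth_overrides,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Synthesize/load a corpus, label it, merge per patient, evaluate and analyze.

    Deterministic for a fixed config; each artifact records the producing
    stage, and the manifest records the config hash and per-stage seeds.
    """
    from . import association, corpus as corpus_io
    from .annotate import annotate_corpus
    from .lexicon import load_lexicon
    from .merge import build_patient_table, patient_table_to_frame
    from .synth import SyntheticCorpusConfig, generate_cohort

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
        "status": "running",
    }
    failed_marker = out_dir / "FAILED"
    if config.engine not in ("annotator", "classifier", "hybrid"):
        raise ValueError(f"unknown engine {config.engine!r}")

    try:
        lexicon = load_lexicon(config.lexicon_id)  # fail fast on a bad lexicon path

        if config.corpus_path:
            notes = corpus_io.read_corpus(config.corpus_path)
        else:
            synth_seed = derive_seed(config.seed, "synth")
            scfg = SyntheticCorpusConfig(
                n_patients=config.n_patients, lexicon_id=config.lexicon_id,
                seed=synth_seed, **config.synth_overrides,
            )
            notes, _ = generate_cohort(scfg, lexicon)
            manifest["stages"]["synth"] = {"seed": synth_seed, "n_notes": len(notes)}
        corpus_io.write_corpus(notes, out_dir / "corpus.jsonl")

        rule_records = annotate_corpus(notes, lexicon, scope=config.scope)
        by_note_events = {
            r["note_id"]: r["events"] for r in rule_records
        }
        if config.engine == "annotator":
            label_records = rule_records
        else:
            from .classifier import ClassifierConfig, evaluate_on, hybrid_postfilter, train
            from .types import FamilyHistoryEvent

            ccfg = ClassifierConfig(
                seed=derive_seed(config.seed, "train"),
                split_fractions=config.split_fractions,
                **config.classifier_overrides,
            )
            model, splits = train(notes, ccfg)
            (out_dir / "model").mkdir(exist_ok=True)
            model.save(out_dir / "model")
            report = evaluate_on(model, splits["test"])
            (out_dir / "metrics.json").write_text(json.dumps(report.to_dict(), indent=1))
            probs = model.predict_proba([n.text for n in notes])
            if config.engine == "hybrid":
                events_per_note = [
                    [FamilyHistoryEvent.from_dict(e) for e in by_note_events[n.note_id]]
                    for n in notes
                ]
                labels = hybrid_postfilter(
                    probs, events_per_note, policy=config.hybrid_policy,
                    threshold=ccfg.decision_threshold,
                )
            else:
                labels = (probs >= ccfg.decision_threshold).astype(int)
            label_records = [
                {
                    "note_id": n.note_id,
                    "patient_id": n.patient_id,
                    "label": dict(zip(FamilyHistoryLabel.zeros().to_dict(), row.tolist())),
                    "events": by_note_events[n.note_id],
                    "probabilities": probs[i].tolist(),
                }
                for i, (n, row) in enumerate(zip(notes, labels))
            ]
        corpus_io.write_jsonl(label_records, out_dir / "labels.jsonl")

        note_labels = {
            r["note_id"]: FamilyHistoryLabel.from_dict(r["label"]) for r in label_records
        }
        note_degrees = {
            r["note_id"]: [e["kinship_degree"] for e in r["events"]] for r in label_records
        }
        patients = build_patient_table(notes, note_labels, note_degrees)
        patient_table_to_frame(patients).to_csv(out_dir / "patients.csv", index=False)

        assoc = association.analyze(patients)
        (out_dir / "association.json").write_text(json.dumps(assoc, indent=1))

        manifest["status"] = "ok"
        manifest["stages"]["label"] = {"engine": config.engine, "n_notes": len(notes)}
        manifest["stages"]["merge"] = {"n_patients": len(patients)}
        if failed_marker.exists():
            failed_marker.unlink()
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        failed_marker.write_text(manifest["error"])
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir
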