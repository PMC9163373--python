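"""Corpus serialization: UTF-8 line-delimited JSON, one admission note per line."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

from .types import AdmissionNote


class CorpusParseError(ValueError):
    """Raised when a corpus line cannot be parsed; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


def write_corpus(notes: Iterable[AdmissionNote], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for note in notes:
            fh.write(json.dumps(note.to_dict(), ensure_ascii=False) + "\n")


def read_corpus(path: str | Path) -> list[AdmissionNote]:
    notes: list[AdmissionNote] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                notes.append(AdmissionNote.from_dict(json.loads(line)))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise CorpusParseError(i, str(exc)) from exc
    return notes


def write_jsonl(records: Iterable[dict], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_jsonl(path: str | Path) -> list[dict]:
    out: list[dict] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                out.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise CorpusParseError(i, str(exc)) from exc
    return out
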