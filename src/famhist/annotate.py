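"""Rule-based family-history annotation.

The annotator mirrors how clinicians structure admission notes: a section
cue (e.g. 家族史) opens the family-history sentence, inside which kinship
terms precede the disease they qualify.  Extraction proceeds in four steps:

1. dictionary longest-match segmentation of the text into tokens with
   character offsets;
2. location of the family-history section (first section cue up to the next
   sentence terminator);
3. matching of disease terms inside the scope, each attached to the nearest
   preceding kinship term within the same sentence, skipping clauses that
   contain a negation cue;
4. reduction of the extracted events to the quintet label (an indicator is
   1 iff some event carries that disease category).

Negation scope is the comma/period-delimited clause containing the cue.
An external segmenter (e.g. jieba) may be registered under its own
tokenizer id; the dictionary tokenizer is the default and has no external
dependency.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

from .lexicon import Lexicon
from .types import AdmissionNote, FamilyHistoryEvent, FamilyHistoryLabel, LABEL_ORDER

SENTENCE_TERMINATORS = set("。.!?！？\n")
CLAUSE_DELIMITERS = SENTENCE_TERMINATORS | set("，,；;、:：")


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int


TokenizerFn = Callable[[str, Lexicon], list[Token]]
_TOKENIZERS: dict[str, TokenizerFn] = {}


def register_tokenizer(tokenizer_id: str, fn: TokenizerFn) -> None:
    _TOKENIZERS[tokenizer_id] = fn


def _longest_match(text: str, lexicon: Lexicon) -> list[Token]:
    terms = lexicon.all_terms() | set(lexicon.section_cues)
    by_length: dict[int, set[str]] = {}
    for t in terms:
        by_length.setdefault(len(t), set()).add(t)
    lengths = sorted(by_length, reverse=True)
    tokens: list[Token] = []
    i, n = 0, len(text)
    while i < n:
        for L in lengths:
            if L > 1 and i + L <= n and text[i : i + L] in by_length[L]:
                tokens.append(Token(text[i : i + L], i, i + L))
                i += L
                break
        else:
            tokens.append(Token(text[i], i, i + 1))
            i += 1
    return tokens


register_tokenizer("longest_match", _longest_match)


def _jieba_tokenizer(text: str, lexicon: Lexicon) -> list[Token]:  # pragma: no cover
    import jieba

    tk = jieba.Tokenizer()
    for term in lexicon.all_terms() | set(lexicon.section_cues):
        tk.add_word(term)
    return [Token(w, s, e) for w, s, e in tk.tokenize(text)]


register_tokenizer("jieba", _jieba_tokenizer)


def segment(text: str, lexicon: Lexicon, tokenizer_id: str = "longest_match") -> list[Token]:
    """Segment ``text`` into tokens with 0-based half-open character offsets.

    The concatenation of token surfaces reconstructs the input; offsets are
    sorted and non-overlapping.  Empty text yields an empty sequence.
    """
    if tokenizer_id not in _TOKENIZERS:
        raise KeyError(
            f"unknown tokenizer_id {tokenizer_id!r}; registered: {sorted(_TOKENIZERS)}"
        )
    if not text:
        return []
    return _TOKENIZERS[tokenizer_id](text, lexicon)


def locate_family_history(text: str, lexicon: Lexicon) -> Optional[tuple[int, int]]:
    """Span from the first section cue to the next sentence boundary, or None."""
    starts = [text.find(cue) for cue in lexicon.section_cues]
    starts = [s for s in starts if s >= 0]
    if not starts:
        return None
    start = min(starts)
    for j in range(start, len(text)):
        if text[j] in SENTENCE_TERMINATORS:
            return (start, j + 1)
    return (start, len(text))


def extract_events(
    text: str,
    lexicon: Lexicon,
    scope: str = "section",
    tokenizer_id: str = "longest_match",
) -> list[FamilyHistoryEvent]:
    """Extract family-history events from ``text``.

    ``scope``: "section" restricts matching to the located family-history
    span (falling back to the full text when no section cue is present);
    "full" always scans the whole text.
    """
    if scope not in ("section", "full"):
        raise ValueError(f"scope must be 'section' or 'full', got {scope!r}")
    offset = 0
    sub = text
    if scope == "section":
        span = locate_family_history(text, lexicon)
        if span is not None:
            offset, end = span
            sub = text[offset:end]
    tokens = segment(sub, lexicon, tokenizer_id)

    # clause/sentence ids per token; clauses holding a negation cue are dead
    sentence_id, clause_id = 0, 0
    ids: list[tuple[int, int]] = []
    negated_clauses: set[int] = set()
    for tok in tokens:
        ids.append((sentence_id, clause_id))
        if tok.surface in lexicon.negation_cues:
            negated_clauses.add(clause_id)
        if tok.surface and tok.surface[-1] in SENTENCE_TERMINATORS:
            sentence_id += 1
            clause_id += 1
        elif tok.surface and tok.surface[-1] in CLAUSE_DELIMITERS:
            clause_id += 1

    events: list[FamilyHistoryEvent] = []
    for idx, tok in enumerate(tokens):
        code = lexicon.disease_terms.get(tok.surface)
        if code is None or ids[idx][1] in negated_clauses:
            continue
        relation, degree = "unknown", "unknown"
        for j in range(idx - 1, -1, -1):
            if ids[j][0] != ids[idx][0]:
                break
            if tokens[j].surface in lexicon.kinship_terms:
                relation = tokens[j].surface
                degree = lexicon.kinship_terms[tokens[j].surface][1]
                break
        events.append(
            FamilyHistoryEvent(
                disease_code=code,
                relation_term=relation,
                kinship_degree=degree,
                span=(offset + tok.start, offset + tok.end),
            )
        )
    return events


def events_to_label(events: Iterable[FamilyHistoryEvent]) -> FamilyHistoryLabel:
    """Quintet with indicator 1 iff some event carries that disease category.

    Idempotent under event duplication and order-invariant.
    """
    codes = {e.disease_code for e in events}
    return FamilyHistoryLabel(tuple(int(c in codes) for c in LABEL_ORDER))  # type: ignore[arg-type]


def kinship_degree(relation_term: str, lexicon: Lexicon) -> str:
    """Consanguinity degree of a relation term; unknown terms map to 'unknown'."""
    entry = lexicon.kinship_terms.get(relation_term)
    return entry[1] if entry is not None else "unknown"


def annotate_note(
    note: AdmissionNote,
    lexicon: Lexicon,
    scope: str = "section",
    tokenizer_id: str = "longest_match",
) -> tuple[FamilyHistoryLabel, list[FamilyHistoryEvent]]:
    events = extract_events(note.text, lexicon, scope=scope, tokenizer_id=tokenizer_id)
    return events_to_label(events), events


def annotate_corpus(
    notes: Sequence[AdmissionNote],
    lexicon: Lexicon,
    scope: str = "section",
    tokenizer_id: str = "longest_match",
) -> list[dict]:
    """Annotate every note; returns JSONL-ready records."""
    out = []
    for note in notes:
        label, events = annotate_note(note, lexicon, scope=scope, tokenizer_id=tokenizer_id)
        out.append(
            {
                "note_id": note.note_id,
                "patient_id": note.patient_id,
                "label": label.to_dict(),
                "events": [e.to_dict() for e in events],
            }
        )
    return out
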