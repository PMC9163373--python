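"""Lexicons: the dictionaries driving rule-based extraction and note synthesis.

A lexicon maps surface terms to the five disease categories, kinship terms to
(canonical relation, consanguinity degree), and carries negation cues plus the
section-marker phrases that open the family-history part of a note.

Two lexicons ship with the package:

``zh``
    Simplified-Chinese terms matching the clinical setting the pipeline
    targets (admission notes with a 家族史 section).
``debug``
    A romanized set producing readable English-like notes, used throughout
    the test suite so fixtures are inspectable.

The default kinship-degree map follows the standard consanguinity
convention: first degree = parents/children/full siblings; second degree =
grandparents/aunts/uncles/nieces/nephews/half-siblings; third degree = first
cousins/great-grandparents.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .types import KINSHIP_DEGREES, LABEL_ORDER

BUILTIN_LEXICONS = ("zh", "debug")


class LexiconError(ValueError):
    """Raised for malformed lexicon files or unknown terms."""


@dataclass
class Lexicon:
    """Term dictionaries for one language/template family."""

    lexicon_id: str
    disease_terms: dict[str, str]  # surface -> disease code
    kinship_terms: dict[str, tuple[str, str]]  # surface -> (relation, degree)
    negation_cues: set[str]
    section_cues: list[str]
    _term_index: dict[int, set[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for term, code in self.disease_terms.items():
            if code not in LABEL_ORDER:
                raise LexiconError(f"disease term {term!r} maps to unknown code {code!r}")
        for term, (_, degree) in self.kinship_terms.items():
            if degree not in KINSHIP_DEGREES:
                raise LexiconError(f"kinship term {term!r} has unknown degree {degree!r}")
        if not self.section_cues:
            raise LexiconError("lexicon must provide at least one section cue")

    @property
    def max_term_length(self) -> int:
        terms = list(self.disease_terms) + list(self.kinship_terms) + list(self.negation_cues)
        return max((len(t) for t in terms), default=1)

    def all_terms(self) -> set[str]:
        return set(self.disease_terms) | set(self.kinship_terms) | set(self.negation_cues)

    def disease_surfaces(self, code: str) -> list[str]:
        """Surface forms for a disease code (first entry = canonical)."""
        out = [t for t, c in self.disease_terms.items() if c == code]
        if not out:
            raise LexiconError(f"lexicon {self.lexicon_id!r} has no surface for {code!r}")
        return out

    def kinship_surfaces(self, degree: str) -> list[str]:
        out = [t for t, (_, d) in self.kinship_terms.items() if d == degree]
        if not out:
            raise LexiconError(f"lexicon {self.lexicon_id!r} has no kinship term of degree {degree!r}")
        return out

    def to_dict(self) -> dict:
        return {
            "lexicon_id": self.lexicon_id,
            "disease_terms": dict(self.disease_terms),
            "kinship_terms": {t: list(v) for t, v in self.kinship_terms.items()},
            "negation_cues": sorted(self.negation_cues),
            "section_cues": list(self.section_cues),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Lexicon":
        try:
            return cls(
                lexicon_id=d.get("lexicon_id", "custom"),
                disease_terms=dict(d["disease_terms"]),
                kinship_terms={t: (v[0], v[1]) for t, v in d["kinship_terms"].items()},
                negation_cues=set(d["negation_cues"]),
                section_cues=list(d["section_cues"]),
            )
        except KeyError as exc:  # pragma: no cover - defensive
            raise LexiconError(f"lexicon file missing field {exc}") from exc


def load_lexicon(name_or_path: str | Path) -> Lexicon:
    """Load a built-in lexicon by id (``zh``/``debug``) or a JSON file by path."""
    if isinstance(name_or_path, str) and name_or_path in BUILTIN_LEXICONS:
        ref = resources.files("famhist.data") / f"lexicon_{name_or_path}.json"
        data = json.loads(ref.read_text(encoding="utf-8"))
        return Lexicon.from_dict(data)
    path = Path(name_or_path)
    if not path.exists():
        raise LexiconError(f"lexicon {name_or_path!r} is neither a built-in id {BUILTIN_LEXICONS} nor a file")
    return Lexicon.from_dict(json.loads(path.read_text(encoding="utf-8")))


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    Path(path).write_text(json.dumps(lexicon.to_dict(), ensure_ascii=False, indent=1), encoding="utf-8")
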