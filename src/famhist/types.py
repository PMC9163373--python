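"""Core domain types shared across the pipeline.

The unit of text is an admission note: one hospitalization record whose
free-text paragraph mixes the patient's family history with present illness,
past history and physical-exam findings.  Family-history mentions are coded
into five ICD-10 categories — schizophrenia (F20), depressive episode (F32),
bipolar disorder (F31), other non-organic mental disorders (F28) and
unspecified non-organic psychosis (F29) — and every note carries a quintet of
binary indicators over those categories, in that fixed order.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

#: Fixed key order of the quintet label.
LABEL_ORDER: tuple[str, ...] = ("F20", "F32", "F31", "F28", "F29")

#: Diagnosis codes admitted into the cohort (first diagnosis at admission).
DIAGNOSIS_CODES: tuple[str, ...] = ("F31", "F32", "F33")

#: Mapping of first-diagnosis code to the two-group analysis outcome.
DIAGNOSIS_GROUP = {"F32": "MDD", "F33": "MDD", "F31": "BD"}

KINSHIP_DEGREES = ("first", "second", "third", "unknown")


@dataclass(frozen=True)
class FamilyHistoryLabel:
    """Quintet of binary indicators keyed (F20, F32, F31, F28, F29)."""

    indicators: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.indicators) != 5 or any(v not in (0, 1) for v in self.indicators):
            raise ValueError(f"quintet must be five binary indicators, got {self.indicators!r}")

    @classmethod
    def zeros(cls) -> "FamilyHistoryLabel":
        return cls((0, 0, 0, 0, 0))

    @classmethod
    def from_codes(cls, codes: Sequence[str]) -> "FamilyHistoryLabel":
        unknown = set(codes) - set(LABEL_ORDER)
        if unknown:
            raise ValueError(f"unknown disease codes: {sorted(unknown)}")
        return cls(tuple(int(c in set(codes)) for c in LABEL_ORDER))  # type: ignore[arg-type]

    @classmethod
    def from_dict(cls, d: dict) -> "FamilyHistoryLabel":
        return cls(tuple(int(d[c]) for c in LABEL_ORDER))  # type: ignore[arg-type]

    def to_dict(self) -> dict:
        return dict(zip(LABEL_ORDER, self.indicators))

    def __or__(self, other: "FamilyHistoryLabel") -> "FamilyHistoryLabel":
        return FamilyHistoryLabel(tuple(a | b for a, b in zip(self.indicators, other.indicators)))  # type: ignore[arg-type]

    def __getitem__(self, code: str) -> int:
        return self.indicators[LABEL_ORDER.index(code)]

    @property
    def any_positive(self) -> bool:
        return any(self.indicators)


@dataclass(frozen=True)
class FamilyHistoryEvent:
    """One extracted mention: a relative linked to a disease category.

    ``span`` is a 0-based half-open character interval into the note text
    covering the disease term of the mention.
    """

    disease_code: str
    relation_term: str
    kinship_degree: str
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.disease_code not in LABEL_ORDER:
            raise ValueError(f"unknown disease code {self.disease_code!r}")
        if self.kinship_degree not in KINSHIP_DEGREES:
            raise ValueError(f"unknown kinship degree {self.kinship_degree!r}")
        if not (0 <= self.span[0] < self.span[1]):
            raise ValueError(f"invalid span {self.span!r}")

    def to_dict(self) -> dict:
        return {
            "disease_code": self.disease_code,
            "relation_term": self.relation_term,
            "kinship_degree": self.kinship_degree,
            "span": list(self.span),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FamilyHistoryEvent":
        return cls(d["disease_code"], d["relation_term"], d["kinship_degree"], tuple(d["span"]))


@dataclass
class GoldAnnotation:
    """Ground-truth annotation attached to a synthetic note."""

    label: FamilyHistoryLabel
    events: list[FamilyHistoryEvent] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"label": self.label.to_dict(), "events": [e.to_dict() for e in self.events]}

    @classmethod
    def from_dict(cls, d: dict) -> "GoldAnnotation":
        return cls(
            label=FamilyHistoryLabel.from_dict(d["label"]),
            events=[FamilyHistoryEvent.from_dict(e) for e in d.get("events", [])],
        )


@dataclass
class AdmissionNote:
    """One hospitalization record with demographics and the free-text paragraph."""

    note_id: str
    patient_id: str
    admission_year: int
    age_years: int
    gender: str
    marital_status: str
    profession: str
    first_diagnosis: str
    text: str
    gold: Optional[GoldAnnotation] = None

    def __post_init__(self) -> None:
        if self.first_diagnosis not in DIAGNOSIS_CODES:
            raise ValueError(
                f"note {self.note_id}: first_diagnosis must be one of {DIAGNOSIS_CODES}, "
                f"got {self.first_diagnosis!r}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gold"] = self.gold.to_dict() if self.gold is not None else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AdmissionNote":
        gold = d.get("gold")
        return cls(
            note_id=d["note_id"],
            patient_id=d["patient_id"],
            admission_year=int(d["admission_year"]),
            age_years=int(d["age_years"]),
            gender=d["gender"],
            marital_status=d["marital_status"],
            profession=d["profession"],
            first_diagnosis=d["first_diagnosis"],
            text=d["text"],
            gold=GoldAnnotation.from_dict(gold) if gold else None,
        )


@dataclass
class PatientRecord:
    """Per-patient merged view used by the association analysis."""

    patient_id: str
    age_years: int
    gender: str
    marital_status: str
    profession: str
    diagnosis_group: str  # "MDD" or "BD"
    merged_label: FamilyHistoryLabel
    any_family_history: int
    kinship_group: str  # "any_degree" or "not_mentioned"
    n_notes: int = 1

    def __post_init__(self) -> None:
        if self.diagnosis_group not in ("MDD", "BD"):
            raise ValueError(f"diagnosis_group must be MDD or BD, got {self.diagnosis_group!r}")
        if self.any_family_history != int(self.merged_label.any_positive):
            raise ValueError("any_family_history inconsistent with merged_label")
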