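"""Patient-level merging of note-level labels and kinship degrees.

A patient hospitalized several times has one label per admission note; the
patient-level family-history label is the bitwise OR across notes (a
category is present for the patient iff any note mentions it).  Because
mentions of second- and third-degree relatives are rare, kinship degrees are
collapsed into a single any-degree group for the association analysis.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

from .types import (
    DIAGNOSIS_GROUP,
    AdmissionNote,
    FamilyHistoryLabel,
    PatientRecord,
)


def merge_labels(labels: Sequence[FamilyHistoryLabel]) -> FamilyHistoryLabel:
    """Componentwise OR of note-level quintets (commutative, associative, idempotent)."""
    if not labels:
        raise ValueError("merge_labels requires at least one label")
    out = labels[0]
    for lab in labels[1:]:
        out = out | lab
    return out


def merge_kinship(degrees: Iterable[str]) -> str:
    """'any_degree' if any element is a known degree, else 'not_mentioned'."""
    return (
        "any_degree"
        if any(d in ("first", "second", "third") for d in degrees)
        else "not_mentioned"
    )


def build_patient_table(
    notes: Sequence[AdmissionNote],
    note_labels: Mapping[str, FamilyHistoryLabel],
    note_degrees: Optional[Mapping[str, Iterable[str]]] = None,
    strict_diagnosis: bool = False,
) -> list[PatientRecord]:
    """One merged record per distinct patient.

    ``note_labels`` maps note_id -> quintet; every labelled note must exist in
    ``notes``.  The diagnosis group is taken from the earliest admission's
    first-diagnosis code (F32/F33 -> MDD, F31 -> BD); with
    ``strict_diagnosis`` a patient whose admissions disagree on the code
    raises instead.  Patients none of whose notes are labelled do not appear.
    """
    by_id = {n.note_id: n for n in notes}
    unknown = sorted(set(note_labels) - set(by_id))
    if unknown:
        raise KeyError(f"labels refer to unknown note ids: {unknown[:5]}")

    groups: dict[str, list[AdmissionNote]] = {}
    for note in notes:
        if note.note_id in note_labels:
            groups.setdefault(note.patient_id, []).append(note)

    records: list[PatientRecord] = []
    for pid in sorted(groups):
        pnotes = sorted(groups[pid], key=lambda n: (n.admission_year, n.note_id))
        codes = {n.first_diagnosis for n in pnotes}
        if strict_diagnosis and len(codes) > 1:
            raise ValueError(f"patient {pid} has conflicting first diagnoses: {sorted(codes)}")
        first = pnotes[0]
        merged = merge_labels([note_labels[n.note_id] for n in pnotes])
        degrees: list[str] = []
        if note_degrees is not None:
            for n in pnotes:
                degrees.extend(note_degrees.get(n.note_id, ()))
        kinship_group = merge_kinship(degrees) if note_degrees is not None else (
            "any_degree" if merged.any_positive else "not_mentioned"
        )
        records.append(
            PatientRecord(
                patient_id=pid,
                age_years=first.age_years,
                gender=first.gender,
                marital_status=first.marital_status,
                profession=first.profession,
                diagnosis_group=DIAGNOSIS_GROUP[first.first_diagnosis],
                merged_label=merged,
                any_family_history=int(merged.any_positive),
                kinship_group=kinship_group,
                n_notes=len(pnotes),
            )
        )
    return records


def patient_table_to_frame(records: Sequence[PatientRecord]):
    """Patient records as a pandas DataFrame (one row per patient)."""
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "age_years": r.age_years,
            "gender": r.gender,
            "marital_status": r.marital_status,
            "profession": r.profession,
            "diagnosis_group": r.diagnosis_group,
            "any_family_history": r.any_family_history,
            "kinship_group": r.kinship_group,
            "n_notes": r.n_notes,
        }
        for code, v in r.merged_label.to_dict().items():
            row[f"fh_{code}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
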