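"""Domain types for the EMR event streams and flat-file interchange I/O.

A surveillance cohort is a set of linked, per-patient event streams pulled
from an EMR extract: demographics and comorbidity indicators, index CIED
procedures (the day-0 anchors), diagnosis events, pharmacy fills,
microbiology orders/results, vital signs, and free-text clinical notes.
Everything downstream (flag extraction, triage, evaluation) consumes a
validated :class:`Cohort`.

Interchange format: one CSV per structured stream plus ``notes.jsonl``
(one JSON object per line, because note text contains delimiters and
newlines).  Column schemas are documented in ``docs/SCHEMA.md`` and enforced
at read time with line-numbered diagnostics.  Dates are ISO-8601 calendar
dates; time of day is ignored throughout because every surveillance window
is day-granular.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator

#: Comorbidity indicators every PatientRecord must carry.
COMORBIDITIES: tuple[str, ...] = (
    "congestive_heart_failure",
    "solid_tumor_without_metastasis",
    "coagulopathy",
    "diabetes_uncomplicated",
    "diabetes_complicated",
    "obesity",
    "pulmonary_circulation_disease",
    "renal_failure",
)

Sex = Literal["male", "female", "unknown"]
SpecimenClass = Literal["blood", "cardiac", "miscellaneous", "other"]
InfectionType = Literal["pocket", "endocarditis_or_lead", "cellulitis_only", "none"]


class SchemaError(ValueError):
    """A stream file is missing required columns or has malformed rows."""


class ReferentialError(ValueError):
    """An event stream row references a patient or procedure that does not exist."""


class PatientRecord(BaseModel):
    patient_id: str
    age: int = Field(ge=0)
    sex: Sex = "unknown"
    race: str = "unknown"
    ethnicity: str = "unknown"
    comorbidities: dict[str, bool]
    death_date: Optional[date] = None

    @field_validator("comorbidities")
    @classmethod
    def _complete_comorbidities(cls, v: dict[str, bool]) -> dict[str, bool]:
        missing = [c for c in COMORBIDITIES if c not in v]
        if missing:
            raise ValueError(f"missing comorbidity indicators: {missing}")
        return v


class ProcedureRecord(BaseModel):
    """One index CIED procedure; ``procedure_date`` is day 0 for every window."""

    procedure_id: str
    patient_id: str
    procedure_date: date
    facility_id: str = "unknown"
    emergent: bool = False


class DiagnosisEvent(BaseModel):
    patient_id: str
    code: str
    event_date: date

    @field_validator("code")
    @classmethod
    def _normalize_code(cls, v: str) -> str:
        v = v.strip().upper()
        if not v:
            raise ValueError("diagnosis code must be non-empty")
        return v


class PharmacyOrder(BaseModel):
    patient_id: str
    drug_name: str
    fill_date: date
    days_supplied: int = Field(ge=1)


class MicrobiologyRecord(BaseModel):
    patient_id: str
    order_date: date
    specimen_class: SpecimenClass
    culture_positive: bool
    susceptibility_tested: bool
    result_text: str = ""


class VitalSign(BaseModel):
    """A temperature measurement.  Values outside the physiologic range
    30-45 degC are rejected at read time as data-entry errors."""

    patient_id: str
    measure: Literal["temperature_c"] = "temperature_c"
    value: float
    measured_at: date

    @field_validator("value")
    @classmethod
    def _physiologic(cls, v: float) -> float:
        if not (30.0 <= v <= 45.0):
            raise ValueError(f"temperature {v} degC outside physiologic range 30-45")
        return v


class ClinicalNote(BaseModel):
    note_id: str
    patient_id: str
    note_title: str
    note_date: date
    text: str = ""


class ReviewLabel(BaseModel):
    """Outcome of manual record review (or synthetic ground truth) for one
    procedure: whether a true 90-day device infection occurred, its type,
    and onset timing."""

    procedure_id: str
    reviewed: bool
    infection: bool
    infection_type: InfectionType = "none"
    present_on_admission: bool = False
    onset_day: Optional[int] = None

    @field_validator("onset_day")
    @classmethod
    def _onset_window(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and not (0 <= v <= 90):
            raise ValueError(f"onset_day {v} outside [0, 90]")
        return v

    def model_post_init(self, __context) -> None:
        if self.infection and not self.reviewed:
            raise ValueError("infection=True requires reviewed=True")
        if self.infection != (self.infection_type != "none"):
            raise ValueError("infection_type must be 'none' iff infection is False")


@dataclass
class Cohort:
    """Linked per-patient EMR streams for one surveillance cohort."""

    patients: list[PatientRecord] = field(default_factory=list)
    procedures: list[ProcedureRecord] = field(default_factory=list)
    diagnoses: list[DiagnosisEvent] = field(default_factory=list)
    pharmacy: list[PharmacyOrder] = field(default_factory=list)
    micro: list[MicrobiologyRecord] = field(default_factory=list)
    vitals: list[VitalSign] = field(default_factory=list)
    notes: list[ClinicalNote] = field(default_factory=list)

    def validate(self) -> None:
        """Check uniqueness and referential closure; raise on violation."""
        pids = [p.patient_id for p in self.patients]
        if len(set(pids)) != len(pids):
            dupes = sorted({x for x in pids if pids.count(x) > 1})
            raise ReferentialError(f"duplicate patient_id values: {dupes}")
        prids = [p.procedure_id for p in self.procedures]
        if len(set(prids)) != len(prids):
            dupes = sorted({x for x in prids if prids.count(x) > 1})
            raise ReferentialError(f"duplicate procedure_id values: {dupes}")
        nids = [n.note_id for n in self.notes]
        if len(set(nids)) != len(nids):
            raise ReferentialError("duplicate note_id values")
        known = set(pids)
        dangling: set[str] = set()
        for stream in (self.procedures, self.diagnoses, self.pharmacy,
                       self.micro, self.vitals, self.notes):
            for rec in stream:
                if rec.patient_id not in known:
                    dangling.add(rec.patient_id)
        if dangling:
            raise ReferentialError(
                f"dangling patient_id references: {sorted(dangling)}")

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def by_patient(self, stream: str) -> dict[str, list]:
        """Index one event stream by patient_id (helper for flag extraction)."""
        out: dict[str, list] = {}
        for rec in getattr(self, stream):
            out.setdefault(rec.patient_id, []).append(rec)
        return out

    def counts(self) -> dict[str, int]:
        return {
            "patients": len(self.patients),
            "procedures": len(self.procedures),
            "diagnoses": len(self.diagnoses),
            "pharmacy": len(self.pharmacy),
            "micro": len(self.micro),
            "vitals": len(self.vitals),
            "notes": len(self.notes),
        }

    def __eq__(self, other) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return all(
            getattr(self, s) == getattr(other, s)
            for s in ("patients", "procedures", "diagnoses", "pharmacy",
                      "micro", "vitals", "notes")
        )


# ---------------------------------------------------------------------------
# Flat-file I/O

_STREAM_FILES = {
    "patients": "patients.csv",
    "procedures": "procedures.csv",
    "diagnoses": "diagnoses.csv",
    "pharmacy": "pharmacy.csv",
    "micro": "micro.csv",
    "vitals": "vitals.csv",
    "notes": "notes.jsonl",
}

_PATIENT_COLUMNS = (
    ["patient_id", "age", "sex", "race", "ethnicity"]
    + list(COMORBIDITIES)
    + ["death_date"]
)
_COLUMNS = {
    "patients": _PATIENT_COLUMNS,
    "procedures": ["procedure_id", "patient_id", "procedure_date",
                   "facility_id", "emergent"],
    "diagnoses": ["patient_id", "code", "event_date"],
    "pharmacy": ["patient_id", "drug_name", "fill_date", "days_supplied"],
    "micro": ["patient_id", "order_date", "specimen_class", "culture_positive",
              "susceptibility_tested", "result_text"],
    "vitals": ["patient_id", "measure", "value", "measured_at"],
}

_TRUE = {"true", "1", "t", "yes"}
_FALSE = {"false", "0", "f", "no", ""}


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot parse boolean from {v!r}")


def _fmt_bool(b: bool) -> str:
    return "true" if b else "false"


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_cohort(directory: str | Path) -> Cohort:
    """Read a cohort from a directory of stream files.

    Every row is validated; malformed rows are collected and reported with
    file name and line number.  Cross-references are checked after parsing.
    Missing optional streams (e.g. no vitals file) are treated as empty.
    """
    directory = Path(directory)
    errors: list[str] = []
    cohort = Cohort()

    def rows(stream: str):
        path = directory / _STREAM_FILES[stream]
        if not path.exists():
            return
        df = _read_csv(path)
        missing = [c for c in _COLUMNS[stream] if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{path.name}: missing required columns {missing}")
        for i, row in enumerate(df.to_dict("records")):
            yield i + 2, row  # +2: header is line 1

    for lineno, row in rows("patients"):
        try:
            cohort.patients.append(PatientRecord(
                patient_id=row["patient_id"],
                age=int(row["age"]),
                sex=row["sex"] or "unknown",
                race=row["race"] or "unknown",
                ethnicity=row["ethnicity"] or "unknown",
                comorbidities={c: _parse_bool(row[c]) for c in COMORBIDITIES},
                death_date=date.fromisoformat(row["death_date"]) if row["death_date"] else None,
            ))
        except (ValueError, TypeError) as e:
            errors.append(f"patients.csv:{lineno}: {e}")

    for lineno, row in rows("procedures"):
        try:
            cohort.procedures.append(ProcedureRecord(
                procedure_id=row["procedure_id"],
                patient_id=row["patient_id"],
                procedure_date=date.fromisoformat(row["procedure_date"]),
                facility_id=row["facility_id"] or "unknown",
                emergent=_parse_bool(row["emergent"]),
            ))
        except (ValueError, TypeError) as e:
            errors.append(f"procedures.csv:{lineno}: {e}")

    for lineno, row in rows("diagnoses"):
        try:
            cohort.diagnoses.append(DiagnosisEvent(
                patient_id=row["patient_id"], code=row["code"],
                event_date=date.fromisoformat(row["event_date"]),
            ))
        except (ValueError, TypeError) as e:
            errors.append(f"diagnoses.csv:{lineno}: {e}")

    for lineno, row in rows("pharmacy"):
        try:
            cohort.pharmacy.append(PharmacyOrder(
                patient_id=row["patient_id"], drug_name=row["drug_name"],
                fill_date=date.fromisoformat(row["fill_date"]),
                days_supplied=int(row["days_supplied"]),
            ))
        except (ValueError, TypeError) as e:
            errors.append(f"pharmacy.csv:{lineno}: {e}")

    for lineno, row in rows("micro"):
        try:
            cohort.micro.append(MicrobiologyRecord(
                patient_id=row["patient_id"],
                order_date=date.fromisoformat(row["order_date"]),
                specimen_class=row["specimen_class"],
                culture_positive=_parse_bool(row["culture_positive"]),
                susceptibility_tested=_parse_bool(row["susceptibility_tested"]),
                result_text=row["result_text"],
            ))
        except (ValueError, TypeError) as e:
            errors.append(f"micro.csv:{lineno}: {e}")

    for lineno, row in rows("vitals"):
        try:
            cohort.vitals.append(VitalSign(
                patient_id=row["patient_id"], measure=row["measure"],
                value=float(row["value"]),
                measured_at=date.fromisoformat(row["measured_at"]),
            ))
        except (ValueError, TypeError) as e:
            errors.append(f"vitals.csv:{lineno}: {e}")

    notes_path = directory / _STREAM_FILES["notes"]
    if notes_path.exists():
        with open(notes_path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                    cohort.notes.append(ClinicalNote(
                        note_id=obj["note_id"], patient_id=obj["patient_id"],
                        note_title=obj["note_title"],
                        note_date=date.fromisoformat(obj["note_date"]),
                        text=obj.get("text", ""),
                    ))
                except (ValueError, KeyError, TypeError) as e:
                    errors.append(f"notes.jsonl:{lineno}: {e}")

    if errors:
        raise SchemaError(
            f"{len(errors)} malformed row(s):\n" + "\n".join(errors))
    cohort.validate()
    return cohort


def _sorted_records(cohort: Cohort) -> Cohort:
    iso = date.isoformat
    return Cohort(
        patients=sorted(cohort.patients, key=lambda p: p.patient_id),
        procedures=sorted(cohort.procedures, key=lambda p: p.procedure_id),
        diagnoses=sorted(cohort.diagnoses,
                         key=lambda d: (d.patient_id, iso(d.event_date), d.code)),
        pharmacy=sorted(cohort.pharmacy,
                        key=lambda o: (o.patient_id, iso(o.fill_date),
                                       o.drug_name, o.days_supplied)),
        micro=sorted(cohort.micro,
                     key=lambda m: (m.patient_id, iso(m.order_date),
                                    m.specimen_class, m.result_text,
                                    m.culture_positive, m.susceptibility_tested)),
        vitals=sorted(cohort.vitals,
                      key=lambda v: (v.patient_id, iso(v.measured_at), v.value)),
        notes=sorted(cohort.notes, key=lambda n: n.note_id),
    )


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort to a directory of stream files.

    Output is deterministic: fixed column order, rows sorted by primary id
    (then by date/value for event streams), so write -> read -> write is
    byte-identical.  Refuses to write a cohort that fails validation.
    """
    cohort.validate()
    c = _sorted_records(cohort)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def dump(stream: str, rows: Iterable[dict]) -> None:
        path = directory / _STREAM_FILES[stream]
        pd.DataFrame(list(rows), columns=_COLUMNS[stream]).to_csv(
            path, index=False, lineterminator="\n")
        paths[stream] = path

    dump("patients", (
        {"patient_id": p.patient_id, "age": p.age, "sex": p.sex,
         "race": p.race, "ethnicity": p.ethnicity,
         **{k: _fmt_bool(p.comorbidities[k]) for k in COMORBIDITIES},
         "death_date": p.death_date.isoformat() if p.death_date else ""}
        for p in c.patients))
    dump("procedures", (
        {"procedure_id": p.procedure_id, "patient_id": p.patient_id,
         "procedure_date": p.procedure_date.isoformat(),
         "facility_id": p.facility_id, "emergent": _fmt_bool(p.emergent)}
        for p in c.procedures))
    dump("diagnoses", (
        {"patient_id": d.patient_id, "code": d.code,
         "event_date": d.event_date.isoformat()}
        for d in c.diagnoses))
    dump("pharmacy", (
        {"patient_id": o.patient_id, "drug_name": o.drug_name,
         "fill_date": o.fill_date.isoformat(), "days_supplied": o.days_supplied}
        for o in c.pharmacy))
    dump("micro", (
        {"patient_id": m.patient_id, "order_date": m.order_date.isoformat(),
         "specimen_class": m.specimen_class,
         "culture_positive": _fmt_bool(m.culture_positive),
         "susceptibility_tested": _fmt_bool(m.susceptibility_tested),
         "result_text": m.result_text}
        for m in c.micro))
    dump("vitals", (
        {"patient_id": v.patient_id, "measure": v.measure, "value": v.value,
         "measured_at": v.measured_at.isoformat()}
        for v in c.vitals))

    notes_path = directory / _STREAM_FILES["notes"]
    with open(notes_path, "w", encoding="utf-8") as fh:
        for n in c.notes:
            fh.write(json.dumps(
                {"note_id": n.note_id, "patient_id": n.patient_id,
                 "note_title": n.note_title,
                 "note_date": n.note_date.isoformat(), "text": n.text},
                ensure_ascii=False, sort_keys=True) + "\n")
    paths["notes"] = notes_path
    return paths


def day_offset(event_date: date, procedure_date: date) -> int:
    """Whole-day offset of an event from the index procedure (day 0)."""
    return (event_date - procedure_date).days


def read_labels(path: str | Path) -> list[ReviewLabel]:
    """Read review labels (truth.csv format: one row per procedure)."""
    df = _read_csv(Path(path))
    out = []
    for row in df.to_dict("records"):
        out.append(ReviewLabel(
            procedure_id=row["procedure_id"],
            reviewed=_parse_bool(row["reviewed"]),
            infection=_parse_bool(row["infection"]),
            infection_type=row["infection_type"] or "none",
            present_on_admission=_parse_bool(row.get("present_on_admission", "false")),
            onset_day=int(row["onset_day"]) if row.get("onset_day") else None,
        ))
    return out


def write_labels(labels: list[ReviewLabel], path: str | Path) -> None:
    rows = [
        {"procedure_id": l.procedure_id, "reviewed": _fmt_bool(l.reviewed),
         "infection": _fmt_bool(l.infection), "infection_type": l.infection_type,
         "present_on_admission": _fmt_bool(l.present_on_admission),
         "onset_day": "" if l.onset_day is None else l.onset_day}
        for l in sorted(labels, key=lambda l: l.procedure_id)
    ]
    pd.DataFrame(rows, columns=["procedure_id", "reviewed", "infection",
                                "infection_type", "present_on_admission",
                                "onset_day"]).to_csv(
        Path(path), index=False, lineterminator="\n")
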