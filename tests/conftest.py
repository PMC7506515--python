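"""Shared fixtures: a small hand-built cohort and helpers for dated events."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from ciedwatch.emr import (
    COMORBIDITIES,
    ClinicalNote,
    Cohort,
    DiagnosisEvent,
    MicrobiologyRecord,
    PatientRecord,
    PharmacyOrder,
    ProcedureRecord,
    VitalSign,
)

DAY0 = date(2017, 1, 15)


def on_day(offset: int) -> date:
    """Calendar date at a whole-day offset from the fixture procedure day."""
    return DAY0 + timedelta(days=offset)


def make_patient(pid: str = "P1", **kw) -> PatientRecord:
    defaults = dict(
        patient_id=pid, age=70, sex="male", race="white",
        ethnicity="not_hispanic",
        comorbidities={c: False for c in COMORBIDITIES},
    )
    defaults.update(kw)
    return PatientRecord(**defaults)


def make_procedure(prid: str = "PR1", pid: str = "P1", **kw) -> ProcedureRecord:
    defaults = dict(procedure_id=prid, patient_id=pid, procedure_date=DAY0,
                    facility_id="F001", emergent=False)
    defaults.update(kw)
    return ProcedureRecord(**defaults)


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Five patients / five procedures with one event of each kind,
    including a note whose text contains a newline (round-trip hazard)."""
    patients = [make_patient(f"P{i}") for i in range(1, 6)]
    patients[1] = make_patient(
        "P2", death_date=on_day(40),
        comorbidities={**{c: False for c in COMORBIDITIES},
                       "congestive_heart_failure": True})
    procedures = [make_procedure(f"PR{i}", f"P{i}") for i in range(1, 6)]
    return Cohort(
        patients=patients,
        procedures=procedures,
        diagnoses=[DiagnosisEvent(patient_id="P1", code="T82.7XXA",
                                  event_date=on_day(30))],
        pharmacy=[PharmacyOrder(patient_id="P3", drug_name="cephalexin",
                                fill_date=on_day(10), days_supplied=7)],
        micro=[MicrobiologyRecord(patient_id="P4", order_date=on_day(20),
                                  specimen_class="blood",
                                  culture_positive=True,
                                  susceptibility_tested=True,
                                  result_text="staphylococcus aureus isolated")],
        vitals=[VitalSign(patient_id="P1", value=38.5, measured_at=on_day(5))],
        notes=[ClinicalNote(note_id="N1", patient_id="P5",
                            note_title="cardiology progress note",
                            note_date=on_day(20),
                            text="assessment:\npocket infection suspected")],
    )
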