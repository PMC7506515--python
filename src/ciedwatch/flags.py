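"""Per-procedure flag extraction: the covariate set for the triage model.

Each index procedure gets one :class:`FlagVector` of boolean/categorical
flags computed from the cohort's event streams inside fixed day windows
around the procedure date (day 0):

==========================  =====================================
flag                        window (inclusive days)
==========================  =====================================
died_90d                    [0, 90)  (death strictly before day 90)
fever_30d                   [0, 30], temperature >= 38.0 degC
icd_*                       [0, 90], prefix match on ICD-10-CM code
antibiotic_class            fills in [6, 90], >= 3 consecutive covered days
micro_*                     [0, 90]
note_infection_post         [+3, +90] (per rule)
note_infection_pre          [-90, -3] (per rule)
==========================  =====================================

Flag extraction is a pure, deterministic function of (cohort, config,
ruleset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields
from importlib import resources
from typing import Literal, Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from ciedwatch.emr import (
    COMORBIDITIES,
    Cohort,
    DiagnosisEvent,
    MicrobiologyRecord,
    PatientRecord,
    PharmacyOrder,
    ProcedureRecord,
    ClinicalNote,
    VitalSign,
    day_offset,
)
from ciedwatch.keywords import Ruleset, default_ruleset, scan_result_text

logger = logging.getLogger(__name__)

AntibioticClass = Literal["none", "staph_directed", "non_staph"]


class Windows(BaseModel):
    fever: tuple[int, int] = (0, 30)
    icd: tuple[int, int] = (0, 90)
    micro: tuple[int, int] = (0, 90)
    antibiotics: tuple[int, int] = (6, 90)
    mortality_days: int = 90


class IcdCodes(BaseModel):
    cied_infection: list[str] = Field(default_factory=lambda: ["T82.6", "T82.7"])
    ssi: list[str] = Field(default_factory=lambda: ["T81.4", "T81.3"])
    unspecified_infection: list[str] = Field(
        default_factory=lambda: ["A49.9", "R78.81"])


class Antibiotics(BaseModel):
    staph_directed: list[str] = Field(default_factory=list)
    other: list[str] = Field(default_factory=list)


class FlagConfig(BaseModel):
    icd_codes: IcdCodes = Field(default_factory=IcdCodes)
    antibiotics: Antibiotics = Field(default_factory=Antibiotics)
    windows: Windows = Field(default_factory=Windows)
    temperature_threshold_c: float = 38.0


def default_flag_config() -> FlagConfig:
    """The packaged default configuration (editable stand-in lists)."""
    text = resources.files("ciedwatch.data").joinpath("config.yaml").read_text()
    return FlagConfig.model_validate(yaml.safe_load(text))


@dataclass
class FlagVector:
    """The per-procedure covariate set fed to the triage model."""

    procedure_id: str
    died_90d: bool = False
    emergent: bool = False
    congestive_heart_failure: bool = False
    solid_tumor_without_metastasis: bool = False
    coagulopathy: bool = False
    diabetes_uncomplicated: bool = False
    diabetes_complicated: bool = False
    obesity: bool = False
    pulmonary_circulation_disease: bool = False
    renal_failure: bool = False
    icd_cied_infection: bool = False
    icd_ssi: bool = False
    icd_unspecified_infection: bool = False
    fever_30d: bool = False
    antibiotic_class: AntibioticClass = "none"
    micro_blood_pos: bool = False
    micro_cardiac_pos: bool = False
    micro_misc_pos: bool = False
    micro_s_aureus: bool = False
    micro_cons: bool = False
    micro_order_no_staph: bool = False
    note_infection_post: bool = False
    note_infection_pre: bool = False


FLAG_COLUMNS: tuple[str, ...] = tuple(f.name for f in dc_fields(FlagVector))


def flag_mortality(procedure: ProcedureRecord, patient: PatientRecord,
                   mortality_days: int = 90) -> bool:
    """Death on day 0 up to (but excluding) day ``mortality_days``.

    A death recorded before the procedure date is a data-quality problem:
    it is logged as a warning and the flag stays False.
    """
    if patient.death_date is None:
        return False
    off = day_offset(patient.death_date, procedure.procedure_date)
    if off < 0:
        logger.warning(
            "patient %s death_date precedes procedure %s by %d days",
            patient.patient_id, procedure.procedure_id, -off)
        return False
    return off < mortality_days


def flag_fever(procedure: ProcedureRecord, vitals: Sequence[VitalSign],
               window: tuple[int, int] = (0, 30),
               threshold_c: float = 38.0) -> bool:
    lo, hi = window
    return any(
        v.value >= threshold_c
        and lo <= day_offset(v.measured_at, procedure.procedure_date) <= hi
        for v in vitals
    )


def _covered_intervals(fills: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge per-drug covered-day intervals; fills that overlap or abut
    (next start <= current end + 1) form one consecutive course."""
    if not fills:
        return []
    fills = sorted(fills)
    merged = [fills[0]]
    for start, end in fills[1:]:
        if start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def flag_antibiotics(procedure: ProcedureRecord,
                     pharmacy: Sequence[PharmacyOrder],
                     config: FlagConfig,
                     _warned: Optional[set] = None) -> AntibioticClass:
    """Classify the procedure's qualifying antibiotic exposure.

    A qualifying course is one or more fills of the same antibiotic whose
    merged covered days (fill_date .. fill_date + days_supplied - 1) span at
    least 3 consecutive days, with every contributing fill dated 6-90 days
    post-procedure.  Staph-directed agents take precedence; drugs absent
    from the configured lists are treated as non-antibiotics and logged
    once per extraction run.
    """
    lo, hi = config.windows.antibiotics
    staph = {d.lower() for d in config.antibiotics.staph_directed}
    other = {d.lower() for d in config.antibiotics.other}
    per_drug: dict[str, list[tuple[int, int]]] = {}
    for o in pharmacy:
        name = o.drug_name.lower()
        if name not in staph and name not in other:
            if _warned is not None and name not in _warned:
                logger.info("drug %r not in antibiotic config; ignored", o.drug_name)
                _warned.add(name)
            continue
        off = day_offset(o.fill_date, procedure.procedure_date)
        if not (lo <= off <= hi):
            continue
        per_drug.setdefault(name, []).append((off, off + o.days_supplied - 1))

    found_staph = found_other = False
    for name, fills in per_drug.items():
        if any(end - start + 1 >= 3 for start, end in _covered_intervals(fills)):
            if name in staph:
                found_staph = True
            else:
                found_other = True
    if found_staph:
        return "staph_directed"
    if found_other:
        return "non_staph"
    return "none"


def _norm_code(code: str) -> str:
    return code.replace(".", "").upper().strip()


def flag_icd(procedure: ProcedureRecord, diagnoses: Sequence[DiagnosisEvent],
             config: FlagConfig) -> tuple[bool, bool, bool]:
    """(cied_infection, ssi, unspecified) flags from prefix-matched
    ICD-10-CM codes dated 0-90 days post-procedure.  Codes are compared
    dot-stripped, so the prefix T82.7 matches T82.7XXA."""
    lo, hi = config.windows.icd
    lists = {
        "cied": [_norm_code(c) for c in config.icd_codes.cied_infection],
        "ssi": [_norm_code(c) for c in config.icd_codes.ssi],
        "unspec": [_norm_code(c) for c in config.icd_codes.unspecified_infection],
    }
    hits = {k: False for k in lists}
    for d in diagnoses:
        if not (lo <= day_offset(d.event_date, procedure.procedure_date) <= hi):
            continue
        code = _norm_code(d.code)
        for k, prefixes in lists.items():
            if any(code.startswith(p) for p in prefixes):
                hits[k] = True
    return hits["cied"], hits["ssi"], hits["unspec"]


def flag_micro(procedure: ProcedureRecord,
               micro: Sequence[MicrobiologyRecord],
               ruleset: Ruleset,
               window: tuple[int, int] = (0, 90)) -> dict[str, bool]:
    """Microbiology flags over orders dated 0-90 days post-procedure.

    Specimen-class flags require a positive culture *with* antibiotic
    susceptibility testing; organism flags come from keyword scanning of
    result text; ``micro_order_no_staph`` fires when at least one order
    exists in-window but neither staphylococcal organism was found.
    """
    lo, hi = window
    in_window = [
        m for m in micro
        if lo <= day_offset(m.order_date, procedure.procedure_date) <= hi
    ]
    out = {
        "micro_blood_pos": False, "micro_cardiac_pos": False,
        "micro_misc_pos": False, "micro_s_aureus": False,
        "micro_cons": False, "micro_order_no_staph": False,
    }
    class_key = {"blood": "micro_blood_pos", "cardiac": "micro_cardiac_pos",
                 "miscellaneous": "micro_misc_pos"}
    for m in in_window:
        if m.culture_positive and m.susceptibility_tested:
            key = class_key.get(m.specimen_class)
            if key:
                out[key] = True
        organisms = scan_result_text(m, ruleset.organisms)
        out["micro_s_aureus"] |= organisms.get("s_aureus", False)
        out["micro_cons"] |= organisms.get("coag_neg_staph", False)
    out["micro_order_no_staph"] = (
        bool(in_window) and not out["micro_s_aureus"] and not out["micro_cons"]
    )
    return out


def flag_notes(procedure: ProcedureRecord, notes: Sequence[ClinicalNote],
               ruleset: Ruleset) -> tuple[bool, bool]:
    """(note_infection_post, note_infection_pre) from the compiled ruleset.

    Each rule carries its own day window (post rules +3..+90, history rules
    -90..-3 by default) and note-title filter.
    """
    post = bool(ruleset.match_notes(notes, procedure.procedure_date,
                                    "post_infection"))
    pre = bool(ruleset.match_notes(notes, procedure.procedure_date,
                                   "pre_history"))
    return post, pre


def build_flag_vectors(cohort: Cohort,
                       config: Optional[FlagConfig] = None,
                       ruleset: Optional[Ruleset] = None) -> list[FlagVector]:
    """One FlagVector per procedure; pure function of its inputs."""
    config = config or default_flag_config()
    ruleset = ruleset or default_ruleset()
    patients = {p.patient_id: p for p in cohort.patients}
    diagnoses = cohort.by_patient("diagnoses")
    pharmacy = cohort.by_patient("pharmacy")
    micro = cohort.by_patient("micro")
    vitals = cohort.by_patient("vitals")
    notes = cohort.by_patient("notes")
    warned: set = set()

    out: list[FlagVector] = []
    for proc in cohort.procedures:
        patient = patients[proc.patient_id]
        icd_cied, icd_ssi, icd_unspec = flag_icd(
            proc, diagnoses.get(proc.patient_id, ()), config)
        micro_flags = flag_micro(proc, micro.get(proc.patient_id, ()),
                                 ruleset, config.windows.micro)
        note_post, note_pre = flag_notes(
            proc, notes.get(proc.patient_id, ()), ruleset)
        out.append(FlagVector(
            procedure_id=proc.procedure_id,
            died_90d=flag_mortality(proc, patient,
                                    config.windows.mortality_days),
            emergent=proc.emergent,
            **{c: patient.comorbidities[c] for c in COMORBIDITIES},
            icd_cied_infection=icd_cied,
            icd_ssi=icd_ssi,
            icd_unspecified_infection=icd_unspec,
            fever_30d=flag_fever(proc, vitals.get(proc.patient_id, ()),
                                 config.windows.fever,
                                 config.temperature_threshold_c),
            antibiotic_class=flag_antibiotics(
                proc, pharmacy.get(proc.patient_id, ()), config, warned),
            **micro_flags,
            note_infection_post=note_post,
            note_infection_pre=note_pre,
        ))
    return out


def flags_frame(vectors: Sequence[FlagVector]) -> pd.DataFrame:
    """FlagVectors as a DataFrame in the documented column order."""
    df = pd.DataFrame(
        [{c: getattr(v, c) for c in FLAG_COLUMNS} for v in vectors],
        columns=list(FLAG_COLUMNS),
    )
    return df


def flag_prevalence(frame: pd.DataFrame) -> pd.DataFrame:
    """Flag-prevalence summary: count and percent per flag (the style of a
    cohort-characteristics table)."""
    rows = []
    n = len(frame)
    for col in FLAG_COLUMNS:
        if col == "procedure_id":
            continue
        if col == "antibiotic_class":
            for level in ("staph_directed", "non_staph", "none"):
                k = int((frame[col] == level).sum())
                rows.append({"flag": f"antibiotic_class={level}", "count": k,
                             "percent": 100.0 * k / n if n else float("nan")})
        else:
            k = int(frame[col].sum())
            rows.append({"flag": col, "count": k,
                         "percent": 100.0 * k / n if n else float("nan")})
    return pd.DataFrame(rows, columns=["flag", "count", "percent"])
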