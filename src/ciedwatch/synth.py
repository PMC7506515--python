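"""Seeded synthetic-EMR generator with planted device infections.

The generator emulates the statistical structure the surveillance
algorithm assumes, not clinical prose.  Each simulated index procedure is
assigned a ground-truth status:

* **infected** (default prevalence 0.8%): an onset day is drawn from a
  truncated normal (mean 35 d, SD 21 d, support [3, 90]) and each
  documentation signal — infection keywords in a cardiology note, a
  device-infection or SSI diagnosis code, a qualifying antibiotic course,
  positive cultures, fever, 90-day death — is emitted with its configured
  conditional probability at dates tied to the onset;
* **preexisting infection** (default 0.7%): the procedure is being done to
  manage an infection already present.  These cases carry infection
  keywords in *pre*-procedure notes and, with a configurable copy-forward
  fraction, repeat the same phrase in post-procedure notes (emulating
  serial copying of historical text), alongside treatment signals
  (antibiotics, diagnosis codes, cultures).  They are the false-positive
  mechanism the preprocedure-history flag exists to counter;
* **background** (the rest): each signal fires independently at its
  configured marginal background rate (unrelated antibiotics, non-device
  infections, incidental cultures).

Everything flows from a single seeded NumPy generator, with draws made in
a fixed per-procedure order, so a (config, seed) pair fixes the output
byte-for-byte.  Keyword phrases are planted into filler-token note text,
sometimes with one intervening token, to exercise the bounded-gap matching
semantics; a fraction of procedures also get a keyword-bearing
"patient instructions" note that the title filter must ignore.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from ciedwatch.adjudication import ChartAbstraction
from ciedwatch.emr import (
    COMORBIDITIES,
    ClinicalNote,
    Cohort,
    DiagnosisEvent,
    MicrobiologyRecord,
    PatientRecord,
    PharmacyOrder,
    ProcedureRecord,
    ReviewLabel,
    VitalSign,
)

_BASE_DATE = date(2016, 10, 1)

# Filler vocabulary deliberately avoids every default rule keyword so that
# planted phrases are the only source of matches in generated text.
_FILLER = (
    "patient seen in clinic today for routine follow up reports feeling "
    "well vital signs stable exam unremarkable heart rate regular rhythm "
    "site clean dry intact no acute distress continue current plan "
    "medication reviewed return visit scheduled as needed labs pending "
    "discussed findings with patient who verbalized understanding"
).split()

_POST_PHRASES = (
    ("pocket", "infection"),
    ("device", "infection"),
    ("cied", "infection"),
    ("pacemaker", "infection"),
    ("endocarditis",),
)
_SIGNAL_TITLES = ("cardiology progress note", "electrophysiology procedure note")
_ROUTINE_TITLES = ("primary care note", "nursing note", "telehealth note",
                   "cardiology progress note")
_NOISE_DRUGS = ("gabapentin", "metformin", "lisinopril", "atorvastatin")
_NOISE_CODES = ("I48.91", "I10", "E78.5", "Z95.810")


class SimulationConfig(BaseModel):
    """Generative parameters; the defaults are the study conditions the
    algorithm is designed for (a large cardiac-device cohort with rare
    infections and much richer background antibiotic/culture noise)."""

    n_procedures: int = Field(default=9606, ge=1)
    seed: int = 0

    infection_prevalence: float = 0.008
    preexisting_infection_rate: float = 0.007

    onset_mean_d: float = 35.0
    onset_sd_d: float = 21.0
    onset_range: tuple[int, int] = (3, 90)
    infection_type_probs: dict[str, float] = Field(default_factory=lambda: {
        "pocket": 0.831, "endocarditis_or_lead": 0.149, "cellulitis_only": 0.020})

    age_mean: float = 71.8
    age_sd: float = 10.6
    male_fraction: float = 0.977
    emergent_rate: float = 0.124
    comorbidity_prevalence: dict[str, float] = Field(default_factory=lambda: {
        "congestive_heart_failure": 0.5072,
        "solid_tumor_without_metastasis": 0.0824,
        "coagulopathy": 0.057,
        "diabetes_uncomplicated": 0.4029,
        "diabetes_complicated": 0.277,
        "obesity": 0.2073,
        "pulmonary_circulation_disease": 0.0429,
        "renal_failure": 0.2564,
    })

    # P(signal | infected): documentation emitted around the onset day.
    infected_signals: dict[str, float] = Field(default_factory=lambda: {
        "icd_cied": 0.787, "icd_ssi": 0.085, "icd_unspec": 0.043,
        "fever": 0.149, "died": 0.149,
        "micro_blood_pos": 0.872, "micro_cardiac_pos": 0.447,
        "micro_misc_pos": 0.021, "s_aureus": 0.149, "cons": 0.085,
        "micro_plain_order": 0.68,
        "note_post": 0.957, "note_pre": 0.15,
    })
    # P(signal | background case): marginal noise rates.
    background_signals: dict[str, float] = Field(default_factory=lambda: {
        "icd_cied": 0.0377, "icd_ssi": 0.0055, "icd_unspec": 0.0135,
        "fever": 0.0271, "died": 0.027,
        "micro_blood_pos": 0.0943, "micro_cardiac_pos": 0.0167,
        "micro_misc_pos": 0.0961, "s_aureus": 0.0058, "cons": 0.0045,
        "micro_plain_order": 0.1864,
        "note_post": 0.0781, "note_pre": 0.030,
    })
    # P(signal | preexisting infection managed by this procedure).
    preexisting_signals: dict[str, float] = Field(default_factory=lambda: {
        "icd_cied": 0.5, "icd_ssi": 0.0, "icd_unspec": 0.02,
        "fever": 0.05, "died": 0.05,
        "micro_blood_pos": 0.3, "micro_cardiac_pos": 0.3,
        "micro_misc_pos": 0.05, "s_aureus": 0.1, "cons": 0.05,
        "micro_plain_order": 0.6,
        "note_post": 0.0, "note_pre": 0.95,  # note_post via copy-forward below
    })
    copy_forward_fraction: float = 0.8

    # qualifying-antibiotic class: (staph_directed, non_staph); rest "none".
    antibiotic_probs_infected: tuple[float, float] = (0.638, 0.043)
    antibiotic_probs_background: tuple[float, float] = (0.1636, 0.0321)
    antibiotic_probs_preexisting: tuple[float, float] = (0.7, 0.02)

    instruction_note_rate: float = 0.10
    split_fill_fraction: float = 0.3  # courses split into merging short fills


@dataclass
class SimulatedCohort:
    cohort: Cohort
    labels: list[ReviewLabel]
    abstractions: list[ChartAbstraction]

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame([l.model_dump() for l in self.labels])


def _note_text(rng: np.random.Generator, phrase: Optional[Sequence[str]] = None) -> str:
    n = int(rng.integers(15, 36))
    tokens = list(rng.choice(_FILLER, size=n))
    if phrase:
        words = list(phrase)
        if len(words) > 1 and rng.random() < 0.5:
            # one intervening filler token, still within the default gap bound
            gap = str(rng.choice(_FILLER))
            words = [words[0], gap] + words[1:]
        pos = int(rng.integers(0, len(tokens) + 1))
        tokens = tokens[:pos] + words + tokens[pos:]
    return " ".join(tokens)


def _truncnorm_day(rng: np.random.Generator, mean: float, sd: float,
                   lo: int, hi: int) -> int:
    while True:  # rejection sampling; acceptance ~0.9 at the defaults
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return int(round(v))


class _Builder:
    """Accumulates one simulated procedure's records with a fixed draw order."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator,
                 staph_drugs: Sequence[str], other_drugs: Sequence[str]):
        self.cfg = config
        self.rng = rng
        self.staph_drugs = list(staph_drugs)
        self.other_drugs = list(other_drugs)
        self.cohort = Cohort()
        self.labels: list[ReviewLabel] = []
        self.abstractions: list[ChartAbstraction] = []

    # -- record emitters ---------------------------------------------------

    def _day(self, proc_date: date, offset: int) -> date:
        return proc_date + timedelta(days=int(offset))

    def note(self, pid: str, proc_date: date, offset: int, title: str,
             phrase: Optional[Sequence[str]], note_counter: list[int]) -> None:
        note_counter[0] += 1
        self.cohort.notes.append(ClinicalNote(
            note_id=f"{pid}-N{note_counter[0]:02d}", patient_id=pid,
            note_title=title, note_date=self._day(proc_date, offset),
            text=_note_text(self.rng, phrase)))

    def micro(self, pid: str, proc_date: date, offset: int, specimen: str,
              positive: bool, tested: bool, text: str) -> None:
        self.cohort.micro.append(MicrobiologyRecord(
            patient_id=pid, order_date=self._day(proc_date, offset),
            specimen_class=specimen, culture_positive=positive,
            susceptibility_tested=tested, result_text=text))

    def abx_course(self, pid: str, proc_date: date, day: int, staph: bool) -> None:
        """A qualifying course: >= 3 consecutive covered days, fills in [6, 90].
        A fraction of courses is split into two short overlapping fills that
        only qualify once merged."""
        rng = self.rng
        drug = str(rng.choice(self.staph_drugs if staph else self.other_drugs))
        day = int(np.clip(day, 6, 88))
        if rng.random() < self.cfg.split_fill_fraction:
            for start, supplied in ((day, 2), (day + 2, 2)):
                self.cohort.pharmacy.append(PharmacyOrder(
                    patient_id=pid, drug_name=drug,
                    fill_date=self._day(proc_date, start),
                    days_supplied=supplied))
        else:
            self.cohort.pharmacy.append(PharmacyOrder(
                patient_id=pid, drug_name=drug,
                fill_date=self._day(proc_date, day),
                days_supplied=int(rng.integers(7, 15))))

    # -- one procedure -----------------------------------------------------

    def build(self, i: int) -> None:
        cfg, rng = self.cfg, self.rng
        pid, prid = f"P{i:06d}", f"PR{i:06d}"
        proc_date = _BASE_DATE + timedelta(days=int(rng.integers(0, 365)))

        u = rng.random()
        if u < cfg.infection_prevalence:
            status = "infected"
        elif u < cfg.infection_prevalence + cfg.preexisting_infection_rate:
            status = "preexisting"
        else:
            status = "background"

        age = int(np.clip(round(rng.normal(cfg.age_mean, cfg.age_sd)), 18, 100))
        sex = "male" if rng.random() < cfg.male_fraction else "female"
        race = str(rng.choice(["white", "african_american", "other_or_unknown"],
                              p=[0.785, 0.155, 0.06]))
        comorbid = {c: bool(rng.random() < cfg.comorbidity_prevalence[c])
                    for c in COMORBIDITIES}

        if status == "infected":
            sig = cfg.infected_signals
            abx_p = cfg.antibiotic_probs_infected
            lo, hi = cfg.onset_range
            onset = _truncnorm_day(rng, cfg.onset_mean_d, cfg.onset_sd_d, lo, hi)
            types = list(cfg.infection_type_probs)
            probs = np.array([cfg.infection_type_probs[t] for t in types])
            itype = str(rng.choice(types, p=probs / probs.sum()))
        elif status == "preexisting":
            sig = cfg.preexisting_signals
            abx_p = cfg.antibiotic_probs_preexisting
            onset, itype = None, "none"
        else:
            sig = cfg.background_signals
            abx_p = cfg.antibiotic_probs_background
            onset, itype = None, "none"

        emit = {k: bool(rng.random() < p) for k, p in sig.items()}

        def sday(center_jitter: tuple[int, int], window: tuple[int, int]) -> int:
            """Signal day: near onset for infected cases, uniform otherwise."""
            lo, hi = window
            if onset is not None:
                j0, j1 = center_jitter
                return int(np.clip(onset + rng.integers(j0, j1 + 1), lo, hi))
            return int(rng.integers(lo, hi + 1))

        death_date = None
        if emit["died"]:
            death_date = self._day(proc_date,
                                   rng.integers(min(onset, 89), 90)
                                   if onset is not None
                                   else rng.integers(0, 90))
        self.cohort.patients.append(PatientRecord(
            patient_id=pid, age=age, sex=sex, race=race,
            ethnicity="not_hispanic", comorbidities=comorbid,
            death_date=death_date))
        self.cohort.procedures.append(ProcedureRecord(
            procedure_id=prid, patient_id=pid, procedure_date=proc_date,
            facility_id=f"F{int(rng.integers(1, 68)):03d}",
            emergent=bool(rng.random() < cfg.emergent_rate)))

        note_counter = [0]

        # diagnosis codes
        if emit["icd_cied"]:
            self.cohort.diagnoses.append(DiagnosisEvent(
                patient_id=pid, code="T82.7XXA",
                event_date=self._day(proc_date, sday((0, 14), (0, 90)))))
        if emit["icd_ssi"]:
            code = str(rng.choice(["T81.41XA", "T81.31XA"]))
            self.cohort.diagnoses.append(DiagnosisEvent(
                patient_id=pid, code=code,
                event_date=self._day(proc_date, sday((0, 14), (0, 90)))))
        if emit["icd_unspec"]:
            code = str(rng.choice(["A49.9", "R78.81"]))
            self.cohort.diagnoses.append(DiagnosisEvent(
                patient_id=pid, code=code,
                event_date=self._day(proc_date, sday((0, 14), (0, 90)))))
        if rng.random() < 0.3:  # unrelated billing noise
            self.cohort.diagnoses.append(DiagnosisEvent(
                patient_id=pid, code=str(rng.choice(_NOISE_CODES)),
                event_date=self._day(proc_date, rng.integers(0, 91))))

        # vitals: routine temperature plus possible fever
        self.cohort.vitals.append(VitalSign(
            patient_id=pid, value=float(np.round(rng.uniform(36.2, 37.4), 1)),
            measured_at=self._day(proc_date, rng.integers(0, 31))))
        if emit["fever"]:
            fever_day = (min(onset, 30) if onset is not None
                         else int(rng.integers(0, 31)))
            self.cohort.vitals.append(VitalSign(
                patient_id=pid, value=float(np.round(rng.uniform(38.0, 39.8), 1)),
                measured_at=self._day(proc_date, fever_day)))

        # pharmacy: qualifying course (mutually exclusive class), then noise
        v = rng.random()
        abx_class = ("staph_directed" if v < abx_p[0]
                     else "non_staph" if v < abx_p[0] + abx_p[1] else "none")
        if abx_class != "none":
            day = sday((0, 3), (6, 90))
            self.abx_course(pid, proc_date, day, abx_class == "staph_directed")
        if rng.random() < 0.4:  # non-antibiotic fills
            self.cohort.pharmacy.append(PharmacyOrder(
                patient_id=pid, drug_name=str(rng.choice(_NOISE_DRUGS)),
                fill_date=self._day(proc_date, rng.integers(0, 91)),
                days_supplied=int(rng.integers(30, 91))))
        if rng.random() < 0.05:  # too-short antibiotic course: never qualifies
            self.cohort.pharmacy.append(PharmacyOrder(
                patient_id=pid, drug_name=str(rng.choice(self.staph_drugs)),
                fill_date=self._day(proc_date, rng.integers(6, 91)),
                days_supplied=int(rng.integers(1, 3))))
        if rng.random() < 0.03:  # early prophylaxis, outside the fill window
            self.cohort.pharmacy.append(PharmacyOrder(
                patient_id=pid, drug_name=str(rng.choice(self.staph_drugs)),
                fill_date=self._day(proc_date, rng.integers(0, 6)),
                days_supplied=int(rng.integers(5, 11))))

        # microbiology
        if emit["micro_blood_pos"]:
            self.micro(pid, proc_date, sday((-2, 3), (0, 90)), "blood",
                       True, True, "gram positive cocci in clusters")
        if emit["micro_cardiac_pos"]:
            self.micro(pid, proc_date, sday((-2, 3), (0, 90)), "cardiac",
                       True, True, "organisms recovered from lead tip culture")
        if emit["micro_misc_pos"]:
            self.micro(pid, proc_date, sday((-2, 3), (0, 90)), "miscellaneous",
                       True, True, "mixed flora recovered")
        if emit["s_aureus"]:
            self.micro(pid, proc_date, sday((-2, 3), (0, 90)), "blood",
                       True, True, "staphylococcus aureus isolated from culture")
        if emit["cons"]:
            self.micro(pid, proc_date, sday((-2, 3), (0, 90)), "blood",
                       True, True, "coagulase negative staphylococcus species isolated")
        if emit["micro_plain_order"]:
            self.micro(pid, proc_date, sday((-2, 3), (0, 90)), "blood",
                       False, False, "no growth to date")

        # clinical notes
        for _ in range(int(rng.integers(1, 3))):  # routine filler notes
            self.note(pid, proc_date, int(rng.integers(-90, 91)),
                      str(rng.choice(_ROUTINE_TITLES)), None, note_counter)
        phrase_idx = int(rng.integers(0, len(_POST_PHRASES)))
        phrase = _POST_PHRASES[phrase_idx]
        if emit["note_post"]:
            self.note(pid, proc_date, sday((0, 5), (3, 90)),
                      str(rng.choice(_SIGNAL_TITLES)), phrase, note_counter)
        if emit["note_pre"]:
            self.note(pid, proc_date, int(rng.integers(-90, -2)),
                      str(rng.choice(_SIGNAL_TITLES)), phrase, note_counter)
            if (status == "preexisting"
                    and rng.random() < cfg.copy_forward_fraction):
                # serial copy-forward of the historical phrase after day 0
                self.note(pid, proc_date, int(rng.integers(3, 91)),
                          str(rng.choice(_SIGNAL_TITLES)), phrase, note_counter)
        if rng.random() < cfg.instruction_note_rate:
            # keyword-bearing instructions; excluded by the title filter
            self.note(pid, proc_date, int(rng.integers(0, 8)),
                      "patient instructions device care",
                      ("device", "infection"), note_counter)

        # ground truth + chart abstraction
        self._truth(prid, status, itype, onset, emit, abx_class)

    def _truth(self, prid: str, status: str, itype: str,
               onset: Optional[int], emit: dict, abx_class: str) -> None:
        rng = self.rng
        any_pos_culture = (emit["micro_blood_pos"] or emit["micro_cardiac_pos"]
                           or emit["micro_misc_pos"] or emit["s_aureus"]
                           or emit["cons"])
        if status == "infected":
            documented = bool(rng.random() < 0.85)
            symptoms = emit["fever"] or bool(rng.random() < 0.6)
            lab = any_pos_culture
            abx = abx_class != "none"
            if not documented and symptoms + lab + abx < 2:
                # the reference standard found it some way; make the record
                # self-consistent with an infected truth label
                symptoms = abx = True
            self.abstractions.append(ChartAbstraction(
                procedure_id=prid, physician_documented_infection=documented,
                symptoms_documented=symptoms, positive_laboratory=lab,
                antibiotics_initiated=abx, days_postprocedure=onset,
                documented_type=itype))
            self.labels.append(ReviewLabel(
                procedure_id=prid, reviewed=True, infection=True,
                infection_type=itype, onset_day=onset))
        elif status == "preexisting":
            self.abstractions.append(ChartAbstraction(
                procedure_id=prid, physician_documented_infection=True,
                symptoms_documented=bool(rng.random() < 0.5),
                positive_laboratory=any_pos_culture,
                antibiotics_initiated=abx_class != "none",
                infection_present_at_procedure=True,
                documented_type="pocket"))
            self.labels.append(ReviewLabel(
                procedure_id=prid, reviewed=True, infection=False,
                present_on_admission=True))
        else:
            # at most one device-attributable criterion, so adjudication
            # stays consistent with the negative truth label
            v = rng.random()
            self.abstractions.append(ChartAbstraction(
                procedure_id=prid,
                symptoms_documented=v < 0.15,
                antibiotics_initiated=0.15 <= v < 0.25))
            self.labels.append(ReviewLabel(
                procedure_id=prid, reviewed=True, infection=False))


def simulate_cohort(config: SimulationConfig,
                    staph_drugs: Optional[Sequence[str]] = None,
                    other_drugs: Optional[Sequence[str]] = None) -> SimulatedCohort:
    """Generate one cohort plus ground-truth labels and chart abstractions.

    Drug-name pools default to the packaged antibiotic configuration so
    generated fills are classifiable by the default flag extractor.
    """
    if staph_drugs is None or other_drugs is None:
        from ciedwatch.flags import default_flag_config
        fc = default_flag_config()
        staph_drugs = staph_drugs or fc.antibiotics.staph_directed
        other_drugs = other_drugs or fc.antibiotics.other
    rng = np.random.default_rng(config.seed)
    b = _Builder(config, rng, staph_drugs, other_drugs)
    for i in range(config.n_procedures):
        b.build(i)
    b.cohort.validate()
    return SimulatedCohort(cohort=b.cohort, labels=b.labels,
                           abstractions=b.abstractions)


def end_to_end_fixture(config: SimulationConfig
                       ) -> tuple[SimulatedCohort, SimulatedCohort]:
    """Two independent cohorts from one config: a development cohort to fit
    on and a validation cohort to evaluate on."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(2)]
    dev = simulate_cohort(config.model_copy(update={"seed": seeds[0]}))
    val = simulate_cohort(config.model_copy(update={"seed": seeds[1]}))
    return dev, val


def simulate_logistic(n: int,
                      intercept: float,
                      beta: dict[str, float],
                      covariate_probs: dict[str, float],
                      seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Design-matrix-level logistic draw for parameter-recovery checks.

    Binary covariates are independent Bernoulli with the given marginal
    probabilities; outcomes follow the logistic model with the planted
    intercept and log-odds vector.
    """
    rng = np.random.default_rng(seed)
    cols = {name: (rng.random(n) < p).astype(float)
            for name, p in covariate_probs.items()}
    X = pd.DataFrame(cols)
    eta = intercept + sum(beta[c] * X[c].to_numpy() for c in beta)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return X, y
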