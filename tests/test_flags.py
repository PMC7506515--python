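"""Flag extraction: window boundaries, course merging, prefix matching,
and whole-vector invariants."""

from __future__ import annotations

from datetime import timedelta

import pytest

from ciedwatch.emr import (
    Cohort,
    DiagnosisEvent,
    MicrobiologyRecord,
    PharmacyOrder,
    VitalSign,
    ClinicalNote,
)
from ciedwatch.flags import (
    build_flag_vectors,
    default_flag_config,
    flag_antibiotics,
    flag_fever,
    flag_icd,
    flag_micro,
    flag_mortality,
    flag_notes,
    flags_frame,
)
from ciedwatch.keywords import default_ruleset
from ciedwatch.synth import SimulationConfig, simulate_cohort

from conftest import make_patient, make_procedure, on_day

CFG = default_flag_config()
RULES = default_ruleset()
PROC = make_procedure()


class TestMortality:
    @pytest.mark.parametrize("day,expected", [(0, True), (89, True),
                                              (90, False), (120, False)])
    def test_90_day_boundary_is_exclusive(self, day, expected):
        patient = make_patient(death_date=on_day(day))
        assert flag_mortality(PROC, patient) is expected

    def test_no_death_date(self):
        assert flag_mortality(PROC, make_patient()) is False

    def test_death_before_procedure_warns_and_stays_false(self, caplog):
        patient = make_patient(death_date=on_day(-5))
        with caplog.at_level("WARNING"):
            assert flag_mortality(PROC, patient) is False
        assert "precedes" in caplog.text


class TestFever:
    @pytest.mark.parametrize("temp,day,expected", [
        (38.0, 10, True),   # threshold is >= 38.0
        (37.9, 10, False),
        (39.0, 30, True),   # window closes after day 30...
        (39.0, 31, False),
        (39.0, -1, False),
    ])
    def test_threshold_and_window(self, temp, day, expected):
        vitals = [VitalSign(patient_id="P1", value=temp, measured_at=on_day(day))]
        assert flag_fever(PROC, vitals) is expected


def fill(drug, day, supplied):
    return PharmacyOrder(patient_id="P1", drug_name=drug,
                         fill_date=on_day(day), days_supplied=supplied)


class TestAntibiotics:
    def test_staph_directed_course(self):
        assert flag_antibiotics(PROC, [fill("cephalexin", 10, 7)], CFG) \
            == "staph_directed"

    def test_non_staph_course(self):
        assert flag_antibiotics(PROC, [fill("azithromycin", 20, 5)], CFG) \
            == "non_staph"

    def test_fill_before_day_6_does_not_qualify(self):
        assert flag_antibiotics(PROC, [fill("cephalexin", 3, 10)], CFG) == "none"

    @pytest.mark.parametrize("day,expected", [(6, "staph_directed"),
                                              (90, "staph_directed"),
                                              (91, "none")])
    def test_fill_window_boundaries(self, day, expected):
        assert flag_antibiotics(PROC, [fill("cefazolin", day, 5)], CFG) == expected

    def test_short_course_does_not_qualify(self):
        assert flag_antibiotics(PROC, [fill("cephalexin", 10, 2)], CFG) == "none"

    def test_overlapping_fills_merge_into_a_qualifying_course(self):
        orders = [fill("cephalexin", 10, 2), fill("cephalexin", 12, 2)]
        assert flag_antibiotics(PROC, orders, CFG) == "staph_directed"

    def test_disjoint_short_fills_do_not_merge(self):
        orders = [fill("cephalexin", 10, 2), fill("cephalexin", 20, 2)]
        assert flag_antibiotics(PROC, orders, CFG) == "none"

    def test_staph_directed_takes_precedence(self):
        orders = [fill("azithromycin", 20, 5), fill("vancomycin", 30, 5)]
        assert flag_antibiotics(PROC, orders, CFG) == "staph_directed"

    def test_unknown_drug_is_not_an_antibiotic(self):
        assert flag_antibiotics(PROC, [fill("gabapentin", 10, 30)], CFG) == "none"


def dx(code, day):
    return DiagnosisEvent(patient_id="P1", code=code, event_date=on_day(day))


class TestIcd:
    def test_prefix_match_through_extension_characters(self):
        assert flag_icd(PROC, [dx("T82.7XXA", 30)], CFG) == (True, False, False)

    def test_wound_dehiscence_counts_as_ssi(self):
        assert flag_icd(PROC, [dx("T81.31XA", 15)], CFG) == (False, True, False)

    def test_unspecified_infection_code(self):
        assert flag_icd(PROC, [dx("A49.9", 15)], CFG) == (False, False, True)

    @pytest.mark.parametrize("day,expected", [(0, True), (90, True), (91, False)])
    def test_window_boundaries(self, day, expected):
        assert flag_icd(PROC, [dx("T82.7XXA", day)], CFG)[0] is expected

    def test_no_events(self):
        assert flag_icd(PROC, [], CFG) == (False, False, False)

    def test_unrelated_code_ignored(self):
        assert flag_icd(PROC, [dx("I48.91", 10)], CFG) == (False, False, False)


def micro_rec(day=40, specimen="cardiac", positive=True, tested=True, text=""):
    return MicrobiologyRecord(patient_id="P1", order_date=on_day(day),
                              specimen_class=specimen,
                              culture_positive=positive,
                              susceptibility_tested=tested, result_text=text)


class TestMicro:
    def test_positive_tested_cardiac_specimen(self):
        out = flag_micro(PROC, [micro_rec()], RULES)
        assert out["micro_cardiac_pos"] is True
        assert out["micro_order_no_staph"] is True  # no organism keyword

    def test_positive_without_susceptibility_testing_does_not_count(self):
        out = flag_micro(PROC, [micro_rec(tested=False)], RULES)
        assert out["micro_cardiac_pos"] is False

    def test_negative_order_sets_no_staph_flag_only(self):
        out = flag_micro(PROC, [micro_rec(specimen="blood", positive=False,
                                          tested=False)], RULES)
        assert out == {"micro_blood_pos": False, "micro_cardiac_pos": False,
                       "micro_misc_pos": False, "micro_s_aureus": False,
                       "micro_cons": False, "micro_order_no_staph": True}

    def test_no_orders_means_all_false(self):
        out = flag_micro(PROC, [], RULES)
        assert not any(out.values())

    def test_organism_keyword_suppresses_no_staph_flag(self):
        out = flag_micro(PROC, [micro_rec(
            specimen="blood", text="staphylococcus aureus isolated")], RULES)
        assert out["micro_s_aureus"] is True
        assert out["micro_order_no_staph"] is False

    def test_out_of_window_order_invisible(self):
        out = flag_micro(PROC, [micro_rec(day=95)], RULES)
        assert not any(out.values())


def note(text, day, title="cardiology progress note"):
    return ClinicalNote(note_id=f"N{day}", patient_id="P1", note_title=title,
                        note_date=on_day(day), text=text)


class TestNotes:
    def test_postprocedure_keyword(self):
        post, pre = flag_notes(PROC, [note("pocket infection noted", 20)], RULES)
        assert (post, pre) == (True, False)

    def test_preprocedure_history_keyword(self):
        post, pre = flag_notes(PROC, [note("prior cied infection", -30)], RULES)
        assert (post, pre) == (False, True)

    def test_day_1_is_inside_neither_window(self):
        assert flag_notes(PROC, [note("pocket infection", 1)], RULES) \
            == (False, False)

    def test_excluded_title_never_flags(self):
        n = note("watch for device infection", 20, title="patient instructions")
        assert flag_notes(PROC, [n], RULES) == (False, False)


class TestBuildFlagVectors:
    def test_bare_cohort_gives_passthrough_only(self):
        cohort = Cohort(
            patients=[make_patient(comorbidities={
                **make_patient().comorbidities, "obesity": True})],
            procedures=[make_procedure(emergent=True)])
        (v,) = build_flag_vectors(cohort, CFG, RULES)
        assert v.emergent and v.obesity
        assert v.antibiotic_class == "none"
        others = [f for f in vars(v)
                  if f not in ("procedure_id", "emergent", "obesity",
                               "antibiotic_class")]
        assert not any(getattr(v, f) for f in others)

    def test_deterministic(self):
        sim = simulate_cohort(SimulationConfig(n_procedures=200, seed=3))
        f1 = flags_frame(build_flag_vectors(sim.cohort, CFG, RULES))
        f2 = flags_frame(build_flag_vectors(sim.cohort, CFG, RULES))
        assert f1.equals(f2)

    def test_shifting_all_events_out_of_window_zeroes_timed_flags(self):
        sim = simulate_cohort(SimulationConfig(n_procedures=150, seed=9))
        shifted = sim.cohort
        delta = timedelta(days=200)
        for stream, attr in (("diagnoses", "event_date"),
                             ("pharmacy", "fill_date"),
                             ("micro", "order_date"),
                             ("vitals", "measured_at"),
                             ("notes", "note_date")):
            for rec in getattr(shifted, stream):
                object.__setattr__(rec, attr, getattr(rec, attr) + delta)
        for p in shifted.patients:
            if p.death_date is not None:
                object.__setattr__(p, "death_date", p.death_date + delta)
        frame = flags_frame(build_flag_vectors(shifted, CFG, RULES))
        timed = ["died_90d", "icd_cied_infection", "icd_ssi",
                 "icd_unspecified_infection", "fever_30d", "micro_blood_pos",
                 "micro_cardiac_pos", "micro_misc_pos", "micro_s_aureus",
                 "micro_cons", "micro_order_no_staph", "note_infection_post",
                 "note_infection_pre"]
        assert not frame[timed].any().any()
        assert (frame["antibiotic_class"] == "none").all()

    def test_antibiotic_class_single_valued_and_no_staph_exclusive(self):
        sim = simulate_cohort(SimulationConfig(n_procedures=500, seed=11))
        frame = flags_frame(build_flag_vectors(sim.cohort, CFG, RULES))
        assert frame["antibiotic_class"].isin(
            ["none", "staph_directed", "non_staph"]).all()
        clash = frame["micro_order_no_staph"] & (
            frame["micro_s_aureus"] | frame["micro_cons"])
        assert not clash.any()
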