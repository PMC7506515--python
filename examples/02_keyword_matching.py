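"""Constrained keyword matching over clinical-note text.

Shows the matcher's semantics: preserved word order, at most one
intervening token between matched words, spelling variants, note-title
filters, and day windows relative to the index procedure.
"""

from datetime import date

from ciedwatch import ClinicalNote, KeywordRule, match_rule

procedure_date = date(2017, 3, 1)
rule = KeywordRule(
    rule_id="device-infection",
    words=(frozenset({"cied", "device", "pacemaker"}),
           frozenset({"infection", "infected"})),
    max_gap_tokens=1,
    note_titles=("cardiology",),
    window_days=(3, 90),
)

notes = [
    ClinicalNote(note_id="N1", patient_id="P1",
                 note_title="cardiology progress note",
                 note_date=date(2017, 3, 20),
                 text="Pocket erythema concerning for CIED pocket infection."),
    ClinicalNote(note_id="N2", patient_id="P1",
                 note_title="cardiology progress note",
                 note_date=date(2017, 3, 21),
                 text="infection ruled out; device site reviewed"),  # order!
    ClinicalNote(note_id="N3", patient_id="P1",
                 note_title="patient instructions",
                 note_date=date(2017, 3, 22),
                 text="call the clinic if you suspect a device infection"),
    ClinicalNote(note_id="N4", patient_id="P1",
                 note_title="cardiology progress note",
                 note_date=date(2017, 1, 5),  # before the procedure
                 text="history of pacemaker infection in 2015"),
]

for note in notes:
    matches = match_rule(note, rule, procedure_date)
    verdict = [m.matched_text for m in matches] or "no match"
    print(f"{note.note_id} ({note.note_title!r}, {note.note_date}): {verdict}")
# Only N1 matches: N2 violates word order, N3 fails the title filter, and
# N4 falls outside the +3..+90 day window (it would match a pre-history rule).
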