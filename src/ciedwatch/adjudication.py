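"""Reference-standard adjudication of chart-abstraction records.

A 90-day CIED infection (device pocket infection, lead infection, and/or
endocarditis) is present when the chart shows either explicit physician
documentation of infection, or at least two of: documented symptoms (e.g.
fever), positive laboratory tests, initiation of antibiotic treatment —
all within 90 days of the procedure.  Three situations are excluded
outright and take precedence over any inclusion criteria: an infection
already present at the time of the procedure, superficial cellulitis at a
site other than the device pocket, and an isolated stitch abscess.

This module scores structured abstraction records; it does not attempt to
abstract charts from raw notes (that is the manual reviewer's job, or the
synthetic generator's).
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, field_validator

from ciedwatch.emr import InfectionType, ReviewLabel


class ChartAbstraction(BaseModel):
    """Structured findings abstracted from one procedure's chart review.

    ``documented_type`` records the reviewer's classification of the
    infection (pocket / endocarditis-lead / cellulitis at the device site)
    and is carried through to the resulting label when the criteria are
    met.  Cellulitis at the device site is a device infection; superficial
    cellulitis elsewhere is the exclusion field.
    """

    procedure_id: str
    physician_documented_infection: bool = False
    symptoms_documented: bool = False
    positive_laboratory: bool = False
    antibiotics_initiated: bool = False
    infection_present_at_procedure: bool = False
    superficial_cellulitis_other_site: bool = False
    stitch_abscess_only: bool = False
    days_postprocedure: Optional[int] = None
    documented_type: InfectionType = "none"

    @field_validator("days_postprocedure")
    @classmethod
    def _within_surveillance(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and v > 90:
            raise ValueError("days_postprocedure exceeds the 90-day window")
        return v


def adjudicate(abstraction: ChartAbstraction) -> ReviewLabel:
    """Score one abstraction against the infection definition.

    Exclusions dominate: any exclusion field true forces infection=False
    regardless of how many inclusion criteria are met.
    """
    criteria = sum([
        abstraction.symptoms_documented,
        abstraction.positive_laboratory,
        abstraction.antibiotics_initiated,
    ])
    included = abstraction.physician_documented_infection or criteria >= 2
    excluded = (
        abstraction.infection_present_at_procedure
        or abstraction.superficial_cellulitis_other_site
        or abstraction.stitch_abscess_only
    )
    in_window = (abstraction.days_postprocedure is None
                 or abstraction.days_postprocedure <= 90)
    infection = included and not excluded and in_window

    if infection:
        itype: InfectionType = (
            abstraction.documented_type
            if abstraction.documented_type != "none" else "pocket"
        )
    else:
        itype = "none"
    return ReviewLabel(
        procedure_id=abstraction.procedure_id,
        reviewed=True,
        infection=infection,
        infection_type=itype,
        present_on_admission=abstraction.infection_present_at_procedure,
        onset_day=abstraction.days_postprocedure if infection else None,
    )
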