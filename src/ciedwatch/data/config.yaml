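# Default flag-extraction configuration.
#
# ICD-10-CM code lists are prefix-based (T82.7 matches T82.7XXA) and, like
# the antibiotic lists, ship as editable stand-ins: a deployment should
# substitute its own curated lists.  Windows are inclusive day intervals
# relative to the index procedure (day 0); mortality uses [0, 90), i.e.
# death strictly before day 90.

icd_codes:
  cied_infection: ["T82.6", "T82.7"]
  ssi: ["T81.4", "T81.3"]          # surgical site infection + wound dehiscence
  unspecified_infection: ["A49.9", "R78.81"]

antibiotics:
  staph_directed:
    - cefazolin
    - cephalexin
    - dicloxacillin
    - nafcillin
    - vancomycin
    - daptomycin
    - linezolid
    - doxycycline
    - trimethoprim-sulfamethoxazole
    - sulfamethoxazole-trimethoprim
    - clindamycin
  other:
    - azithromycin
    - amoxicillin
    - amoxicillin-clavulanate
    - ciprofloxacin
    - levofloxacin
    - metronidazole
    - nitrofurantoin
    - ampicillin

windows:
  fever: [0, 30]
  icd: [0, 90]
  micro: [0, 90]
  antibiotics: [6, 90]
  mortality_days: 90

temperature_threshold_c: 38.0
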