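# Default keyword ruleset for CIED-infection surveillance.
#
# This is a curated stand-in list built from the phrases known to perform
# well for this task (device/pocket + infection with preserved word order
# and at most one intervening token, endocarditis, lead infection); every
# deployment should review and replace it with site-specific keyword and
# note-title lists.  Post-procedure rules search days +3..+90 in cardiology
# and related notes; pre-procedure history rules search days -90..-3.

rules:
  - id: post-pocket-infection
    words: [["pocket"], ["infection", "infections", "infected"]]
    max_gap_tokens: 1
    note_titles: ["cardiology", "electrophysiology", "infectious disease"]
    window_days: [3, 90]
    polarity: post_infection
  - id: post-device-infection
    words:
      - ["cied", "device", "pacemaker", "defibrillator", "icd", "generator", "lead"]
      - ["infection", "infections", "infected"]
    max_gap_tokens: 1
    note_titles: ["cardiology", "electrophysiology", "infectious disease"]
    window_days: [3, 90]
    polarity: post_infection
  - id: post-endocarditis
    words: [["endocarditis"]]
    max_gap_tokens: 1
    note_titles: ["cardiology", "electrophysiology", "infectious disease"]
    window_days: [3, 90]
    polarity: post_infection
  - id: pre-device-infection
    words:
      - ["cied", "device", "pacemaker", "defibrillator", "icd", "pocket", "lead"]
      - ["infection", "infections", "infected"]
    max_gap_tokens: 1
    note_titles: ["cardiology", "electrophysiology", "infectious disease"]
    window_days: [-90, -3]
    polarity: pre_history
  - id: pre-endocarditis
    words: [["endocarditis"]]
    max_gap_tokens: 1
    note_titles: ["cardiology", "electrophysiology", "infectious disease"]
    window_days: [-90, -3]
    polarity: pre_history

organisms:
  s_aureus:
    words: [["staphylococcus", "staph"], ["aureus"]]
    max_gap_tokens: 1
  coag_neg_staph:
    words:
      - ["coagulase", "coag"]
      - ["negative", "neg"]
      - ["staphylococcus", "staphylococci", "staphylococcal", "staph"]
    max_gap_tokens: 1
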