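# Methods

## Problem and approach

Healthcare-associated infections after cardiovascular implantable
electronic device (CIED) procedures — pacemaker or defibrillator pocket
infections, lead infections, endocarditis — are rare (roughly 1% of
procedures within 90 days), costly, and poorly captured by diagnosis codes
alone.  Exhaustive manual chart review is the reference standard but does
not scale to a national cohort.  `ciedwatch` implements a triage strategy:
derive a vector of cheap per-procedure *flags* from structured EMR streams
and from constrained keyword searches of clinical-note text, score each
procedure with a logistic model for the probability of a true 90-day
infection, and send only cases above a probability threshold (plus a small
safety sample below it) to manual review.

## Case definition (adjudication)

A 90-day CIED infection is present when the reviewed chart shows either
explicit physician documentation of infection, or at least two of:
documented symptoms (e.g. fever), positive laboratory tests, initiation of
antibiotic treatment — all within 90 days of the procedure.  Three
situations are excluded outright: infection already present at the time of
the procedure (the procedure is managing it, not causing it), superficial
cellulitis at a non-device site, and an isolated stitch abscess.
Exclusions take precedence over inclusion criteria; this precedence is a
design choice made explicit here because the criteria and exclusions could
in principle be composed either way.  Cellulitis *at the device site*
counts as a device infection (type `cellulitis_only`); cellulitis elsewhere
is the exclusion — the two are separate abstraction fields.  The
adjudicator consumes structured abstraction records; it does not parse raw
notes, mirroring the role of a trained human reviewer.  The abstraction
carries an optional reviewer-documented infection type that passes through
to the label; an infection meeting the criteria with no documented type
defaults to `pocket`, the dominant type.

## Flags

All windows are inclusive day intervals relative to the procedure date
(day 0); day arithmetic is calendar-date subtraction in whole days.

| flag | definition | window |
|---|---|---|
| `died_90d` | death date present | [0, 90) — death strictly before day 90 |
| `fever_30d` | any temperature ≥ 38.0 °C | [0, 30] |
| `icd_cied_infection`, `icd_ssi`, `icd_unspecified_infection` | ≥ 1 diagnosis code matching the configured prefix list (dots ignored; T82.7 matches T82.7XXA) | [0, 90] |
| `antibiotic_class` | qualifying course of a configured antibiotic: merged fills of one drug covering ≥ 3 consecutive days; staph-directed agents take precedence over other antibiotics | fills in [6, 90] |
| `micro_*_pos` | culture-positive specimen of that class **with** susceptibility testing | orders in [0, 90] |
| `micro_s_aureus`, `micro_cons` | organism keyword rules match the result text | orders in [0, 90] |
| `micro_order_no_staph` | ≥ 1 order in window and neither organism flag | [0, 90] |
| `note_infection_post` | any post-infection keyword rule matches a note | [+3, +90] |
| `note_infection_pre` | any history keyword rule matches a note | [−90, −3] |

Choices worth flagging:

- **Endpoint inclusivity** is not something "up to 30 days" phrasing pins
  down; both endpoints are inclusive here (mortality excepted: "< 90
  days") and every window is configurable.
- **The fever threshold is 38.0 °C** exactly (a configurable constant).
- **Antibiotic courses are computed from fills**, not administrations:
  covered days run from fill date through fill date + days supplied − 1,
  and overlapping or abutting fills of the same drug merge into one
  course.  A fill dated before day 6 never contributes (early
  postprocedure prophylaxis is not evidence of infection).  The
  staph-directed and other-antibiotic lists ship as editable config;
  drugs absent from both are not antibiotics for this purpose.
- **ICD code lists ship as editable config** (device-infection codes
  T82.6\*/T82.7\*, surgical-site-infection plus wound-dehiscence codes
  T81.4\*/T81.3\*, unspecified-infection codes A49.9/R78.81 by default);
  the SSI flag deliberately includes wound-dehiscence codes, which in
  practice are how these infections get coded.

## Keyword matching

A rule is an ordered sequence of word groups (each group a set of curated
spelling variants), a gap bound, a note-title filter, a day window, and a
polarity (`post_infection` / `pre_history` / `organism`).  Text is
lowercased and tokenized on punctuation/whitespace.  A rule matches when
its groups appear in order with at most `max_gap_tokens` tokens between
consecutive matched words — default 1, i.e. adjacent or one intervening
word.  Tight word-order-preserving matching with small gaps discriminates
far better than liberal any-order search in copy-paste-heavy clinical
prose, and curated variant lists beat stemming or edit distance for this
vocabulary, so there is deliberately no fuzzy matching and no negation
detection ("no evidence of infection" matches; the preprocedure-history
flag, not NLP, is the guard against stale text).  Matching is implemented
as a backward reachability sweep over token positions because a greedy
left-to-right scan is unsound under a gap bound (committing to the
earliest candidate for one group can strand the next group outside its
window); tests check exact agreement with a brute-force subsequence
enumerator.  Title filters are case-insensitive substring patterns
(exact note titles are site-specific).  The shipped ruleset (device /
pocket / pacemaker + infection, endocarditis, and staphylococcal organism
patterns for microbiology text) is a reasonable starting point, not a
validated instrument: every deployment should review and replace it.

## Triage model

A plain fixed-effects binomial-logit GLM (IRLS, convergence 1e-8 on
parameters, 100 iterations max) over the flag vector; the categorical
antibiotic flag enters as two indicators against reference "no qualifying
antibiotics".  The default covariate set is the one that carries the
signal: 90-day mortality, congestive heart failure, solid tumor without
metastasis, the device-infection and SSI code flags, the two antibiotic
indicators, positive cardiac specimen, and the two note flags.  No
facility random effects are modeled: the fitted object is a single
coefficient vector applied out-of-sample.  Odds ratios are reported with
Wald 95% CIs; the C statistic is the Mann–Whitney concordance of fitted
probabilities.

Several flags are rare enough that a finite cohort can (quasi-)separate:
the plain MLE then diverges and `fit` raises a diagnostic naming the
separating covariate.  Firth's bias-reduced fit (Jeffreys-prior penalized
likelihood, Newton iterations on the modified score) is provided and is
the recommended response; the pipeline falls back to it automatically and
logs that it did.

The default review threshold is a predicted probability of 0.10, applied
as ≥ (so the threshold coincides with the 10% band edge of the report
tables).  The review queue is drawn by seeded simple random sampling
without replacement: 80% of above-threshold cases and 1% of
below-threshold cases by default, with stratum sample sizes
round(fraction × stratum size).

## Evaluation

All accuracy metrics are computed **over reviewed cases only** (partial
verification): PPV = TP/(TP+FP) among reviewed above-threshold cases,
sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP) over the reviewed
set.  No verification-bias correction is applied — the numbers reproduce
exactly the arithmetic a review-sampling deployment produces, and they
should be read with that caveat: unreviewed false negatives are invisible,
so sensitivity is conditional on the review design.  Confidence intervals
are Clopper–Pearson exact binomial (95%).  AUC is the Mann–Whitney
concordance probability with midrank tie handling; ROC points are taken at
every distinct threshold.  Cohen's κ is available for inter-rater checks,
with the degenerate convention κ = 1 when both raters assign one identical
constant label.  Band tables partition [0, 1] into bands [lo, hi) (last
band closed) — default edges 0, 1%, 3%, 10%, 50%, 100% — and report cohort
count, reviewed count, true infections, and band PPV.  Displayed
percentages use half-up rounding to one decimal.  A zero denominator makes
a metric *undefined* (reported as null), never 0.

## Synthetic cohort generator

The generator emulates the statistical structure the algorithm assumes,
not clinical realism.  Each procedure draws a status: **infected**
(prevalence 0.008), **preexisting infection** (0.007), or **background**.
Infected cases draw an onset day from a truncated normal (mean 35 d, SD
21 d, support [3, 90]) and an infection type (pocket 0.831 /
endocarditis-lead 0.149 / cellulitis 0.020), then emit each documentation
signal with a conditional probability (device-infection code 0.787,
postprocedure note keyword 0.957, staph-directed antibiotic course 0.638,
positive blood culture 0.872, positive cardiac specimen 0.447, fever
0.149, death 0.149, …) at dates tied to the onset.  Background cases emit
the same signals independently at marginal noise rates (device code
0.038, note keyword 0.078, staph-directed course 0.164, …): the realistic
fog of unrelated antibiotics, incidental cultures, and non-device
infections.  Preexisting-infection cases are the planted failure mode the
history flag exists to counter: they carry infection keywords in
preprocedure notes (0.95) and, with copy-forward fraction 0.8, repeat the
same phrase after day 0, alongside treatment signals (device code 0.5,
staph antibiotics 0.7, cultures).  Conditional rates were fixed once from
the flag profile such a surveillance cohort exhibits; the preexisting-case
rates encode the copy-forward mechanism rather than any printed marginal.
Note text is filler vocabulary (disjoint from every rule keyword) with
the phrase planted at a random position, half the time with one
intervening token, to exercise the gap semantics; a fraction of
procedures also receives a keyword-bearing "patient instructions" note
that the title filter must ignore.  Antibiotic courses are sometimes
split into two short overlapping fills that qualify only after merging.

Signals are drawn **independently given status**, which real documentation
is not: a real infected chart tends to accumulate code, note, culture and
antibiotic evidence together.  Independence produces a heavier tail of
single-signal infected cases than real data shows, so cohort-wide
(full-verification) sensitivity of the synthetic pipeline understates what
correlated documentation yields; the reviewed-case metrics are the
designed estimand.  Chart abstractions are generated consistently with
the planted truth — for infected cases the criteria are forced coherent
with the label, for background cases at most one device-attributable
criterion is recorded — so adjudicating the abstractions reproduces the
truth labels exactly (a tested invariant).  All randomness flows from one
seeded NumPy generator with a fixed per-procedure draw order: a (config,
seed) pair fixes every output file byte-for-byte.

## End-to-end pipeline and problem sizes

`run_pipeline` simulates paired development/validation cohorts (default
9606 procedures each, split from one seed), extracts flags, fits on the
development cohort against its full ground-truth labels (simulation is
omniscient; a real deployment would fit on its reviewed sample), applies
the model out-of-sample, draws the review queue, and evaluates over the
queued cases.  Unit tests run cohorts of a few hundred to 20 000
procedures; the acceptance script uses 9606 per arm and the end-to-end
property tests 10 000 — sizes at which binomial checks on planted rates
(3 SE) and coefficient-recovery checks (2 SE) are sharp, and a full run
takes seconds on one CPU.

## Known limitations

- No negation or temporality handling in text matching beyond day windows
  and the history flag.
- Metrics are uncorrected for partial verification; two-phase-design
  estimators are out of scope.
- The shipped keyword, ICD, and antibiotic lists are editable stand-ins,
  not validated site lists.
- Comorbidity indicators are consumed, never computed.
- The generator's conditional-independence assumption (above) bounds what
  passing synthetic tests can say about real charts: they validate the
  machinery and its statistical behavior, not clinical performance.
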