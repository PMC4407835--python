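# Methods

This note documents the modelling choices behind `espre`: what each stage
assumes, the parameters that matter, what the synthetic worlds do and do
not emulate, and the numerical conventions.

## Text normalization and concept extraction

All text — terminology synonyms, criteria, notes, diagnosis labels — is
normalized identically: lowercased, characters outside `[a-z0-9]` treated
as separators, tokens being maximal alphanumeric runs. This is deliberately
coarse; it makes dictionary lookup, trigger matching and bag-of-words keys
operate at one shared granularity and keeps the pipeline deterministic.
The cost is that dotted acronyms ("C.N.S.") split into single letters and
will not match a multi-letter synonym; the bundled terminology therefore
lists surface forms as they appear undotted in text.

Concept extraction is greedy leftmost-longest dictionary matching over
token sequences. The match window is bounded by the longest indexed phrase,
matched spans never overlap, and the scan is equivalent to enumerating all
matching sub-spans and repeatedly taking the earliest-starting, longest one
(the test suite checks this equivalence against an independent enumerator
on small texts). There is no word-sense disambiguation: an ambiguous
surface form must simply not be indexed if it would fire spuriously.

## Negation and signed keys

Negation follows the NegEx scheme with pre-negation triggers only. A
mention is negated when a trigger phrase ends at most `window − 1` tokens
before the mention starts, the trigger is not embedded in a pseudo-negation
phrase, and no scope terminator or pseudo-negation begins between trigger
and mention. The window defaults to 5 tokens, the customary choice for this
family of detectors, and is configurable. Post-negation patterns
("… is unlikely") and finer assertion classes (hypothetical, family
history) are out of scope; the trigger lexicon is a plain-text file
(`[PRE]`/`[PSEUDO]`/`[TERM]` sections) so deployments can extend it.

Vectors are binary sets of signed keys: `c` for an asserted concept,
`NEGc` for a negated one, optionally `w:token` for non-stopword tokens
outside any mention (on by default for narrative text, off for structured
diagnosis labels, whose bare labels also never run through negation — a
problem-list entry asserts presence). A vector never holds both `c` and
`NEGc`; when sources conflict — a note denying a finding, a diagnosis
asserting it — the asserted key wins, on the reasoning that clinical text
asserting a finding anywhere is stronger evidence for matching than a
negated mention elsewhere. Exclusion-criteria vectors are polarity-flipped
before merging into the trial profile. With the default configuration
negation detection also runs inside exclusion sections first, so "no prior
chemotherapy" under exclusion composes (negate, then flip) into an
asserted prior-chemotherapy requirement; the alternative — flipping raw
asserted terms only — is available as `negex_in_exclusion: false`, since
the clinical intent of double-negated exclusions is genuinely ambiguous.

## Demographics and time

Age bounds parsed from criteria are stored as whole-day durations
(1 year = 365.25 d, 1 month = 30.44 d, rounded); strict bounds ("younger
than 18 years") are stored as the adjacent inclusive day (6573 d), which
is equivalent at whole-day granularity. A patient passes a trial's filter
when their age on *some* day of the enrollment window lies within bounds —
the least restrictive reading, chosen because it can only add candidates,
never silently drop an eligible one — and when they have at least one
clinical note dated inside the window (no in-window notes means the
patient was not under the institution's care during enrollment). Dates are
whole days throughout; the closing date itself is included in the visible
window, while for enrolled patients only entries strictly before the
enrollment date are visible, reflecting what the deciding physician could
have known.

## Matching score

The score is a binary cosine with a subtractive contradiction penalty,
`(|T∩P| − λ·n_contra)/√(|T||P|)`, λ = 1 by default. The penalty term is
what makes the signed representation consequential: a patient asserting a
concept the trial excludes is pushed below unrelated patients rather than
merely not gaining. λ = 0 recovers plain cosine for sensitivity analyses.
The score is symmetric, bounded above by the cosine, and equals 1 exactly
for identical non-empty vectors without penalties. Ties in ranking are
broken by candidate id for reproducibility. No tf-idf weighting, query
expansion or supervised re-ranking is attempted.

## Evaluation framework

Workload is the 1-based rank of the deepest reference positive; anchors
with no positives cost their full post-filter list, and a positive removed
by the demographic filter (a filter error) costs the whole universe, so
the evaluation can never silently reward an unsound filter. Recall and NPV
are 1 by construction at this cutoff; precision k/WL and specificity
(N−WL)/(N−k) (defined 1 when N = k) follow from the confusion matrix with
FN = 0. Aggregation reports the mean workload with a 95% Student-t
interval (degenerate at the point for a single anchor or zero variance)
and both micro- (pooled counts) and macro- (mean of ratios) averaged
precision/specificity; micro is the headline since pooled figures are what
a screening service experiences. The paired comparison of two algorithms'
per-anchor workloads is a two-sided paired t-test, with the zero-variance
branches made explicit (all-zero differences → p = 1, constant non-zero
shift → p = 0).

The random-baseline expectation k(N+1)/(k+1) is the mean of the maximum of
k positive positions in a uniform permutation of N; the tests verify it by
exhaustive enumeration for N ≤ 7 and by 2,000 seeded shuffles at N = 50.

Chart-review arithmetic follows the printed worked example bundled under
`src/espre/data/`: pooled historical precision Σhits/Σoutputs and
clinician-adjusted precision Σ(hits+additional)/Σoutputs are rounded to
2 decimals before the relative improvement (1 decimal, as a percentage) is
taken, and projecting that improvement onto a base precision rounds to
3 decimals and caps at 1. The error-category breakdown truncates (not
rounds) the grouped categories-3–5 share to 1 decimal and rounds single
categories to whole percents — these conventions reproduce the published
figures exactly and are fixed in code rather than configurable.

## Synthetic worlds

The generator plants known truth so every stage is testable end-to-end:
each trial gets a signature of 4 inclusion concepts and 2 exclusion
concepts (pairwise disjoint across trials whenever the concept pool
allows, which the defaults do); eligible patients receive one plant note
per trial, dated inside the window and before any enrollment date,
mentioning each signature concept with probability `signal` plus
background distractors at `distractor_rate`; ineligible patients draw only
from a background pool disjoint from every signature. Criteria templates
use stopword-only filler around concept phrases, so a trial vector shares
nothing with a non-eligible patient's notes. Consequently at
`signal=1.0, distractor_rate=0.0` eligible patients strictly outrank all
others, and with `enrollment_prob=1.0` workload equals the positive count
and precision is 1 for every anchor — the recovery invariant. The full
recovery condition is run with `enrollment_prob=1.0` deliberately: with
partial enrollment an unenrolled-but-eligible patient can legitimately
outrank an enrolled one, raising workload without any algorithm defect.

Defaults (20 trials, 100 patients, 150 concepts, 2–40 notes of 50–300
tokens, 90% enrollment of eligibles) echo the order of magnitude of a
single-institution pediatric-oncology screening cohort, including the
near-universal enrollment of eligible pediatric patients; these sizes also
keep a full two-direction run in the low seconds on one CPU, which is the
problem size the test suite and the acceptance script use. What synthetic
worlds do *not* emulate: real clinical language (templated sentences
only), terminology ambiguity and misspellings (except via the corruption
harness), quantitative lab criteria, medication records, and inter-trial
semantic similarity. Passing recovery tests therefore demonstrates the
correctness of the pipeline mechanics, not expected precision on real
EHR text. The corruption harness (`typo_injection`, `negation_flip`,
`date_shift`) provides controlled degradation for robustness checks,
emulating the dominant real-world error modes: lexical mismatch, wrong
assertion status, and late-arriving documentation.

## Known limitations

* Dictionary matching with a flat terminology cannot separate disease
  sub-categories sharing most surface words ("T-cell" vs "Pre-B-cell"
  lymphoblastic lymphoma collapse unless both phrases are indexed
  distinctly) — the dominant error mode in chart-reviewed deployments of
  this architecture.
* The matching formula is a design choice of this package (the vector
  family is standard information retrieval); alternatives can be swapped
  in behind `match_score` without touching ranking or evaluation.
* Quantitative eligibility logic (lab thresholds, dosing history) is out
  of scope; criteria sentences carrying it contribute only their words.
* Single-institution, retrospective framing: the evaluation measures
  effort to reproduce historical decisions, not prospective yield.
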