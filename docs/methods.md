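# Methods

## The phenotype and the rule

The Asthma Predictive Index (API) labels a young child as likely asthmatic
when two conditions hold together:

1. **Frequent wheezing** — at least `min_episodes` (default 2) distinct
   wheezing episodes within a trailing window of `wheeze_window_days`
   (default 365, boundary-inclusive: episodes exactly one year apart
   qualify);
2. at least `min_major` (default 1) **major** criteria — parental
   physician-diagnosed asthma, or eczema in the patient — **or** at least
   `min_minor` (default 2) **minor** criteria — allergic rhinitis,
   wheezing apart from colds, or a blood eosinophil differential at or
   above `eos_threshold_pct` (default 4%, boundary-inclusive).

The **index date** is the earliest calendar date on which the accumulated
evidence satisfies the whole rule; operationally it is the earliest
evidence date `d` such that frequent wheezing is established on or before
`d` and the major/minor count over criteria satisfied on or before `d`
meets the threshold. Because the rule is monotone in evidence, the index
date is the maximum of the completing criteria's satisfaction dates, and
`classify_api` is verified in tests against a brute-force scan over all
candidate dates.

Episodes are collapsed **per calendar date**: repeated documentation of
wheeze on one day is one episode. Whether later-dated major/minor evidence
may complete the rule at an earlier wheeze date is genuinely open in
retrospective use; this package counts evidence **on or before** the
candidate date (`evidence_timing`), which makes truncation consistency
hold exactly: removing all data after the index date preserves the result,
removing anything at or before it can only lose the label.

## Text processing

Extraction is deliberately rule-based and deterministic — the level of
machinery that section-constrained pattern matching with assertion status
actually needs — so every decision is auditable in the mention trace.

* **Sectioning.** Header lines (case-insensitive, colon or standalone
  line, longest match then rule order) open typed sections that tile the
  note. The shipped lexicon covers the common pediatric note headers;
  only the family-history and diagnosis/impression sections carry policy
  weight downstream.
* **Sentences.** Split on `.?!` and newlines with an abbreviation and
  decimal guard; spans tile the text, so offsets always round-trip.
* **Concepts.** Literal whole-word phrase patterns per concept (wheeze,
  cold, eczema, allergic rhinitis, asthma), editable YAML. Overlapping
  matches of one concept merge to the longest ("common cold" beats
  "cold").
* **Assertion.** NegEx-style: a negation trigger preceding the mention in
  the same sentence within a 6-token forward window negates it, unless a
  scope terminator ("but", ";", …) intervenes. Hypothetical triggers
  ("if", "rule out", "watch for") use the same scoping for temporality.
  Negation scope never crosses a sentence boundary.
* **Experiencer.** A parent term anywhere in the sentence attributes the
  mention to a parent; other-relative terms to other family; a mention
  inside the family-history section with no named relative is treated as
  parental by default (`strict_parent_attribution=False`). Strict mode
  demands a named parent, reflecting that the API major criterion is
  specifically parental; the default is lenient because family-history
  sections of pediatric charts overwhelmingly record parental history.
  Known limitation: "mother reports wheezing" would mis-attribute the
  wheeze to the mother; the sentence-level heuristic has no argument
  structure.
* **"cold" sense.** The word "cold" is the illness unless its immediate
  context is an enumerated temperature/sensation pattern (following noun
  in {air, compress, intolerance, water, …} or preceding sensation verb
  {feels, felt, got, …}). Multiword and plural forms ("head cold",
  "colds", "URI") are always the illness. This addresses the documented
  failure mode where "wheezing without cold" / "cold air" contexts
  corrupt the wheezing-apart-from-colds minor criterion; the shipped
  42-sentence labeled bank pins the behaviour in tests.

Patient-level asthma mentions are retained in traces for audit but are
never an input to the rule — the index predicts asthma, so only parental
asthma counts as evidence.

## Structured evidence

Eosinophil **percentages** are used as printed; absolute counts are
ignored rather than converted (unit-safe, no reference-range guessing).
Every percentage in the record is eligible regardless of indication.
Parental asthma is the deduplicated union of questionnaire yes-answers
(PPI) and affirmed, current, parent-experiencer text mentions; removing
one source can only delay or remove evidence, never create it.

## Validation statistics

Criterion validity: the 2×2 agreement table with Cohen's kappa
(`(p_o − p_e)/(1 − p_e)`), agreement, sensitivity, specificity, PPV, NPV —
all returned unrounded; display rounding is formatting-only, since
published percentages are sometimes truncated rather than rounded (tests
compare numerically, never by string). Kappa is cross-checked in tests
against scikit-learn's implementation, which is never the implementation
path. Stratified tables always sum cellwise to the pooled table.

Construct validity: cross-product odds ratios with Wald 95% CIs on the
log scale (`exp(ln OR ± 1.96·SE)`, `SE = sqrt(1/a+1/b+1/c+1/d)`); this
method reproduces the published risk-factor CIs from their printed cells.
A zero cell triggers the Haldane–Anscombe 0.5 correction with an explicit
flag; an empty margin is undefined and raises. Continuous covariates use
a univariate logistic fit (statsmodels, Newton, tol 1e-10, max 100
iterations); non-convergence and separation are flagged, never returned
silently. For a binary covariate the logistic OR equals the closed-form
cross-product OR to 1e-8 (tested both ways). Wald p-values are computed
for completeness; exact intervals and multivariable models are out of
scope.

## Synthetic corpus generator

The generator emulates a population birth cohort followed from birth for
about seven years: default 200 patients, API prevalence 8–10%, 48% male,
74% white, roughly half late-preterm — the regime the method targets. Each
patient receives a *plan* (wheeze episode dates, criterion evidence dates,
distractors), rendered into sectioned notes from a fixed template bank,
labs, and PPI records. Gold labels are **entailed**: the rule logic runs
on the plan itself, so labels are provably consistent with the documents,
and intended-status contradictions raise instead of emitting bad gold.
Negative patients draw one of four failure modes (no wheeze; a single
episode; a 366–520-day episode gap; frequent wheeze with all wheeze notes
cold-associated and at most one other minor), so every boundary of the
rule is populated.

Distractor channels (negated mentions, sibling/family-attributed
mentions, hypothetical phrasing, temperature-sense "cold") are injected
at configurable rates; `inject_noise` additionally supports dropping the
PPI stream, corrupting cold-free wheeze notes into URI notes, and pushing
a wheeze episode outside the window. Noise draws are made for every
candidate regardless of rate, so sweeps over rates with a fixed seed
corrupt nested subsets and monotone comparisons are meaningful.

Risk-factor covariates are sampled conditionally on the entailed status
with configured odds multipliers (defaults in the published effect-size
range: parental asthma history 5.8, eczema 2.7, allergic rhinitis 3.4,
maternal smoking 4.4). They are sampled independently of the planted note
text, so a patient can carry an eczema *covariate* without an eczema
*note*; the covariates emulate an external risk-factor table, not the
chart. `simulate_covariate_cohort` provides the text-free path for
coverage experiments (exact planted conditional OR by construction).

What passing on synthetic corpora does **not** show: robustness to real
clinical prose (spelling noise, telegraphic style, coreference, templated
boilerplate), to section-header variation beyond the shipped lexicon, or
to assertion constructions outside the trigger lists. The generator's
templates are drawn from the same grammar the extractor parses; perfect
recovery demonstrates internal consistency and rule correctness, not
field performance.

## Numerical and degenerate-input choices

* Window and threshold comparisons are boundary-inclusive (`≥ 4%`,
  `≤ 365 days`), per the rule's published wording.
* Same-day lab and text evidence both count on that day (no intra-day
  ordering).
* Kappa on a degenerate table (one class absent for both raters) is
  `None`, never a number.
* Header ties: longest match, then rule order. Mention ties on a date:
  irrelevant — criteria are counted, not ranked.
* Problem sizes in tests and the acceptance script (200-patient
  end-to-end corpus; 1,000-instance oracle equivalences; 100 replicates
  of n=5,000 for covariate recovery) were chosen to make every boundary
  and property statistically meaningful while keeping the default suite
  fast to iterate.
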