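# Methods

This note records how the package models the P3C-OCT, the choices made
where the published scoring scheme is silent, and what the synthetic-data
generator does and does not emulate.

## Instrument encoding

The instrument schema distinguishes *activity* codes, an optional *Other*
box (scoreable, since write-in activity is evidence of activity), and the
non-scoring markers *None* and *Not relevant*. Every objective part carries
exactly one None marker, at most one Not relevant marker and at most one
Other box. A question may have several objective parts; scoring pools their
codes.

The bundled instrument reproduces the published structure exactly:

* 29 core questions; level listings 11 / 4 / 12 / 4 (person-practitioner,
  practitioner-practitioner, organisational systems, information
  systems/IT). These listings sum to 31, so two organisational-systems
  questions with a strong IT character (Q18, Q19) are double-listed under
  information systems; the instrument file flags this rather than silently
  resolving it.
* Six domains whose item counts are 6 / 2 / 14 / 6 / 6 / 8 and sum to 42
  over 29 distinct questions. A question therefore has one *primary* domain
  (used for domain scores, so nothing is double-counted within a domain
  mean) plus subdomain taps that may cross domains (used for the item
  counts and the overlapping subdomain views). The per-subdomain item
  counts (goal setting 2, case management 7, continuity of care 6, ...) are
  reproduced exactly.
* 435 scoreable response codes in total. We read the published count of
  "possible components/response codes" as counting the scoreable codes —
  the activities organisations can action, including each Other box — and
  not the None/Not relevant markers, which are not components of care.
* Q4 (the care-plan element checklist) is encoded verbatim: nine named
  elements plus Other = 10 scoreable codes, with None and Not relevant as
  markers. Q1 has eight scoreable codes; the count is only consistent with
  the stated per-activity weight of 1.25 if the Other box is one of the
  eight, so it is. Q6 has two pooled parts (6 + 4 scoreable codes), the
  second on personal budgets, so its objective maximum remains 10.
* The full wording of most activities is not published; those labels are
  systematic placeholders flagged `placeholder: true` in the serialised
  file so they can be replaced without code changes. Placeholder labels
  never affect scoring, which depends only on code identity and category.

Counts-by-structure (29 questions, level/domain/subdomain totals, 435
codes) are properties of the bundled instrument asserted by the test suite,
not schema invariants: the loader accepts any structurally valid
instrument, which is what makes small randomised instruments usable in
oracle tests.

The canonical serialisation is sorted-key JSON (YAML is accepted on input),
making round-trips byte-stable.

## Scoring

Let a question have *n* pooled scoreable codes of which *k* are ticked, and
let *m(r)* be the multiplier of its Likert rating *r*.

* objective = *k · 10/n* ∈ [0, 10].
* subjective, default `scaled_by_objective` mode: *objective · m* ∈
  [−10, 10].
* total = objective + subjective ∈ [0, 20] under the default mode.

The default multipliers are 1, 0.5, 0, −0.5, −1 from "working very well"
down to "not working" — the unique evenly spaced progressive scale spanning
+1 to −1. Any strictly decreasing scale with those endpoints may be
substituted through `ScoringPolicy`.

**Why subjective scaling is the default.** The published scheme shows one
Likert rating per question yet describes the subjective maximum as divided
across response codes, with −10 meaning "all activities are not working".
Scaling the single rating by the objective score is the one reading that
satisfies both printed anchors simultaneously: full activity rated not
working gives 10 − 10 = 0, "the same score as not implementing an activity
at all", and no activity gives 0 regardless of rating. The alternative
reading — an independent ±10 block per question — is retained as
`subjective_mode = "independent_additive"`, with the subjective score
forced to 0 when nothing is ticked so the inactivity anchor still holds.
Under that mode, a question whose Not relevant marker is ticked scores 0
like everything else unticked; the two modes differ only when activity is
present.

A blank Likert falls back to the "not working" multiplier (the published
equivalence of *not relevant*, *none* and *not working*); this is
consequential only when activities are ticked but the rating was skipped.

**Unanswered questions.** A core question absent from a response file
scores 0 under the default `score_zero` policy — absence of evidence of
activity scores like no activity, and denominators stay constant across
timepoints, which matters for change detection. The alternative
`exclude_from_denominator` drops unanswered questions from every mean.

**Conflicts.** Ticking None or Not relevant together with an activity *of
the same part* is a validation error and is never silently scored; across
different parts of a multi-part question the combination is legitimate
(activity in one part, none in the other).

No rounding occurs during computation; one-decimal rounding happens only in
the dashboard rendering layer.

## Aggregation and benchmarking

The instrument total is the mean of the 29 question totals — equal
weighting with an exact maximum of 20; summing and rescaling is
algebraically identical. Domain and level scores are means over member
questions (primary-domain membership for domains; level listings, including
the two secondary listings, for levels). Benchmark deltas are organisation
minus reference at every granularity; with the cohort mean as reference
they sum to zero across the cohort. Percentile ranks use the mid-rank
convention 100·(#below + ½·#equal)/N, so a cohort of identical scores sits
at the 50th percentile and a unique maximum in a cohort of four at 87.5,
not 100.

## Change analysis

`paired_change` implements the paired Student's t-test on any card metric
(total or a domain), using only organisations present at both timepoints
(no imputation; exclusions are counted and logged). Two-sided p-values are
the conservative default. Zero-variance differences are reported as *t* = 0,
*p* = 1 when the mean difference is also zero and raise a
`DegenerateVarianceError` otherwise — never a silent NaN.

## The synthetic-data generator

Each organisation has a latent maturity θ ∈ [0, 1] coupling both halves of
the instrument:

* every scoreable code is ticked independently with probability θ, so the
  expected objective score of every question is exactly 10θ; when a part
  gets no ticks its None marker is ticked, as a real respondent would;
* the Likert rating comes from a proportional-odds model: a logistic latent
  judgement centred on θ with scale 0.15 is cut at 0.2 / 0.4 / 0.6 / 0.8,
  so θ = 0.5 centres the distribution on "requires some improvement" and
  the expected rating rises smoothly with maturity. This encodes the
  working assumption that activity and perceived functioning co-vary
  through a single organisational capability.

Defaults emulate a mid-maturity 40-practice cohort assessed twice about six
months apart: θ ~ Beta(5.3, 4.7) (mean ≈ 0.53, SD ≈ 0.15), giving
first-timepoint mean totals near 6 of 20, and an additive improvement
δ applied to θ at the second timepoint (truncated to [0, 1]) with response
noise independent between timepoints. δ ≈ 0.04 produces an expected
total-score improvement of about 0.9 points at these defaults. δ acts on
the latent maturity, not on scores, so score-scale effects emerge through
the actual scoring engine.

Randomness derives from one root seed with per-organisation,
per-timepoint substreams keyed by counter, so enlarging a cohort never
reshuffles existing organisations and identical configurations yield
byte-identical output files.

**What the generator does not emulate.** Real response sets have correlated
ticks within questions, respondent-specific Likert styles, item
missingness, free-text content, and practice-size/rurality effects; the
generator has none of these, and its between-timepoint noise (binomial tick
noise averaged over 29 questions) is far smaller than the between-practice
heterogeneity a real cohort would show. Passing calibration tests therefore
demonstrates internal correctness of the pipeline — not that real cohorts
would show the simulated power. In particular, the power of the paired
t-test at a 0.9-point shift is near 1 under the generator's noise model,
whereas a real cohort with a difference SD of ~2.6 points would sit near
the boundary of significance at n = 40; the generator's SD can be inflated
by widening the Beta distribution or δ heterogeneity if that regime is of
interest.

`power_simulation` uses a vectorised score-level path: because the
objective score depends only on the *count* of ticked codes
(k ~ Binomial(n, θ)) and the default question total is objective·(1 + m),
cohort totals can be drawn directly with the same distribution as the full
object-level pipeline (an exact marginalisation, verified in the tests),
making 2,000-replicate power grids a matter of seconds.

## Numerical and interface choices

* Scores are plain double-precision arithmetic; test tolerances are 1e-9
  against the brute-force oracle and the scipy paired-t reference.
* Percentile and benchmark computations define ties by exact float
  equality, which is appropriate because tied cards are usually exact
  copies.
* The dashboard CSV/JSON outputs are byte-deterministic for identical
  inputs; the HTML embeds a generation timestamp and standard caveats about
  interpretation (aggregation hides nuance, context and organisation size
  mediate scores, and scores carry the respondent's subjectivity).
* The CLI (`oct`) is a thin wrapper: every verb is one library call plus
  I/O. HTML is rendered from a small built-in template with all numbers
  precomputed; templates never calculate.

## Problem sizes

The test suite exercises 1,000 random small instruments against the
brute-force oracle, 100 random datasets against the scipy paired-t
reference, 2,000 simulated 40-practice cohorts for type-I-error
calibration, a 3 × 2 power grid at 500 replicates, and 500-organisation
cohorts at three maturity levels for monotonicity — sizes chosen so the
Monte-Carlo error is small relative to the effects being checked while the
whole suite runs in well under a minute.

## Known limitations

* Most activity wordings are placeholders pending the published appendix;
  structure and scoring are unaffected.
* The two-question double-listing across operational levels and the
  domain-item overlap are modelled (secondary levels, cross-domain
  subdomain taps) but the specific questions chosen for the double listings
  are an editorial choice.
* The flat CSV surface cannot carry demographics; use the JSON surface when
  demographics matter.
* Benchmarks are not risk-adjusted for practice size or rurality; those are
  interpretation caveats, not model terms.
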