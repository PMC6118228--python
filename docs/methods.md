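# Methods

`lexitrain` simulates and analyses an adaptive word-reading training therapy
for central alexia (acquired reading impairment with aphasia after left-
hemisphere stroke), together with the crossover randomized-trial machinery in
which such a therapy is evaluated: matched stimulus lists, an exposure/
challenge training engine with three coupled difficulty parameters, a
synthetic learner, minimization randomization, a six-timepoint crossover
schedule with an anodal-tDCS condition modelled as a learning-rate
multiplier, and the outcome statistics (effect sizes, mixed repeated-measures
ANOVA, non-parametric and single-case tests).

## Synthetic lexicon

Real therapy builds its word lists from a subtitle-frequency corpus; the
package generates a statistical stand-in. Word forms are 3–6 letter strings
built from alternating consonant/vowel chunks (so letter bigrams resemble a
natural orthography and pseudowords can be sampled from attested bigrams).
Per-million frequencies are i.i.d. draws from a Pareto tail
(P(F > f) = f^(−α), α configurable; default 1.1 standalone, 0.6 inside trial
simulations so that enough types clear the 50-per-million training threshold
on an 8 000-type lexicon). The highest-frequency stratum is flagged as
function words and draws imageability from a low mixture component
(N(2.0, 0.5) on the 1–7 scale) while content words draw from a broad high
component (N(4.5, 1.2)); this supports the 40th-percentile imageability
split in the exploratory analyses. Syllable count is the vowel-group count —
deterministic and testable. Training candidates must exceed the frequency
threshold (strictly), be 3–6 letters, contain no hyphen/apostrophe, and at
most one member of each regular morphological family is retained (suffixes
s/es/ed/en/ing with e-drop and final-consonant doubling; the scanner keeps
the most frequent member). The morphological rule and the pseudoword
parameterization are explicit package choices, not reconstructions of the
original software.

## Matched lists

Words are stratified by (length, syllables), which therefore match exactly
within a triplet; log-frequency and imageability are z-scored and matched by
greedy nearest-neighbour triplet formation (scarcest strata first) followed
by swap-based local search, then triplet members are assigned to lists A/B/C
greedily to keep running list-level sums balanced. On 9-word toy pools the
greedy+refine cost is within 10% of the exhaustive optimum (tested). The 50
highest-frequency candidates (ties alphabetical) form the separate core
list before matching. Per-patient customization — selecting 150 of 180
triplets, with optional within-triplet rotations, matched on baseline
accuracy (≤ 2 pp pairwise) and RT (≤ 50 ms) — and testing-subset selection
(90 + 90 + 90 + 30 items whose mean baseline accuracy stays within 2 pp of
the full-corpus mean, a guard against regression to the mean) both use
seeded simulated annealing; an unreachable tolerance returns the best
assignment found, flagged non-conforming with a diagnostic, never silently.
Tolerances in the scaled-down test fixtures are widened to the granularity
of one item score-step.

## Training engine

Each cycle pairs a 10-trial passive exposure phase (picture + written +
spoken forms; one familiarity update per event; speaker voice randomized)
with a challenge phase of up to 30 same/different trials, half same/half
different, randomized within successive pairs so every prefix stays balanced
to one trial even under early stopping. Scoring: +2 fast correct, +1 slow
correct, −1 incorrect; reaching the criterion score passes the level.
Difficulty derives from a level counter via three coupled parameters:
written word duration (initialized at the patient's baseline reading speed,
−50 ms per level, floor 100 ms), criterion score (16 + 2 per level, cap 60),
and the fast/slow RT boundary (initialized at the baseline median RT,
−50 ms per level, floor 400 ms). Stepping duration and the RT boundary
*down* while the criterion steps *up* is the only reading under which all
three changes make the task harder. Passing advances one increment; three
successive failed levels revert one increment (floor at level 0). The
increments and initial criterion are configuration with documented defaults.
A phase can optionally stop early once the criterion is unreachable in the
remaining trials; the default runs all 30 trials. Independently each word
carries an easy/medium/hard distractor staircase moving one step per
response. Distractors share the target's length and first letter and are
tiered by positionally shared letters (easy = 1, hard = length−1, medium
between, nearest to half the length preferred) — the only reading that
orders the canonical heap/hood/hard example monotonically; three-letter
words have no strict medium count and degenerate to the hard count. Tiers
without real-word candidates are filled with synthesized pseudowords of the
required overlap so every target stays trainable. Sessions alternate phases
until a 40-minute budget is spent (4 s per exposure trial, 3 s per challenge
trial); blocks run stimulated face-to-face sessions (11 by default) then
unstimulated home sessions until the cumulative dose reaches 35 h.

## Synthetic learner

A learner is a per-word familiarity bank f ∈ [0, 1] plus an ability offset.
Same/different accuracy is guessing-corrected logistic:
P = 0.5 + 0.5·σ(ability + 3f + 0.5·log(duration/1 s) − 0.75·tier). Oral
reading is trinomial with P(correct attempt) = σ(ability + 6(f − 0.5)),
self-correction probability 0.05 (scored 0.5), and a log-normal voice-key RT
around base 800 ms + 1700 ms·(1 − f); onsets beyond the 4-s window score 0.
Learning is a saturating update f ← f + η·m·(1 − f) per exposure event,
with m the stimulation multiplier during anodal stimulation (first 20 min of
face-to-face sessions) and 1 otherwise; under anodal stimulation every other
word receives spillover g·η·(m − 1)·(1 − f). Scaling spillover by (m − 1)
makes a multiplier of exactly 1 completely null — the property the type-I
error study relies on — while reproducing generalization to untrained words
when m > 1. Deficits (1 − f) transform multiplicatively under every update,
so updates commute and block-level training has an exact closed form given
the deterministic least-recently-trained round-robin schedule; the
"aggregate" trial fidelity uses this closed form (with a fixed average
challenge length of 20 trials to convert the time budget into exposure
events), and its equivalence to per-event updates is unit-tested.
Forgetting relaxes familiarity toward its pre-training baseline,
f ← f₀ + (f − f₀)e^(−λ·days); each assessment applies a small global
practice bump ε(1 − f) reproducing test-retest gains.

Defaults were calibrated once, by a closed-form dose calculation checked
against a handful of probe cohorts, to the group-level behaviour of the
published trial: η = 0.0023 and the RT span give ≈ 8–10 pp trained-word
accuracy gain and ≈ −100 ms RT gain over a 35 h block; practice ε = 0.02
gives ≈ 1 pp test-retest gain; m = 3.0 with g = 0.005 gives ≈ 2.6 pp anodal
facilitation that generalizes to untrained words; λ = 0.004/day leaves
roughly 70% of the gain after the 90-day follow-up. Baseline severity is a
per-learner Beta familiarity distribution whose means span roughly 5–95%
reading accuracy, centred near the published cohort mean of 57%.

What the generator does **not** emulate: item-level psycholinguistic
difficulty (frequency/imageability affect list construction but not the
learning rule), error taxonomy (semantic vs. visual errors), the observed
under-performance of core function words (simulated core words train in both
blocks and therefore gain *more* than list words, where the published cohort
gained less), speed–accuracy trade-offs, and participant drop-out. Passing
tests therefore validate the machinery and the design's statistical
calibration, not patient-level realism.

## Trial design and analyses

Allocation is Pocock–Simon minimization over baseline accuracy × RT
terciles (range method, biased coin p = 0.8) under a hard cap of ⌈N/2⌉ per
arm — the "block" component that fixes 21 arrivals at a 10/11 split. List
roles (trained block 1 / trained block 2 / untrained) cycle the six
permutations across participants; core words train in both blocks. The
schedule is T1–T5 at 28-day spacing with T6 90 days after T5; baseline
covers the full 590-word corpus split over T1/T2, later timepoints the
personal 300-item battery. Outcome records never carry the stimulation
condition; analyses join the allocation table explicitly.

Analyses: single-pass 2-SD RT trimming (iterated trimming would silently
change results); within-subject effect sizes with t-based 95% CIs and
Cohen's d = mean(change)/SD(change) (the standard paired-design convention;
the published table's d values are near but not exactly consistent with any
single convention, so second-decimal agreement is not claimed); paired t;
Wilcoxon signed-rank with exact enumeration for n ≤ 12 (average ranks,
zero differences dropped) and a tie-corrected normal approximation beyond;
a Type-III mixed repeated-measures ANOVA for one or two within factors and
one between factor built on orthonormal contrast scores per error stratum
(matching SPSS/`aov` on balanced designs exactly, and the group-stratified
terms on unbalanced designs; the three-level word-list factor reports a
Greenhouse–Geisser-corrected p alongside the uncorrected one — two-level
factors satisfy sphericity trivially); the Crawford single-case t for
comparison against control samples; subtype classification (impaired
pseudowords without semantic errors → phonological, with ≥ 2 semantic
errors → deep, regularity effect with regularization errors and relatively
spared pseudowords → surface, conflicts flagged ambiguous, threshold
configurable); and absolute-gain conversions (whole words = Σ gain% ×
n-items/100, rounded; ms per word = item-weighted mean RT change). No
multiple-testing correction is applied — planned contrasts are reported
uncorrected, and reports state so.

## Monte-Carlo calibration studies

The type-I-error study simulates cohorts with multiplier forced to 1
(and spillover off) and measures the rejection rate of the Block × group
interaction at α = 0.05; the directionality study uses a deliberately
strong multiplier (8) and asks only for the sign of the cohort-mean
anodal-minus-sham trained gain, since at the calibrated 2.6 pp effect the
sign is informative in only ~87% of 21-participant cohorts — a property of
the design's power, not of the implementation. Both studies run at the
aggregate fidelity with shared stimulus materials and fixed first-150/
first-90 list selection (customization does not affect either property),
keeping 1 000 + 200 cohorts tractable on one CPU.

## Numerical choices and degenerate inputs

Seeded `numpy` Generators everywhere; a single top-level seed fans out to
named per-stage streams so one stage's draw count cannot perturb another.
Frequency ties in core selection break alphabetically. Zero-variance change
vectors raise (Cohen's d undefined) rather than returning infinities; empty
RT lists trim to empty; singleton and zero-SD RT samples are retained
unchanged. Familiarity is clipped to [0, 1] after every update. TSV lexicon
parsing validates every row and reports the offending row number.

## Known limitations

The engine's trial-by-trial fidelity is too slow for thousand-cohort
studies (≈ 36 000 simulated trials per participant-block at full dose);
the aggregate fidelity is exact for familiarity but replaces the adaptive
challenge-length variation with its mean, so session-level logs exist only
at engine fidelity. The mixed ANOVA supports at most two within factors and
one between factor — exactly the published Therapy design — and the
multivariate omnibus analysis is intentionally out of scope. Reference
effect-size rows are printed values from the original trial report, used
for arithmetic cross-checks and conversions, not recomputed from patient
data (which are not public).
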