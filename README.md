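# lexitrain

Simulation and analysis toolkit for adaptive word-reading training in
**central alexia** — the acquired reading disorder that accompanies aphasia
after left-hemisphere stroke. The package re-creates, in software, the full
machinery of a crossover rehabilitation trial built around an iReadMore-style
exposure/challenge training app paired with anodal tDCS:

* a synthetic SUBTLEX-like **lexicon** (Zipfian per-million frequencies, 3–6
  letter words, graded 1–7 imageability, a high-frequency function-word
  stratum) plus Wuggy-style pseudowords with attested letter bigrams;
* **matched stimulus lists**: three 180-word lists matched triplet-wise on
  letter length, syllables, written frequency and imageability, a 50-word
  high-frequency core list, per-patient 150-word customization matched on
  baseline accuracy/RT, and 90 + 90 + 90 + 30-item testing subsets whose
  expected accuracy matches baseline (a regression-to-the-mean guard);
* the **adaptive training engine**: 10-trial passive exposure phases
  alternating with up-to-30-trial same/different challenge phases (+2 fast
  correct / +1 slow correct / −1 incorrect), three coupled difficulty
  parameters (word duration, criterion score, fast-RT boundary) that advance
  one increment per passed level and revert after three failed levels, and a
  per-word easy/medium/hard distractor staircase where distractors share the
  target's length and first letter and are tiered by positionally shared
  letters (think *hand* → *heap*, *hood*, *hard*);
* a **synthetic learner** whose per-word familiarity drives both the
  training task and oral reading outcomes, with saturating learning, an
  anodal-stimulation learning-rate multiplier whose effect generalizes to
  untrained words, test-retest practice effects and exponential forgetting;
* the **crossover trial**: Pocock–Simon minimization keeping the two
  stimulation-order groups balanced on baseline severity, counterbalanced
  list-role assignment, six assessment timepoints (T1–T6, 4-week spacing,
  3-month follow-up), two 35-hour training blocks with the anodal/sham
  condition crossed between groups;
* the **outcome statistics**: 1 / 0.5 / 0 reading scores with a 4-s timeout,
  single-pass 2-SD RT trimming, within-subject effect sizes
  (d = mean(change)/SD(change) with t-based 95% CI), paired *t*, exact
  Wilcoxon signed-rank (enumeration for n ≤ 12), a Type-III mixed
  repeated-measures ANOVA (two within factors × one between factor, unequal
  groups, Greenhouse–Geisser for 3-level factors), the Crawford single-case
  test, alexia subtype classification (phonological / deep / surface), and
  absolute-gain conversions (words regained, ms saved per word).

It is aimed at researchers designing or power-analysing item-based
rehabilitation trials, and at anyone who wants a reproducible, testable
reference implementation of this family of adaptive training procedures.

## Worked example

The whole pipeline — lexicon → matched lists → cohort → crossover simulation
→ analysis report — runs from one command:

```bash
cat > demo.json <<'EOF'
{"customize": "first", "fidelity": "aggregate"}
EOF
lexitrain run --config demo.json --seed 7 --out artifacts
cat artifacts/report.txt
```

which prints (abridged):

```
Primary outcome effect sizes
==============================
accuracy  trained_block1  T4-T3            9.89 (95% CI 5.82 to 13.97)  d=1.11
accuracy  untrained       T4-T3            2.35 (95% CI -0.37 to 5.08)  d=0.39
accuracy  trained_block2  T5-T4            8.94 (95% CI 4.90 to 12.99)  d=1.01
accuracy  trained_both    after-before     9.42 (95% CI 6.04 to 12.80)  d=1.27
rt        trained_both    after-before   -89.24 (95% CI -113.46 to -65.02)  d=-1.68
...
Therapy ANOVA
==============================
block:wordlist         F(2,38) = 9.94, p = 0.0003
block:group            F(1,19) = 0.78, p = 0.3874
...
Anodal-vs-sham facilitation (trained words): 1.80 pp (95% CI -2.64 to 6.24), d = 0.18
Absolute gain: 36 more words readable across 300 trained + 50 core items
```

Reading the output: the simulated 21-participant cohort improves ~9–10
percentage points on words trained in each block while untrained words move
only with the test-retest effect — the item-specific therapy signature that
shows up as the strongly significant Block × Word-list interaction. RTs
improve ~90 ms for trained words with no speed–accuracy trade-off. The
anodal-vs-sham contrast is the per-participant difference between
gains in the stimulated and unstimulated block; at the calibrated effect
size it is small and often non-significant in a single cohort, which is
exactly the power situation of a real 21-participant crossover. The
absolute-gain line converts percentage gains into whole words across the
300 trained + 50 core tested items.

Individual stages are also exposed (`lexitrain genlex`, `pseudowords`,
`build-lists`, `gencohort`, `simulate`, `analyze`, `report`), and everything
is importable as a library (`lexitrain.lexicon`, `.stimuli`, `.engine`,
`.learner`, `.trial`, `.outcomes`, `.reference`).

## Documentation

`docs/methods.md` describes the models, their assumptions, the calibration
of every default, and what the synthetic learner does and does not emulate.
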