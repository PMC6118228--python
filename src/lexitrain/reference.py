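"""Published reference data from the original iReadMore crossover RCT.

Ships the per-patient baseline characteristics of the 21 trial completers and
the reported unstandardized/standardized effect sizes for the primary word
reading outcomes, as printed in the trial report.  These serve three roles:
cohort summary statistics for calibrating the synthetic-learner severity
range, internal-consistency arithmetic (the combined-block and maintenance
effects are recoverable from the per-interval effects), and the real-world
absolute-gain conversions (words regained, milliseconds saved per word).
"""

from __future__ import annotations

import pandas as pd

from .outcomes import absolute_gains, absolute_rt_gain

__all__ = [
    "reference_cohort",
    "reference_effect_sizes",
    "CONTROL_WORD_READING",
    "CONTROL_PSEUDOWORD_READING",
    "N_CONTROLS",
    "combined_block_effects",
    "reference_absolute_gains",
]

# control normative data: (mean %, SD), n = 21 age/sex-matched controls
CONTROL_WORD_READING = (100.0, 1.0)
CONTROL_PSEUDOWORD_READING = (93.0, 11.0)
N_CONTROLS = 21

# Baseline characteristics of the 21 completers (tDCS crossover groups).
# Columns: group, sex, age (years), months post-stroke, lesion volume (cm^3),
# picture naming accuracy (%), word reading accuracy (%), pseudoword reading
# accuracy (%), alexia subtype (P phonological / D deep / S surface).
_COHORT_ROWS = [
    # id, group, sex, age, months, lesion, naming, word, pseudo, subtype
    ("P7", 1, "M", 67, 107, 12, 72, 12, 3, "D"),
    ("P18", 1, "M", 72, 101, 243, 9, 13, 0, "D"),
    ("P16", 1, "M", 60, 16, 103, 33, 28, 10, "D"),
    ("P2", 1, "M", 50, 82, 305, 53, 40, 0, "D"),
    ("P1", 1, "M", 44, 94, 241, 69, 58, 0, "D"),
    ("P8", 1, "F", 43, 55, 399, 81, 58, 20, "D"),
    ("P13", 1, "M", 56, 23, 45, 72, 80, 0, "P"),
    ("P5", 1, "F", 55, 75, 151, 93, 92, 30, "P"),
    ("P12", 1, "M", 54, 24, 149, 86, 92, 65, "P"),
    ("P10", 1, "M", 52, 12, 34, 88, 96, 75, "P"),
    ("P9", 2, "M", 61, 19, 196, 40, 3, 0, "D"),
    ("P15", 2, "M", 73, 158, 205, 71, 20, 0, "D"),
    ("P17", 2, "F", 50, 72, 141, 28, 36, 5, "P"),
    ("P14", 2, "M", 54, 39, 190, 14, 47, 3, "P"),
    ("P19", 2, "F", 58, 41, 298, 81, 59, 0, "P"),
    ("P4", 2, "F", 56, 93, 150, 5, 64, 75, "S"),
    ("P3", 2, "M", 52, 66, 123, 66, 71, 0, "P"),
    ("P20", 2, "M", 42, 13, 44, 72, 75, 28, "P"),
    ("P21", 2, "F", 26, 81, 162, 79, 76, 0, "D"),
    ("P6", 2, "F", 33, 59, 181, 95, 90, 3, "P"),
    ("P11", 2, "F", 50, 14, 59, 83, 91, 25, "P"),
]


def reference_cohort() -> pd.DataFrame:
    """The 21-patient baseline characteristics table."""
    return pd.DataFrame(
        _COHORT_ROWS,
        columns=[
            "id",
            "group",
            "sex",
            "age_years",
            "months_post_stroke",
            "lesion_cm3",
            "naming_pct",
            "word_reading_pct",
            "pseudoword_pct",
            "alexia_subtype",
        ],
    )


# Reported effect sizes for the primary outcomes: mean change with 95% CI and
# Cohen's d, per measure and time interval.  Accuracy in percentage points,
# reaction time in ms (negative = faster).
_EFFECT_ROWS = [
    # measure, wordlist, interval, mean, ci_low, ci_high, d
    ("accuracy", "trained_block1", "T4-T3", 9.2, 6.2, 12.3, 1.29),
    ("accuracy", "untrained", "T4-T3", 0.7, -1.3, 2.7, 0.16),
    ("accuracy", "trained_block2", "T5-T4", 8.1, 5.3, 10.9, 1.25),
    ("accuracy", "untrained", "T5-T4", 1.3, -0.6, 3.1, 0.29),
    ("accuracy", "trained_both", "after-before", 8.7, 6.0, 11.4, 1.38),
    ("rt", "trained_block1", "T4-T3", -128.0, -202.0, -53.0, 0.75),
    ("rt", "untrained", "T4-T3", -92.0, -228.0, 44.0, 0.30),
    ("rt", "trained_block2", "T5-T4", -73.0, -142.0, -4.0, 0.47),
    ("rt", "untrained", "T5-T4", -4.0, -125.0, 117.0, 0.01),
    ("rt", "trained_both", "after-before", -100.0, -145.0, -56.0, 0.98),
    ("accuracy", "core", "T4-T3", 5.7, 1.5, 9.9, 0.58),
    ("accuracy", "core", "T5-T4", 0.3, -2.4, 3.0, 0.04),
    ("accuracy", "core", "T5-T3", 6.0, 2.7, 9.2, 0.78),
    ("rt", "core", "T4-T3", -66.0, -245.0, 113.0, 0.17),
    ("rt", "core", "T5-T4", -144.0, -281.0, -6.0, 0.47),
    ("rt", "core", "T5-T3", -210.0, -304.0, -116.0, 1.00),
]


def reference_effect_sizes() -> pd.DataFrame:
    """Reported primary-outcome effect sizes of the original trial."""
    return pd.DataFrame(
        _EFFECT_ROWS,
        columns=["measure", "wordlist", "interval", "mean", "ci_low", "ci_high", "d"],
    )


def combined_block_effects() -> dict[str, float]:
    """Internal-consistency arithmetic on the reported effects.

    The combined-blocks trained effect is the mean of the two per-block
    effects (equal weights: each block trains a fresh 150-word list), and the
    core-word T5-T3 change is the sum of the two consecutive interval
    changes.  Recomputing them checks the printed table's additivity.
    """
    eff = reference_effect_sizes().set_index(["measure", "wordlist", "interval"])

    def m(measure, wl, interval):
        return float(eff.loc[(measure, wl, interval), "mean"])

    return {
        "combined_trained_accuracy_gain_pct": (
            m("accuracy", "trained_block1", "T4-T3") + m("accuracy", "trained_block2", "T5-T4")
        )
        / 2.0,
        "combined_trained_rt_change_ms": (
            m("rt", "trained_block1", "T4-T3") + m("rt", "trained_block2", "T5-T4")
        )
        / 2.0,
        "core_accuracy_change_t5_t3_pct": (
            m("accuracy", "core", "T4-T3") + m("accuracy", "core", "T5-T4")
        ),
        "core_rt_change_t5_t3_ms": (m("rt", "core", "T4-T3") + m("rt", "core", "T5-T4")),
    }


def reference_absolute_gains() -> dict[str, float]:
    """Real-world conversions: whole words regained across the 300 tested
    trained words plus 50 core words, and ms saved per trained word, with
    ranges from the reported 95% CIs."""
    eff = reference_effect_sizes().set_index(["measure", "wordlist", "interval"])
    acc = eff.loc[("accuracy", "trained_both", "after-before")]
    core_acc = eff.loc[("accuracy", "core", "T5-T3")]
    rt = eff.loc[("rt", "trained_both", "after-before")]
    core_rt = eff.loc[("rt", "core", "T5-T3")]
    n_trained, n_core = 300, 50
    return {
        "words_gained": absolute_gains(acc["mean"], n_trained, core_acc["mean"], n_core),
        "words_gained_low": absolute_gains(acc["ci_low"], n_trained, core_acc["ci_low"], n_core),
        "words_gained_high": absolute_gains(acc["ci_high"], n_trained, core_acc["ci_high"], n_core),
        "ms_faster_per_word": -absolute_rt_gain(rt["mean"], n_trained, core_rt["mean"], n_core),
        "ms_faster_per_word_low": -absolute_rt_gain(
            rt["ci_high"], n_trained, core_rt["ci_high"], n_core
        ),
        "ms_faster_per_word_high": -absolute_rt_gain(
            rt["ci_low"], n_trained, core_rt["ci_low"], n_core
        ),
    }
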