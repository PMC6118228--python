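"""Assessment scoring and trial statistics.

Implements the analysis toolkit for the word-reading outcome measures:
1 / 0.5 / 0 trial scoring with a 4-s timeout, single-pass 2-SD reaction-time
trimming, within-subject effect sizes (mean change with t-based 95% CI and
Cohen's d = mean(change)/SD(change)), paired t and exact Wilcoxon signed-rank
tests, a Type-III mixed repeated-measures ANOVA (two within-subject factors,
one between-subject factor, unequal group sizes allowed), the Crawford
single-case comparison against a control sample, alexia subtype
classification, absolute-gain conversions, and the imageability
percentile-split analysis.

No multiple-testing correction is applied anywhere: the planned contrasts are
reported uncorrected, and reports state this.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrialRecord",
    "ReadingTestResult",
    "EffectSize",
    "AnovaResult",
    "AlexiaProfile",
    "score_word_reading_test",
    "trim_reaction_times",
    "effect_size",
    "paired_t",
    "wilcoxon_signed_rank",
    "mixed_anova",
    "singlims",
    "classify_alexia",
    "absolute_gains",
    "absolute_rt_gain",
    "imageability_split",
]

TIMEOUT_MS = 4000.0

RESPONSE_CATEGORIES = ("correct", "self_correction", "incorrect")


@dataclass(frozen=True)
class TrialRecord:
    """One raw oral-reading trial as recorded by the experimenter."""

    item: str
    response: str  # correct | self_correction | incorrect
    rt_ms: float | None = None
    voicekey_failed: bool = False


@dataclass
class ReadingTestResult:
    """Scored assessment for one participant at one timepoint."""

    items: list[str]
    scores: np.ndarray  # values in {0, 0.5, 1}
    rts: np.ndarray  # NaN where excluded
    flags: list[str]  # kept | incorrect | self_corrected | voicekey_fail | outlier_2sd | timeout

    @property
    def accuracy_pct(self) -> float:
        return float(100.0 * np.mean(self.scores))

    @property
    def mean_rt_ms(self) -> float:
        kept = self.rts[~np.isnan(self.rts)]
        return float(kept.mean()) if kept.size else float("nan")


@dataclass(frozen=True)
class EffectSize:
    """Within-subject change: mean, t-based 95% CI and Cohen's d."""

    mean_change: float
    ci_low: float
    ci_high: float
    cohens_d: float
    n: int


@dataclass
class AnovaResult:
    """F tests per effect of the mixed design."""

    table: pd.DataFrame  # index: effect; columns: F, df_num, df_den, p, (p_gg, eps where applicable)

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


@dataclass(frozen=True)
class AlexiaProfile:
    pseudoword_impaired: bool
    semantic_errors: bool
    regularity_effect: bool
    imageability_effect: bool
    subtype: str  # phonological | deep | surface
    ambiguous: bool = False


# ---------------------------------------------------------------------------
# scoring and trimming


def score_word_reading_test(records: list[TrialRecord]) -> ReadingTestResult:
    """Score raw trials 1 / 0.5 / 0 and trim reaction times.

    RTs are retained only for clean correct trials (no self-correction, no
    voice-key failure, onset within the 4-s window); retained RTs further than
    2 SD from their mean are flagged as outliers and excluded (single pass).
    """
    items, scores, rts, flags = [], [], [], []
    for rec in records:
        if rec.response not in RESPONSE_CATEGORIES:
            raise ValueError(f"unknown response category {rec.response!r} for item {rec.item!r}")
        items.append(rec.item)
        if rec.response == "incorrect":
            scores.append(0.0), rts.append(np.nan), flags.append("incorrect")
        elif rec.response == "self_correction":
            scores.append(0.5), rts.append(np.nan), flags.append("self_corrected")
        elif rec.rt_ms is not None and rec.rt_ms > TIMEOUT_MS:
            scores.append(0.0), rts.append(np.nan), flags.append("timeout")
        elif rec.voicekey_failed or rec.rt_ms is None:
            scores.append(1.0), rts.append(np.nan), flags.append("voicekey_fail")
        else:
            scores.append(1.0), rts.append(float(rec.rt_ms)), flags.append("kept")

    rts_arr = np.array(rts, float)
    kept_mask = np.array([f == "kept" for f in flags])
    kept_rts = rts_arr[kept_mask]
    retained = trim_reaction_times(list(kept_rts))
    retained_set = _multiset(retained)
    for i in np.flatnonzero(kept_mask):
        v = rts_arr[i]
        if retained_set.get(v, 0) > 0:
            retained_set[v] -= 1
        else:
            flags[i] = "outlier_2sd"
            rts_arr[i] = np.nan
    return ReadingTestResult(items=items, scores=np.array(scores), rts=rts_arr, flags=flags)


def _multiset(values):
    out: dict[float, int] = {}
    for v in values:
        out[v] = out.get(v, 0) + 1
    return out


def trim_reaction_times(rts: list[float]) -> list[float]:
    """Single-pass 2-SD trim: drop values with |x - mean| > 2 * sample SD,
    with mean and SD computed once on the input.  A singleton or zero-variance
    input is returned unchanged."""
    if len(rts) == 0:
        return []
    arr = np.asarray(rts, float)
    if arr.size == 1:
        return list(arr)
    mu = arr.mean()
    sd = arr.std(ddof=1)
    if sd == 0:
        return list(arr)
    keep = np.abs(arr - mu) <= 2.0 * sd
    return list(arr[keep])


# ---------------------------------------------------------------------------
# effect sizes and simple tests


def effect_size(changes, conf: float = 0.95) -> EffectSize:
    """Mean within-subject change with t-based CI and d = mean / SD."""
    arr = np.asarray(changes, float)
    n = arr.size
    if n < 2:
        raise ValueError("need at least 2 change scores")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("SD of changes is zero; Cohen's d undefined")
    mean = arr.mean()
    tcrit = stats.t.ppf(0.5 + conf / 2.0, n - 1)
    half = tcrit * sd / np.sqrt(n)
    return EffectSize(
        mean_change=float(mean),
        ci_low=float(mean - half),
        ci_high=float(mean + half),
        cohens_d=float(mean / sd),
        n=int(n),
    )


def paired_t(x, y) -> tuple[float, int, float]:
    """Two-tailed paired t-test on differences x - y; returns (t, df, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if d.std(ddof=1) == 0:
        raise ValueError("differences have zero variance")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def _signed_rank_stats(d: np.ndarray) -> tuple[np.ndarray, float]:
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    return ranks, w_plus


def wilcoxon_signed_rank(x, y, exact_max_n: int = 12) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples; returns (T, p two-sided).

    Zero differences are dropped.  For n <= ``exact_max_n`` the p-value is
    exact, from enumeration of all 2**n sign patterns (average ranks, so ties
    in |d| are handled); larger samples use the normal approximation with tie
    correction and continuity correction.  T is the smaller of the two
    signed-rank sums, the convention of printed tables.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    ranks, w_plus = _signed_rank_stats(d)
    total = ranks.sum()
    T = min(w_plus, total - w_plus)
    if n <= exact_max_n:
        count_le = 0
        count_ge = 0
        for signs in itertools.product((0, 1), repeat=n):
            w = sum(r for s, r in zip(signs, ranks) if s)
            count_le += w <= w_plus
            count_ge += w >= w_plus
        m = 2**n
        p = min(1.0, 2.0 * min(count_le / m, count_ge / m))
    else:
        mean = total / 2.0
        # variance with tie correction on average ranks
        var = float(np.sum(ranks**2)) / 4.0
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return float(T), float(p)


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (Helmert, normalized)."""
    c = np.zeros((k - 1, k))
    for i in range(1, k):
        c[i - 1, :i] = 1.0
        c[i - 1, i] = -i
        c[i - 1] /= np.linalg.norm(c[i - 1])
    return c


def _contrast_f(Z: np.ndarray, groups: np.ndarray) -> tuple[float, float, int, int, float, float, np.ndarray]:
    """Type-III F tests for one within-subject effect.

    ``Z``: subjects x q matrix of orthonormal contrast scores; ``groups``:
    integer group label per subject.  Returns (F_effect, F_interaction,
    df_num, df_den, SS pieces ...) plus the pooled within-group covariance of
    Z (for the sphericity estimate).
    """
    labels = np.unique(groups)
    a = labels.size
    N, q = Z.shape
    group_means = np.stack([Z[groups == g].mean(axis=0) for g in labels])
    ns = np.array([(groups == g).sum() for g in labels], float)
    # Type III: unweighted grand mean of group means
    grand = group_means.mean(axis=0)
    inv_n = float((1.0 / ns).sum())
    # Type-III SS of the grand (unweighted) mean: grand_j^2 / (inv_n / a^2) per contrast
    ss_effect = float((grand**2).sum() / (inv_n / a**2))
    # interaction SS: between-group variation of contrast means (Type III)
    resid_between = group_means - grand
    # weighted by group sizes under the cell-means model:
    # SS_int = sum_j sum_g n_g * (m_gj - hat)^2 with hat the weighted projection;
    # for a = 2 this reduces to (m1 - m2)^2 / (1/n1 + 1/n2) per contrast.
    if a == 2:
        diff = group_means[0] - group_means[1]
        ss_inter = float((diff**2).sum() / (1.0 / ns[0] + 1.0 / ns[1]))
    else:
        centered = group_means - (ns[:, None] * group_means).sum(axis=0) / ns.sum()
        ss_inter = float((ns[:, None] * centered**2).sum())
    resid = Z - group_means[np.searchsorted(labels, groups)]
    ss_err = float((resid**2).sum())
    df_num = q
    df_den = q * (N - a)
    S = resid.T @ resid / (N - a)
    return ss_effect, ss_inter, df_num, df_den, ss_err, a, S


def _gg_epsilon(S: np.ndarray) -> float:
    q = S.shape[0]
    if q == 1:
        return 1.0
    return float(np.trace(S) ** 2 / (q * np.trace(S @ S)))


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: list[str],
    between: str,
) -> AnovaResult:
    """Mixed-design repeated-measures ANOVA via sums-of-squares decomposition.

    Supports one or two within-subject factors crossed with one
    between-subject factor; groups may be unequal.  Each within effect is
    tested against its own subject-by-effect error stratum (Type III, the
    convention of standard statistical packages); three-or-more-level within
    effects additionally report a Greenhouse-Geisser corrected p.  Missing
    within-subject cells raise an error listing them.
    """
    if not 1 <= len(within) <= 2:
        raise ValueError("mixed_anova supports one or two within factors")
    cols = [subject, between, *within, dv]
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ValueError(f"missing columns: {missing_cols}")
    wide = data.pivot_table(index=[subject, between], columns=within, values=dv, aggfunc="mean")
    if wide.isna().any().any():
        bad = [
            (idx, col)
            for idx, row in wide.iterrows()
            for col, v in row.items()
            if pd.isna(v)
        ]
        raise ValueError(f"missing within-subject cells: {bad[:10]}")
    subjects = wide.index.get_level_values(0)
    group_codes, _ = pd.factorize(wide.index.get_level_values(1))
    Y = wide.to_numpy()
    if len(within) == 1:
        level_counts = [wide.columns.size]
    else:
        level_counts = [wide.columns.levels[0].size, wide.columns.levels[1].size]
        # pivot_table sorts columns lexicographically: reshape is consistent
    N = Y.shape[0]
    a = np.unique(group_codes).size

    rows = {}

    # between-subjects effect: one-way ANOVA on subject means
    subj_means = Y.mean(axis=1)
    labels = np.unique(group_codes)
    ns = np.array([(group_codes == g).sum() for g in labels], float)
    gm = np.array([subj_means[group_codes == g].mean() for g in labels])
    grand_w = (ns * gm).sum() / ns.sum()
    ss_g = float((ns * (gm - grand_w) ** 2).sum()) * np.prod(level_counts)
    ss_sw = float(
        sum(((subj_means[group_codes == g] - gm[i]) ** 2).sum() for i, g in enumerate(labels))
    ) * np.prod(level_counts)
    df_g, df_sw = a - 1, N - a
    F_g = (ss_g / df_g) / (ss_sw / df_sw)
    rows[between] = dict(F=F_g, df_num=df_g, df_den=df_sw, p=float(stats.f.sf(F_g, df_g, df_sw)))

    # within effects and their group interactions
    if len(within) == 1:
        b = level_counts[0]
        effect_defs = {within[0]: _orthonormal_contrasts(b)}
    else:
        b, c = level_counts
        Cb = _orthonormal_contrasts(b)
        Cc = _orthonormal_contrasts(c)
        Ib = np.full((1, b), 1.0 / np.sqrt(b))
        Ic = np.full((1, c), 1.0 / np.sqrt(c))
        effect_defs = {
            within[0]: np.kron(Cb, Ic),
            within[1]: np.kron(Ib, Cc),
            f"{within[0]}:{within[1]}": np.kron(Cb, Cc),
        }

    for name, C in effect_defs.items():
        Z = Y @ C.T
        ss_eff, ss_int, df_num, df_den, ss_err, _, S = _contrast_f(Z, group_codes)
        ms_err = ss_err / df_den
        F_eff = (ss_eff / df_num) / ms_err
        F_int = (ss_int / df_num) / ms_err
        entry = dict(F=F_eff, df_num=df_num, df_den=df_den, p=float(stats.f.sf(F_eff, df_num, df_den)))
        inter = dict(F=F_int, df_num=df_num, df_den=df_den, p=float(stats.f.sf(F_int, df_num, df_den)))
        if df_num > 1:
            eps = _gg_epsilon(S)
            entry["eps_gg"] = eps
            entry["p_gg"] = float(stats.f.sf(F_eff, df_num * eps, df_den * eps))
            inter["eps_gg"] = eps
            inter["p_gg"] = float(stats.f.sf(F_int, df_num * eps, df_den * eps))
        rows[name] = entry
        rows[f"{name}:{between}"] = inter

    table = pd.DataFrame(rows).T
    table.index.name = "effect"
    return AnovaResult(table=table)


# ---------------------------------------------------------------------------
# single-case statistics and classification


def singlims(x: float, control_mean: float, control_sd: float, n_controls: int) -> tuple[float, int, float]:
    """Crawford's modified t comparing a single case to a control sample.

    t = (x - mean) / (sd * sqrt((n + 1) / n)) on n - 1 df; returns the
    one-tailed p for the observed direction.
    """
    if n_controls < 2:
        raise ValueError("need at least 2 controls")
    if control_sd <= 0:
        raise ValueError("control SD must be positive")
    t = (x - control_mean) / (control_sd * np.sqrt((n_controls + 1) / n_controls))
    df = n_controls - 1
    p = float(stats.t.sf(abs(t), df)) if t != 0 else 0.5
    return float(t), int(df), p


def classify_alexia(
    pseudoword_accuracy: float,
    control_mean: float,
    control_sd: float,
    n_controls: int,
    n_semantic_errors: int,
    regularity_p: float,
    n_regularization_errors: int = 0,
    imageability_p: float = 1.0,
    alpha: float = 0.05,
    semantic_error_threshold: int = 2,
) -> AlexiaProfile:
    """Classify the alexia subtype from the baseline reading profile.

    Rules: impaired pseudoword reading (Crawford test one-tailed p < alpha
    below controls) without semantic errors -> phonological; with semantic
    errors (count >= threshold) -> deep; a significant regularity effect with
    regularization errors and relatively spared pseudowords -> surface.
    Conflicting evidence never fails silently: the profile carries an
    ``ambiguous`` flag.
    """
    t, _, p = singlims(pseudoword_accuracy, control_mean, control_sd, n_controls)
    pseudo_impaired = (t < 0) and (p < alpha)
    semantic = n_semantic_errors >= semantic_error_threshold
    reg_effect = regularity_p < alpha
    imag_effect = imageability_p < alpha
    surface_evidence = reg_effect and n_regularization_errors > 0 and not pseudo_impaired

    if surface_evidence:
        subtype, ambiguous = "surface", semantic
    elif pseudo_impaired and semantic:
        subtype, ambiguous = "deep", False
    elif pseudo_impaired:
        subtype, ambiguous = "phonological", False
    else:
        # no pseudoword impairment and no surface profile: closest fit is
        # phonological (mildest central subtype) but flagged ambiguous
        subtype, ambiguous = "phonological", True
    return AlexiaProfile(
        pseudoword_impaired=pseudo_impaired,
        semantic_errors=semantic,
        regularity_effect=reg_effect,
        imageability_effect=imag_effect,
        subtype=subtype,
        ambiguous=ambiguous,
    )


# ---------------------------------------------------------------------------
# absolute-gain conversions and imageability split


def absolute_gains(
    trained_gain_pct: float, n_trained: int, core_gain_pct: float, n_core: int
) -> int:
    """Convert percentage accuracy gains into a whole-word count:
    round(trained% * n_trained / 100 + core% * n_core / 100)."""
    if n_trained <= 0 or n_core < 0:
        raise ValueError("word counts must be positive")
    return int(round(trained_gain_pct * n_trained / 100.0 + core_gain_pct * n_core / 100.0))


def absolute_rt_gain(
    trained_rt_ms: float, n_trained: int, core_rt_ms: float, n_core: int
) -> int:
    """Word-count-weighted mean RT change per trained word, rounded to ms."""
    if n_trained <= 0 or n_core < 0:
        raise ValueError("word counts must be positive")
    return int(round((trained_rt_ms * n_trained + core_rt_ms * n_core) / (n_trained + n_core)))


def imageability_split(
    imageability: dict[str, float],
    changes: pd.DataFrame,
    percentile: float = 40.0,
) -> dict:
    """Split items at the given imageability percentile and compare per-
    stratum mean changes with a paired t-test across participants.

    ``changes``: participants x items change scores.  Items at or below the
    percentile rank are "low" imageability, the rest "high".
    """
    items = list(changes.columns)
    missing = [i for i in items if i not in imageability]
    if missing:
        raise ValueError(f"imageability missing for items: {missing[:5]}")
    vals = np.array([imageability[i] for i in items])
    order = np.argsort(vals, kind="stable")
    n_low = int(np.floor(percentile / 100.0 * len(items)))
    low_items = [items[i] for i in order[:n_low]]
    high_items = [items[i] for i in order[n_low:]]
    if not low_items or not high_items:
        raise ValueError("imageability split produced an empty stratum")
    low = changes[low_items].mean(axis=1)
    high = changes[high_items].mean(axis=1)
    diff = high - low
    if diff.std(ddof=1) == 0:
        t, df, p = 0.0, len(diff) - 1, 1.0
    else:
        t, df, p = paired_t(high.to_numpy(), low.to_numpy())
    return {
        "low_items": low_items,
        "high_items": high_items,
        "low_mean_change": float(low.mean()),
        "high_mean_change": float(high.mean()),
        "t": float(t),
        "df": int(df),
        "p": float(p),
    }
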