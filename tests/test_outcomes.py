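"""Scoring, trimming, effect sizes, exact tests, mixed ANOVA, single-case
statistics, classification, and the absolute-gain conversions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lexitrain.outcomes as out


class TestScoring:
    def test_response_categories_map_to_scores(self):
        res = out.score_word_reading_test([
            out.TrialRecord("a", "correct", 900.0),
            out.TrialRecord("b", "self_correction", 1500.0),
            out.TrialRecord("c", "incorrect", None),
        ])
        assert list(res.scores) == [1.0, 0.5, 0.0]
        assert res.flags == ["kept", "self_corrected", "incorrect"]
        assert np.isnan(res.rts[1]) and np.isnan(res.rts[2])

    def test_correct_just_inside_timeout_kept(self):
        res = out.score_word_reading_test([out.TrialRecord("a", "correct", 3990.0)])
        assert res.scores[0] == 1.0 and res.rts[0] == 3990.0

    def test_timeout_scores_zero(self):
        res = out.score_word_reading_test([out.TrialRecord("a", "correct", 4200.0)])
        assert res.scores[0] == 0.0 and res.flags[0] == "timeout"

    def test_voicekey_failure_keeps_score_drops_rt(self):
        res = out.score_word_reading_test([out.TrialRecord("a", "correct", 900.0, voicekey_failed=True)])
        assert res.scores[0] == 1.0 and np.isnan(res.rts[0]) and res.flags[0] == "voicekey_fail"

    def test_unknown_category_is_an_error(self):
        with pytest.raises(ValueError, match="category"):
            out.score_word_reading_test([out.TrialRecord("a", "dunno", 1.0)])

    def test_outlier_rts_flagged_and_accuracy_bookkeeping(self):
        recs = [out.TrialRecord(f"w{i}", "correct", rt) for i, rt in
                enumerate([500, 510, 490, 505, 495, 3900])]
        res = out.score_word_reading_test(recs)
        assert res.flags[5] == "outlier_2sd"
        assert np.isnan(res.rts[5])
        assert res.accuracy_pct == pytest.approx(100.0)
        assert res.accuracy_pct == pytest.approx(100 * res.scores.sum() / len(res.scores))


class TestTrimming:
    def test_worked_example(self):
        kept = out.trim_reaction_times([500, 510, 490, 505, 495, 5000])
        assert kept == [500, 510, 490, 505, 495]

    def test_all_equal_values_kept(self):
        assert out.trim_reaction_times([700.0] * 5) == [700.0] * 5

    def test_singleton_and_empty(self):
        assert out.trim_reaction_times([812.0]) == [812.0]
        assert out.trim_reaction_times([]) == []

    def test_every_retained_value_within_pretrim_band(self):
        rng = np.random.default_rng(0)
        x = list(rng.lognormal(6.8, 0.5, 200))
        mu, sd = np.mean(x), np.std(x, ddof=1)
        for v in out.trim_reaction_times(x):
            assert mu - 2 * sd <= v <= mu + 2 * sd


class TestEffectSize:
    def test_closed_form_example(self):
        es = out.effect_size([1, 2, 3])
        assert es.mean_change == pytest.approx(2.0)
        assert es.cohens_d == pytest.approx(2.0)
        assert es.ci_low == pytest.approx(-0.4841, abs=1e-3)
        assert es.ci_high == pytest.approx(4.4841, abs=1e-3)

    def test_sign_flip_symmetry(self):
        a = out.effect_size([1.0, 2.5, 4.0, 2.0])
        b = out.effect_size([-1.0, -2.5, -4.0, -2.0])
        assert b.mean_change == -a.mean_change
        assert b.ci_low == pytest.approx(-a.ci_high)
        assert b.cohens_d == pytest.approx(-a.cohens_d)

    def test_zero_sd_is_an_error(self):
        with pytest.raises(ValueError):
            out.effect_size([5, 5, 5])

    def test_too_few_observations_is_an_error(self):
        with pytest.raises(ValueError):
            out.effect_size([1.0])


class TestPairedT:
    def test_hand_computed_example(self):
        t, df, p = out.paired_t([1, 2, 3, 4], [2, 3, 5, 5])
        assert t == pytest.approx(-5.0)
        assert df == 3
        assert p == pytest.approx(2 * stats.t.sf(5.0, 3))

    def test_zero_variance_differences_error(self):
        with pytest.raises(ValueError):
            out.paired_t([1, 2, 3], [2, 3, 4])

    def test_agrees_with_sign_symmetry(self):
        x = np.array([3.1, 2.2, 5.0, 4.4, 1.0, 2.8])
        y = np.array([2.0, 2.9, 4.1, 4.9, 0.2, 2.1])
        t1, _, p1 = out.paired_t(x, y)
        t2, _, p2 = out.paired_t(y, x)
        assert t2 == pytest.approx(-t1) and p2 == pytest.approx(p1)


def brute_force_wilcoxon_p(d):
    """Independent enumeration oracle over all sign patterns."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product((0, 1), repeat=len(d)):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.array(ws)
    m = len(ws)
    return min(1.0, 2 * min((ws <= w_obs).sum() / m, (ws >= w_obs).sum() / m))


class TestWilcoxon:
    @pytest.mark.parametrize("n,seed", [(5, 0), (6, 1), (7, 2), (8, 3), (9, 4), (10, 5)])
    def test_exact_p_matches_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.3, 1.0, n)
        y = rng.normal(0.0, 1.0, n)
        _, p = out.wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(brute_force_wilcoxon_p(x - y))

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0.5, 1.0, 11)
        y = rng.normal(0.0, 1.0, 11)
        T, p = out.wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x, y, mode="exact")
        assert T == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
        _, p1 = out.wilcoxon_signed_rank(x, y)
        _, p2 = out.wilcoxon_signed_rank(y, x)
        assert p1 == pytest.approx(p2)

    def test_identical_samples_error(self):
        with pytest.raises(ValueError):
            out.wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])

    def test_large_sample_normal_approximation_reasonable(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.4, 1.0, 40)
        y = rng.normal(0.0, 1.0, 40)
        _, p = out.wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x, y, correction=True, mode="approx")
        assert p == pytest.approx(ref.pvalue, rel=0.05)


# balanced toy design; F values frozen from an independent R `aov` fit with
# Error(subject/(block*wordlist)) strata
R_ORACLE_BALANCED = {
    "group": (1.202, 1, 4, 0.334),
    "block": (1.162, 1, 4, 0.342),
    "block:group": (0.001, 1, 4, 0.977),
    "wordlist": (1.638, 1, 4, 0.270),
    "wordlist:group": (1.830, 1, 4, 0.248),
    "block:wordlist": (0.210, 1, 4, 0.670),
    "block:wordlist:group": (0.494, 1, 4, 0.521),
}


def balanced_toy():
    rng = np.random.default_rng(42)
    rows = []
    for si in range(6):
        g = 1 if si < 3 else 2
        for b in (1, 2):
            for l in ("x", "y"):
                rows.append((f"s{si}", g, b, l, int(rng.integers(0, 20))))
    return pd.DataFrame(rows, columns=["subject", "group", "block", "wordlist", "y"])


class TestMixedAnova:
    def test_balanced_toy_matches_independent_oracle(self):
        res = out.mixed_anova(balanced_toy(), dv="y", subject="subject",
                              within=["block", "wordlist"], between="group")
        for effect, (F, dfn, dfd, p) in R_ORACLE_BALANCED.items():
            row = res.table.loc[effect]
            assert row["F"] == pytest.approx(F, abs=2e-3), effect
            assert (row["df_num"], row["df_den"]) == (dfn, dfd)
            assert row["p"] == pytest.approx(p, abs=2e-3)

    def test_balanced_toy_matches_hand_computed_sums_of_squares(self):
        """Textbook split-plot decomposition computed directly from cell
        means, independent of the implementation's contrast route."""
        df = balanced_toy()
        res = out.mixed_anova(df, dv="y", subject="subject",
                              within=["block", "wordlist"], between="group")
        Y = df.pivot_table(index="subject", columns=["block", "wordlist"], values="y").to_numpy()
        groups = np.array([1, 1, 1, 2, 2, 2])
        n, bc = Y.shape
        # Block effect: per-subject block means
        bmeans = Y.reshape(n, 2, 2).mean(axis=2)
        grand = bmeans.mean()
        ss_block = 2 * n * ((bmeans.mean(axis=0) - grand) ** 2).sum() * 1.0
        # interaction error: subject x block within groups
        cell = np.stack([bmeans[groups == g].mean(axis=0) for g in (1, 2)])
        ss_bg = 2 * 3 * ((cell - cell.mean(axis=1, keepdims=True)
                          - cell.mean(axis=0, keepdims=True) + cell.mean()) ** 2).sum()
        resid = bmeans - cell[groups - 1] - bmeans.mean(axis=1, keepdims=True)[..., :1] * 0
        subj_mean = bmeans.mean(axis=1, keepdims=True)
        group_mean = np.stack([bmeans[groups == g].mean() for g in (1, 2)])[groups - 1][:, None]
        dev = bmeans - subj_mean - cell[groups - 1] + group_mean
        ss_err = 2 * (dev ** 2).sum()
        F_block = (ss_block / 1) / (ss_err / 4)
        F_bg = (ss_bg / 1) / (ss_err / 4)
        assert res.table.loc["block", "F"] == pytest.approx(F_block, rel=1e-10)
        assert res.table.loc["block:group", "F"] == pytest.approx(F_bg, rel=1e-10)

    def test_grand_mean_shift_leaves_f_unchanged(self):
        df = balanced_toy()
        res1 = out.mixed_anova(df, dv="y", subject="subject",
                               within=["block", "wordlist"], between="group")
        df2 = df.assign(y=df.y + 1000)
        res2 = out.mixed_anova(df2, dv="y", subject="subject",
                               within=["block", "wordlist"], between="group")
        for effect in res1.table.index:
            assert res1.table.loc[effect, "F"] == pytest.approx(res2.table.loc[effect, "F"])

    def test_unequal_groups_match_r_for_group_stratified_effects(self):
        """With unequal group sizes the group-interaction terms and the
        between-group test agree with R's aov (frozen oracle values)."""
        rng = np.random.default_rng(7)
        rows = []
        for si in range(7):
            g = 1 if si < 3 else 2
            for b in (1, 2):
                for l in ("x", "y", "z"):
                    rows.append((f"s{si}", g, b, l, int(rng.integers(0, 30))))
        df = pd.DataFrame(rows, columns=["subject", "group", "block", "wordlist", "y"])
        res = out.mixed_anova(df, dv="y", subject="subject",
                              within=["block", "wordlist"], between="group")
        for effect, F in (("group", 0.014), ("block:group", 0.346),
                          ("wordlist:group", 1.706), ("block:wordlist:group", 5.755)):
            assert res.table.loc[effect, "F"] == pytest.approx(F, abs=2e-3), effect
        # the 3-level factor carries a Greenhouse-Geisser correction
        assert 0 < res.table.loc["wordlist", "eps_gg"] <= 1.0
        assert res.table.loc["wordlist", "p_gg"] >= res.table.loc["wordlist", "p"]

    def test_missing_cells_are_reported(self):
        df = balanced_toy().iloc[:-1]
        with pytest.raises(ValueError, match="missing within-subject cells"):
            out.mixed_anova(df, dv="y", subject="subject",
                            within=["block", "wordlist"], between="group")

    def test_single_within_factor_design(self):
        df = balanced_toy().query("wordlist == 'x'")
        res = out.mixed_anova(df, dv="y", subject="subject", within=["block"], between="group")
        assert {"group", "block", "block:group"} <= set(res.table.index)


class TestSinglims:
    def test_case_at_control_mean(self):
        t, df, p = out.singlims(93.0, 93.0, 11.0, 21)
        assert t == 0.0 and df == 20 and p == 0.5

    def test_reference_control_comparison(self):
        t, df, p = out.singlims(50.0, 93.0, 11.0, 21)
        assert t == pytest.approx(-3.8192, abs=1e-3)
        assert df == 20
        assert p < 0.001

    def test_t_magnitude_decreasing_in_control_sd(self):
        ts = [abs(out.singlims(50.0, 93.0, sd, 21)[0]) for sd in (5.0, 11.0, 20.0)]
        assert ts[0] > ts[1] > ts[2]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            out.singlims(50.0, 93.0, 0.0, 21)
        with pytest.raises(ValueError):
            out.singlims(50.0, 93.0, 11.0, 1)


class TestClassification:
    CONTROLS = dict(control_mean=93.0, control_sd=11.0, n_controls=21)

    def test_impaired_pseudowords_without_semantic_errors_is_phonological(self):
        prof = out.classify_alexia(20.0, **self.CONTROLS, n_semantic_errors=0, regularity_p=0.8)
        assert prof.subtype == "phonological" and not prof.ambiguous
        assert prof.pseudoword_impaired

    def test_impaired_pseudowords_with_semantic_errors_is_deep(self):
        prof = out.classify_alexia(10.0, **self.CONTROLS, n_semantic_errors=4, regularity_p=0.6)
        assert prof.subtype == "deep"

    def test_regularity_effect_with_spared_pseudowords_is_surface(self):
        prof = out.classify_alexia(88.0, **self.CONTROLS, n_semantic_errors=0,
                                   regularity_p=0.002, n_regularization_errors=5)
        assert prof.subtype == "surface" and not prof.pseudoword_impaired

    def test_conflicting_evidence_is_flagged_not_silent(self):
        prof = out.classify_alexia(90.0, **self.CONTROLS, n_semantic_errors=0, regularity_p=0.9)
        assert prof.ambiguous


class TestAbsoluteGains:
    def test_reported_word_count_conversion(self):
        assert out.absolute_gains(8.7, 300, 6.0, 50) == 29

    def test_zero_gains(self):
        assert out.absolute_gains(0.0, 300, 0.0, 50) == 0

    def test_reported_rt_conversion(self):
        assert out.absolute_rt_gain(100.0, 300, 210.0, 50) == 116

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            out.absolute_gains(5.0, 0, 5.0, 50)


class TestImageabilitySplit:
    def test_forty_percent_split_of_ten_items(self):
        items = [f"w{i}" for i in range(10)]
        imag = {w: float(i) for i, w in enumerate(items)}
        changes = pd.DataFrame(
            np.arange(30).reshape(3, 10) * 1.0, columns=items, index=["p1", "p2", "p3"]
        )
        res = out.imageability_split(imag, changes)
        assert len(res["low_items"]) == 4 and len(res["high_items"]) == 6
        assert set(res["low_items"]) == {"w0", "w1", "w2", "w3"}

    def test_stratum_means_match_bruteforce_grouping(self):
        rng = np.random.default_rng(3)
        items = [f"w{i}" for i in range(15)]
        imag = {w: float(rng.uniform(1, 7)) for w in items}
        changes = pd.DataFrame(rng.normal(5, 2, (6, 15)), columns=items)
        res = out.imageability_split(imag, changes)
        thresh = sorted(imag.values())[5]  # floor(0.4*15) = 6 low items
        low = [w for w in items if imag[w] <= thresh]
        assert set(res["low_items"]) == set(low)
        assert res["low_mean_change"] == pytest.approx(changes[low].mean(axis=1).mean())

    def test_identical_strata_give_zero_t(self):
        items = [f"w{i}" for i in range(10)]
        imag = {w: float(i) for i, w in enumerate(items)}
        changes = pd.DataFrame(np.ones((4, 10)), columns=items)
        res = out.imageability_split(imag, changes)
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_missing_imageability_is_an_error(self):
        with pytest.raises(ValueError, match="missing"):
            out.imageability_split({}, pd.DataFrame({"w0": [1.0, 2.0]}))
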