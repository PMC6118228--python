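"""Adaptive engine: scoring, level logic, staircases, phases, sessions."""

import numpy as np
import pytest

import lexitrain.engine as eng
import lexitrain.learner as lrn
import lexitrain.stimuli as stm


def make_responder(correct=True, rt=300.0):
    def responder(word, duration_ms, tier, is_same, rng):
        ans = ("same" if is_same else "different") if correct else ("different" if is_same else "same")
        return ans, rt
    return responder


def chance_responder(rng_seed=0, rt=10_000.0):
    """Coin-flip responder with slow responses (expected phase score 0)."""
    local = np.random.default_rng(rng_seed)

    def responder(word, duration_ms, tier, is_same, rng):
        truth = "same" if is_same else "different"
        other = "different" if is_same else "same"
        return (truth if local.random() < 0.5 else other), rt
    return responder


@pytest.fixture()
def phase_setup():
    words = [f"w{i}" for i in range(10)]
    staircases = {w: eng.WordStaircase(orth=w) for w in words}
    distractors = {
        w: stm.DistractorSet(
            target=None, easy=[w[:-1] + "x"], medium=[w[:-1] + "y"], hard=[w[:-1] + "z"]
        )
        for w in words
    }
    return words, staircases, distractors


def make_params(**kw):
    cfg_kw = {k: kw.pop(k) for k in list(kw) if hasattr(eng.TrainingConfig, k)}
    return eng.AdaptiveParams(
        base_duration_ms=kw.pop("base_duration_ms", 1500.0),
        base_fast_rt_ms=kw.pop("base_fast_rt_ms", 800.0),
        config=eng.TrainingConfig(**cfg_kw),
        **kw,
    )


class TestScoring:
    @pytest.mark.parametrize(
        "correct,rt,fast,expected",
        [(True, 600, 800, 2), (True, 900, 800, 1), (False, 600, 800, -1), (True, 800, 800, 1)],
    )
    def test_points(self, correct, rt, fast, expected):
        assert eng.score_response(correct, rt, fast) == expected

    def test_nonpositive_rt_is_an_error(self):
        with pytest.raises(ValueError):
            eng.score_response(True, 0.0, 800.0)


class TestAdaptiveParams:
    def test_pass_increments_all_three_difficulty_parameters(self):
        p = make_params(level=5)
        q = eng.update_adaptive_params(p, passed=True)
        assert q.level == 6
        assert q.word_duration_ms == p.word_duration_ms - p.config.duration_delta_ms
        assert q.criterion_score == p.criterion_score + p.config.criterion_delta
        assert q.fast_rt_ms == p.fast_rt_ms - p.config.fast_rt_delta_ms
        assert q.fail_streak == 0

    def test_two_fails_leave_parameters_unchanged(self):
        p = make_params(level=3)
        q = eng.update_adaptive_params(eng.update_adaptive_params(p, False), False)
        assert q.level == 3 and q.fail_streak == 2
        assert q.word_duration_ms == p.word_duration_ms

    def test_third_fail_reverts_one_increment(self):
        p = make_params(level=3)
        q = p
        for _ in range(3):
            q = eng.update_adaptive_params(q, False)
        assert q.level == 2 and q.fail_streak == 0

    def test_pass_fail_fail_fail_restores_pre_pass_values(self):
        p = make_params(level=4)
        q = eng.update_adaptive_params(p, True)
        for _ in range(3):
            q = eng.update_adaptive_params(q, False)
        assert (q.word_duration_ms, q.criterion_score, q.fast_rt_ms) == (
            p.word_duration_ms, p.criterion_score, p.fast_rt_ms
        )

    def test_level_floors_at_zero_and_parameters_respect_floors(self):
        p = make_params(level=0)
        q = p
        for _ in range(3):
            q = eng.update_adaptive_params(q, False)
        assert q.level == 0
        deep = make_params(level=100)
        assert deep.word_duration_ms == deep.config.duration_floor_ms
        assert deep.fast_rt_ms == deep.config.fast_rt_floor_ms
        assert deep.criterion_score == deep.config.criterion_max


class TestStaircase:
    @pytest.mark.parametrize(
        "tier,correct,expected",
        [("easy", True, "medium"), ("medium", True, "hard"), ("hard", True, "hard"),
         ("medium", False, "easy"), ("easy", False, "easy")],
    )
    def test_one_step_moves_with_clamping(self, tier, correct, expected):
        s = eng.WordStaircase(orth="w", tier=tier)
        assert eng.update_word_staircase(s, correct).tier == expected


class TestExposurePhase:
    def test_emits_ten_events_and_updates_familiarity(self, flat_learner):
        params = make_params()
        before = flat_learner.familiarity.copy()
        events = eng.run_exposure_phase(flat_learner.words, params, flat_learner,
                                        np.random.default_rng(0))
        assert len(events) == 10
        assert all(e.duration_ms == params.word_duration_ms for e in events)
        assert np.all(flat_learner.familiarity >= before)
        assert {e.voice for e in events} <= {"female", "male"}

    def test_empty_schedule_is_an_error(self, flat_learner):
        with pytest.raises(ValueError):
            eng.run_exposure_phase([], make_params(), flat_learner, np.random.default_rng(0))


class TestChallengePhase:
    def test_fast_perfect_responder_passes_at_trial_ten_with_criterion_20(self, phase_setup):
        words, stairs, dis = phase_setup
        params = make_params(criterion_initial=20)
        out = eng.run_challenge_phase(words, params, stairs, dis, None,
                                      np.random.default_rng(1), responder=make_responder(True, 300.0))
        assert out.passed and out.score == 20 and out.trials_used == 10

    def test_always_incorrect_scores_minus_thirty(self, phase_setup):
        words, stairs, dis = phase_setup
        out = eng.run_challenge_phase(words, make_params(), stairs, dis, None,
                                      np.random.default_rng(1), responder=make_responder(False))
        assert not out.passed and out.score == -30 and out.trials_used == 30

    def test_same_different_balance_within_one_in_every_prefix(self, phase_setup):
        words, stairs, dis = phase_setup
        out = eng.run_challenge_phase(words, make_params(), stairs, dis, None,
                                      np.random.default_rng(2), responder=make_responder(False))
        running = 0
        for t in out.trials:
            running += 1 if t.is_same else -1
            assert abs(running) <= 1
        n_same = sum(t.is_same for t in out.trials)
        assert n_same == 15 and len(out.trials) - n_same == 15

    def test_score_equals_sum_of_trial_points(self, phase_setup):
        words, stairs, dis = phase_setup
        out = eng.run_challenge_phase(words, make_params(), stairs, dis, None,
                                      np.random.default_rng(3), responder=chance_responder(5))
        assert out.score == sum(t.points for t in out.trials)

    def test_distractor_drawn_at_current_tier_and_staircase_moves(self, phase_setup):
        words, stairs, dis = phase_setup
        out = eng.run_challenge_phase(words, make_params(), stairs, dis, None,
                                      np.random.default_rng(4), responder=make_responder(True, 300.0))
        for t in out.trials:
            if not t.is_same:
                assert t.written_word in dis[t.spoken_word].tier(t.distractor_tier)
        # a perfect responder drives every touched staircase upward
        touched = {t.spoken_word for t in out.trials}
        assert all(stairs[w].tier in ("medium", "hard") for w in touched)

    def test_missing_staircase_is_an_error(self, phase_setup):
        words, stairs, dis = phase_setup
        del stairs[words[0]]
        with pytest.raises(ValueError, match="staircase"):
            eng.run_challenge_phase(words, make_params(), stairs, dis, None,
                                    np.random.default_rng(0), responder=make_responder())

    def test_unreachable_early_stop_is_opt_in(self, phase_setup):
        words, stairs, dis = phase_setup
        params = make_params(stop_when_unreachable=True, criterion_initial=20)
        out = eng.run_challenge_phase(words, params, stairs, dis, None,
                                      np.random.default_rng(1), responder=make_responder(False))
        assert not out.passed and out.trials_used < 30


class TestDifficultyTrajectories:
    def test_perfect_responder_level_never_decreases(self, phase_setup):
        words, stairs, dis = phase_setup
        params = make_params()
        rng = np.random.default_rng(6)
        levels = []
        for _ in range(100):
            out = eng.run_challenge_phase(words, params, stairs, dis, None, rng,
                                          responder=make_responder(True, 300.0))
            params = eng.update_adaptive_params(params, out.passed)
            levels.append(params.level)
        assert all(b >= a for a, b in zip(levels, levels[1:]))
        assert params.level == 100  # every level passed

    def test_chance_responder_difficulty_stays_bounded(self, phase_setup):
        """With p=0.5 and slow responses the expected phase score is 0, so
        the level stays within one increment of the floor over 1000 phases."""
        words, stairs, dis = phase_setup
        params = make_params()
        rng = np.random.default_rng(7)
        responder = chance_responder(8)
        max_level = 0
        for _ in range(1000):
            out = eng.run_challenge_phase(words, params, stairs, dis, None, rng, responder=responder)
            params = eng.update_adaptive_params(params, out.passed)
            max_level = max(max_level, params.level)
        assert max_level <= 1


class TestSessionsAndBlocks:
    def _materials(self, flat_learner):
        words = flat_learner.words
        dis = {
            w: stm.DistractorSet(target=None, easy=[w[:-1] + "x"], medium=[w[:-1] + "y"],
                                 hard=[w[:-1] + "z"])
            for w in words
        }
        return words, dis

    def test_session_minutes_close_to_budget_and_deterministic(self, flat_learner):
        words, dis = self._materials(flat_learner)
        stairs = {w: eng.WordStaircase(orth=w) for w in words}
        params = make_params()
        logs = []
        for _ in range(2):
            state = lrn.LearnerState(
                ability=0.0, words=words, familiarity=np.full(10, 0.5),
                baseline_familiarity=np.full(10, 0.5), config=flat_learner.config, seed=42,
            )
            log, _ = eng.run_session(
                state, eng._Scheduler(list(words)), params,
                {w: eng.WordStaircase(orth=w) for w in words}, dis,
                "sham", np.random.default_rng(11), minutes=5.0,
            )
            logs.append(log)
        pair_max_s = 10 * 4.0 + 30 * 3.0
        assert 5.0 <= logs[0].minutes <= 5.0 + pair_max_s / 60.0
        assert logs[0].to_record() == logs[1].to_record()

    def test_challenge_words_come_from_preceding_exposure(self, flat_learner):
        words, dis = self._materials(flat_learner)
        calls = []
        orig = eng.run_exposure_phase

        def spy(batch, params, learner, rng, condition="sham"):
            calls.append(list(batch))
            return orig(batch, params, learner, rng, condition)

        state = flat_learner
        scheduler = eng._Scheduler(list(words))
        params = make_params()
        stairs = {w: eng.WordStaircase(orth=w) for w in words}
        rng = np.random.default_rng(12)
        batch = scheduler.next_batch(10)
        eng.run_exposure_phase(batch, params, state, rng)
        out = eng.run_challenge_phase(batch, params, stairs, dis, state, rng)
        assert {t.spoken_word for t in out.trials} <= set(batch)

    def test_block_reaches_dose_and_counts_exposures(self, flat_learner):
        words, dis = self._materials(flat_learner)
        params = make_params()
        log = eng.run_block(
            flat_learner, words, "anodal", params, np.random.default_rng(13), dis,
            target_hours=0.2, face_to_face_sessions=1, session_minutes=5.0,
        )
        assert log.total_minutes >= 0.2 * 60.0
        assert log.stimulated_sessions == 1
        assert set(log.exposure_counts) == set(words)
        stim = sum(c[0] for c in log.exposure_counts.values())
        total = sum(c[0] + c[1] for c in log.exposure_counts.values())
        assert stim > 0 and total == sum(s.exposures for s in log.sessions)
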