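"""Adaptive word-reading training engine.

The engine alternates two phases.  In an *exposure* phase the participant
passively views 10 trials pairing a picture with the written and spoken word
forms; each event produces one familiarity update in the learner model.  In a
*challenge* phase (up to 30 trials) a spoken word from the preceding exposure
set is paired with a written word - the same word in half the trials, a
distractor in the other half - and the participant answers same/different.
Scoring: +2 fast correct, +1 slow correct, -1 incorrect.  Reaching the
criterion score passes the level.

Difficulty is governed by three coupled parameters derived from a level
counter: written word duration (steps down), criterion score (steps up) and
the fast/slow RT boundary (steps down).  Passing a level advances all three
one increment; three successive failed levels revert them by one increment.
Independently, each word carries its own easy/medium/hard distractor
staircase that moves one step per response.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .learner import LearnerState, respond_same_different, update_familiarity
from .stimuli import DistractorSet

__all__ = [
    "TrainingConfig",
    "AdaptiveParams",
    "ChallengeTrial",
    "PhaseOutcome",
    "WordStaircase",
    "ExposureEvent",
    "SessionLog",
    "BlockLog",
    "score_response",
    "update_adaptive_params",
    "update_word_staircase",
    "run_exposure_phase",
    "run_challenge_phase",
    "run_session",
    "run_block",
]

TIERS = ("easy", "medium", "hard")

EXPOSURE_TRIALS_PER_PHASE = 10
MAX_CHALLENGE_TRIALS = 30


@dataclass(frozen=True)
class TrainingConfig:
    """Increment sizes, floors and timing of the adaptive procedure.

    The increments and the initial criterion are configuration (stand-ins,
    documented in the methods note): duration and the fast-RT boundary step
    *down* by one increment per level and the criterion steps *up*, which is
    the only direction in which all three make the task harder.
    """

    duration_delta_ms: float = 50.0
    duration_floor_ms: float = 100.0
    criterion_initial: int = 16
    criterion_delta: int = 2
    criterion_max: int = 2 * MAX_CHALLENGE_TRIALS
    fast_rt_delta_ms: float = 50.0
    fast_rt_floor_ms: float = 400.0
    exposure_trial_s: float = 4.0
    challenge_trial_s: float = 3.0
    stimulated_minutes: float = 20.0  # anodal period at the start of a session
    stop_when_unreachable: bool = False


@dataclass(frozen=True)
class AdaptiveParams:
    """The three coupled difficulty parameters plus level bookkeeping.

    Current values are derived from ``level`` and the participant's baseline
    anchors: word duration starts at the baseline reading speed and the
    fast-RT boundary at the baseline median RT.
    """

    base_duration_ms: float
    base_fast_rt_ms: float
    level: int = 0
    fail_streak: int = 0
    config: TrainingConfig = field(default_factory=TrainingConfig)

    def __post_init__(self) -> None:
        if self.level < 0 or not (0 <= self.fail_streak < 3):
            raise ValueError("level must be >= 0 and fail_streak in [0,3)")

    @property
    def word_duration_ms(self) -> float:
        c = self.config
        return max(c.duration_floor_ms, self.base_duration_ms - self.level * c.duration_delta_ms)

    @property
    def criterion_score(self) -> int:
        c = self.config
        return min(c.criterion_max, c.criterion_initial + self.level * c.criterion_delta)

    @property
    def fast_rt_ms(self) -> float:
        c = self.config
        return max(c.fast_rt_floor_ms, self.base_fast_rt_ms - self.level * c.fast_rt_delta_ms)


def score_response(correct: bool, rt_ms: float, fast_rt_ms: float) -> int:
    """+2 fast correct, +1 slow correct, -1 incorrect."""
    if rt_ms <= 0:
        raise ValueError("rt_ms must be positive")
    if not correct:
        return -1
    return 2 if rt_ms < fast_rt_ms else 1


def update_adaptive_params(params: AdaptiveParams, passed: bool) -> AdaptiveParams:
    """Level up on a pass; revert one increment after three successive fails."""
    if passed:
        return replace(params, level=params.level + 1, fail_streak=0)
    if params.fail_streak + 1 >= 3:
        return replace(params, level=max(0, params.level - 1), fail_streak=0)
    return replace(params, fail_streak=params.fail_streak + 1)


@dataclass(frozen=True)
class WordStaircase:
    """Per-word distractor-difficulty staircase (one-step moves, clamped)."""

    orth: str
    tier: str = "easy"

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")


def update_word_staircase(staircase: WordStaircase, correct: bool) -> WordStaircase:
    i = TIERS.index(staircase.tier)
    j = min(i + 1, 2) if correct else max(i - 1, 0)
    return replace(staircase, tier=TIERS[j])


@dataclass(frozen=True)
class ExposureEvent:
    orth: str
    duration_ms: float
    voice: str  # "female" | "male"


@dataclass(frozen=True)
class ChallengeTrial:
    spoken_word: str
    written_word: str
    is_same: bool
    distractor_tier: str | None
    response: str  # "same" | "different"
    rt_ms: float
    points: int

    def __post_init__(self) -> None:
        if self.is_same != (self.spoken_word == self.written_word):
            raise ValueError("is_same inconsistent with stimuli")


@dataclass
class PhaseOutcome:
    trials: list[ChallengeTrial]
    score: int
    passed: bool
    criterion: int

    @property
    def trials_used(self) -> int:
        return len(self.trials)


@dataclass
class SessionLog:
    session_index: int
    condition: str  # "anodal" | "sham" | "home"
    minutes: float
    phases: list[PhaseOutcome]
    exposures: int

    def to_record(self) -> dict:
        return {
            "session_index": self.session_index,
            "condition": self.condition,
            "minutes": round(self.minutes, 3),
            "n_phases": len(self.phases),
            "n_exposures": self.exposures,
            "scores": [p.score for p in self.phases],
            "passes": [p.passed for p in self.phases],
        }


@dataclass
class BlockLog:
    sessions: list[SessionLog]
    final_params: AdaptiveParams
    exposure_counts: dict[str, tuple[int, int]]  # orth -> (stimulated, unstimulated)

    @property
    def total_minutes(self) -> float:
        return sum(s.minutes for s in self.sessions)

    @property
    def stimulated_sessions(self) -> int:
        return sum(1 for s in self.sessions if s.condition == "anodal")


# ---------------------------------------------------------------------------
# phases


def run_exposure_phase(
    words: list[str],
    params: AdaptiveParams,
    learner: LearnerState,
    rng: np.random.Generator,
    condition: str = "sham",
) -> list[ExposureEvent]:
    """Run one 10-trial passive exposure phase; updates learner familiarity
    once per event and draws the speaker voice at random per trial."""
    if not words:
        raise ValueError("empty exposure schedule")
    if len(words) != EXPOSURE_TRIALS_PER_PHASE:
        raise ValueError(f"exposure phase needs exactly {EXPOSURE_TRIALS_PER_PHASE} scheduled items")
    events = []
    for w in words:
        voice = "female" if rng.random() < 0.5 else "male"
        update_familiarity(learner, w, condition=condition)
        events.append(ExposureEvent(orth=w, duration_ms=params.word_duration_ms, voice=voice))
    return events


def _balanced_same_sequence(n: int, rng: np.random.Generator) -> list[bool]:
    """Same/different indicator sequence whose every prefix is balanced to
    within one trial (randomized within successive pairs)."""
    out: list[bool] = []
    while len(out) < n:
        pair = [True, False]
        if rng.random() < 0.5:
            pair.reverse()
        out.extend(pair)
    return out[:n]


def run_challenge_phase(
    words: list[str],
    params: AdaptiveParams,
    staircases: dict[str, WordStaircase],
    distractors: dict[str, DistractorSet],
    learner: LearnerState | None,
    rng: np.random.Generator,
    responder=None,
) -> PhaseOutcome:
    """Run one challenge phase of up to 30 same/different trials.

    Trials cycle through the exposure words; the written stimulus on
    "different" trials is drawn from the word's current staircase tier.  The
    phase stops as soon as the criterion score is reached (pass), after 30
    trials (fail), or - if configured - as soon as the criterion has become
    unreachable in the remaining trials.

    ``responder(word, duration_ms, tier, is_same, rng) -> (response, rt_ms)``
    may replace the learner model (e.g. scripted responders in validation
    studies); by default the learner's same/different model is used.
    """
    if responder is None:
        if learner is None:
            raise ValueError("either a learner or a responder is required")

        def responder(word, duration_ms, tier, is_same, rng):
            return respond_same_different(learner, word, duration_ms, tier, is_same, rng=rng)

    for w in words:
        if w not in staircases:
            raise ValueError(f"missing staircase for word {w!r}")
        if w not in distractors:
            raise ValueError(f"missing distractor set for word {w!r}")
    criterion = params.criterion_score
    same_seq = _balanced_same_sequence(MAX_CHALLENGE_TRIALS, rng)
    order = list(rng.permutation(len(words)))
    trials: list[ChallengeTrial] = []
    score = 0
    passed = False
    for t in range(MAX_CHALLENGE_TRIALS):
        w = words[order[t % len(words)]]
        is_same = same_seq[t]
        tier = staircases[w].tier
        if is_same:
            written = w
            shown_tier = None
        else:
            bank = distractors[w].tier(tier)
            written = bank[int(rng.integers(len(bank)))]
            shown_tier = tier
        response, rt = responder(w, params.word_duration_ms, shown_tier, is_same, rng)
        correct = response == ("same" if is_same else "different")
        pts = score_response(correct, rt, params.fast_rt_ms)
        score += pts
        staircases[w] = update_word_staircase(staircases[w], correct)
        trials.append(
            ChallengeTrial(
                spoken_word=w,
                written_word=written,
                is_same=is_same,
                distractor_tier=shown_tier,
                response=response,
                rt_ms=rt,
                points=pts,
            )
        )
        if score >= criterion:
            passed = True
            break
        remaining = MAX_CHALLENGE_TRIALS - (t + 1)
        if params.config.stop_when_unreachable and score + 2 * remaining < criterion:
            break
    return PhaseOutcome(trials=trials, score=score, passed=passed, criterion=criterion)


# ---------------------------------------------------------------------------
# sessions and blocks


class _Scheduler:
    """Least-recently-trained-first cycling over the block's trained words."""

    def __init__(self, words: list[str]):
        if not words:
            raise ValueError("empty training schedule")
        self.queue = list(words)

    def next_batch(self, k: int) -> list[str]:
        batch = []
        while len(batch) < k:
            w = self.queue.pop(0)
            batch.append(w)
            self.queue.append(w)
        return batch


def run_session(
    learner: LearnerState,
    scheduler: _Scheduler,
    params: AdaptiveParams,
    staircases: dict[str, WordStaircase],
    distractors: dict[str, DistractorSet],
    condition: str,
    rng: np.random.Generator,
    minutes: float = 40.0,
    session_index: int = 0,
    exposure_counts: dict[str, list[int]] | None = None,
) -> tuple[SessionLog, AdaptiveParams]:
    """Run alternating exposure/challenge phases until the minute budget is
    spent.  During an anodal session the stimulation condition applies only to
    exposure events within the first ``stimulated_minutes`` of the session."""
    if minutes <= 0:
        raise ValueError("minutes must be positive")
    cfg = params.config
    elapsed_s = 0.0
    phases: list[PhaseOutcome] = []
    n_exposures = 0
    while elapsed_s < minutes * 60.0:
        batch = scheduler.next_batch(EXPOSURE_TRIALS_PER_PHASE)
        stim_now = condition == "anodal" and elapsed_s < cfg.stimulated_minutes * 60.0
        event_condition = "anodal" if stim_now else "sham"
        run_exposure_phase(batch, params, learner, rng, condition=event_condition)
        if exposure_counts is not None:
            for w in batch:
                exposure_counts.setdefault(w, [0, 0])[0 if stim_now else 1] += 1
        n_exposures += EXPOSURE_TRIALS_PER_PHASE
        elapsed_s += EXPOSURE_TRIALS_PER_PHASE * cfg.exposure_trial_s
        outcome = run_challenge_phase(batch, params, staircases, distractors, learner, rng)
        elapsed_s += outcome.trials_used * cfg.challenge_trial_s
        phases.append(outcome)
        params = update_adaptive_params(params, outcome.passed)
    log = SessionLog(
        session_index=session_index,
        condition=condition,
        minutes=elapsed_s / 60.0,
        phases=phases,
        exposures=n_exposures,
    )
    return log, params


def run_block(
    learner: LearnerState,
    trained_words: list[str],
    condition: str,
    params0: AdaptiveParams,
    rng: np.random.Generator,
    distractors: dict[str, DistractorSet],
    target_hours: float = 35.0,
    face_to_face_sessions: int = 11,
    session_minutes: float = 40.0,
) -> BlockLog:
    """Run one training block: stimulated face-to-face sessions first, then
    unstimulated home sessions until the cumulative logged time reaches the
    target dose.  ``condition`` is the block's stimulation condition
    ("anodal" or "sham"); home sessions are always unstimulated."""
    if target_hours <= 0:
        raise ValueError("target_hours must be positive")
    scheduler = _Scheduler(list(trained_words))
    staircases = {w: WordStaircase(orth=w) for w in trained_words}
    params = params0
    sessions: list[SessionLog] = []
    counts: dict[str, list[int]] = {}
    index = 0
    total_minutes = 0.0
    while total_minutes < target_hours * 60.0:
        sess_condition = condition if index < face_to_face_sessions else "home"
        log, params = run_session(
            learner,
            scheduler,
            params,
            staircases,
            distractors,
            sess_condition,
            rng,
            minutes=session_minutes,
            session_index=index,
            exposure_counts=counts,
        )
        sessions.append(log)
        total_minutes += log.minutes
        index += 1
    return BlockLog(
        sessions=sessions,
        final_params=params,
        exposure_counts={w: (c[0], c[1]) for w, c in counts.items()},
    )
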