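"""Synthetic participant model.

A learner is a bank of per-word familiarity values in [0, 1] plus a global
ability offset.  Familiarity drives both tasks the trial machinery needs:

* same/different audio-visual matching (the training task), via a guessing-
  corrected logistic model: P(correct) = 0.5 + 0.5 * sigmoid(...)
* oral single-word reading (the outcome task), scored 1 / 0.5 / 0 with a
  voice-key reaction time that shortens as familiarity grows.

Learning is a saturating update f <- f + eta * m * (1 - f) applied once per
exposure event; ``m`` is the stimulation multiplier (> 1 during anodal tDCS,
1 otherwise).  Under anodal stimulation every *other* word also receives a
small spillover g * eta * (m - 1) * (1 - f), which is what lets stimulation
effects generalize to untrained items while leaving a multiplier of exactly 1
perfectly null.  Forgetting relaxes familiarity exponentially toward its
pre-training baseline.  Deficits (1 - f) transform multiplicatively under
every update, so update order never matters - block-level outcomes have an
exact closed form used by the aggregate trial fidelity.

This is a behavioural stand-in, not a cognitive architecture: it is the
simplest mechanism exhibiting item-specific training gains, a generalizing
stimulation effect, test-retest practice gains, and partial maintenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "LearnerState",
    "LearnerConfig",
    "TIER_DIFFICULTY",
    "respond_same_different",
    "read_aloud",
    "read_aloud_battery",
    "update_familiarity",
    "apply_aggregate_training",
    "decay_familiarity",
    "apply_practice_effect",
    "generate_cohort",
]

TIER_DIFFICULTY = {"easy": 0.0, "medium": 1.0, "hard": 2.0, None: 0.0, "none": 0.0}

READ_TIMEOUT_MS = 4000.0


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class LearnerConfig:
    """Constants of the response and learning models (defaults are the
    package's calibrated study conditions; see the methods note)."""

    # same/different model
    k_familiarity: float = 3.0
    k_duration: float = 0.5  # per log-unit of duration relative to 1 s
    k_tier: float = 0.75
    duration_ref_ms: float = 1000.0
    # oral reading model: P(correct) = sigmoid(ability + slope * (f - 0.5))
    read_slope: float = 6.0
    p_self_correct: float = 0.05
    # reaction-time model
    rt_base_ms: float = 800.0
    rt_span_ms: float = 1700.0
    rt_noise_sd: float = 0.18  # SD of log RT
    # learning
    learning_rate: float = 0.0023
    tdcs_multiplier: float = 3.0
    generalization_rate: float = 0.005
    decay_rate: float = 0.004  # per day
    practice_effect: float = 0.02  # global familiarity bump per assessment


@dataclass
class LearnerState:
    """One synthetic participant."""

    ability: float
    words: list[str]
    familiarity: np.ndarray  # aligned with words, values in [0,1]
    baseline_familiarity: np.ndarray  # snapshot used as the decay attractor
    config: LearnerConfig = field(default_factory=LearnerConfig)
    seed: int = 0
    participant_id: str = "P0"

    def __post_init__(self) -> None:
        self.familiarity = np.asarray(self.familiarity, float)
        self.baseline_familiarity = np.asarray(self.baseline_familiarity, float)
        if self.familiarity.min() < 0 or self.familiarity.max() > 1:
            raise ValueError("familiarity values must lie in [0,1]")
        self._index = {w: i for i, w in enumerate(self.words)}
        self.rng = np.random.default_rng(self.seed)

    def idx(self, word: str) -> int:
        try:
            return self._index[word]
        except KeyError:
            raise KeyError(f"unknown word {word!r}") from None

    def f(self, word: str) -> float:
        return float(self.familiarity[self.idx(word)])

    def snapshot_baseline(self) -> None:
        """Freeze current familiarity as the forgetting attractor."""
        self.baseline_familiarity = self.familiarity.copy()

    def to_json(self) -> str:
        d = {
            "participant_id": self.participant_id,
            "ability": self.ability,
            "seed": self.seed,
            "config": asdict(self.config),
            "words": self.words,
            "familiarity": self.familiarity.tolist(),
            "baseline_familiarity": self.baseline_familiarity.tolist(),
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LearnerState":
        d = json.loads(text)
        return cls(
            ability=d["ability"],
            words=d["words"],
            familiarity=np.array(d["familiarity"]),
            baseline_familiarity=np.array(d["baseline_familiarity"]),
            config=LearnerConfig(**d["config"]),
            seed=d["seed"],
            participant_id=d["participant_id"],
        )


# ---------------------------------------------------------------------------
# response models


def p_correct_same_different(
    state: LearnerState, word: str, duration_ms: float, tier: str | None
) -> float:
    """Guessing-corrected probability of a correct same/different response."""
    cfg = state.config
    logit = (
        state.ability
        + cfg.k_familiarity * state.f(word)
        + cfg.k_duration * np.log(duration_ms / cfg.duration_ref_ms)
        - cfg.k_tier * TIER_DIFFICULTY[tier]
    )
    return float(0.5 + 0.5 * _sigmoid(logit))


def respond_same_different(
    state: LearnerState,
    word: str,
    duration_ms: float,
    tier: str | None,
    is_same: bool,
    rng: np.random.Generator | None = None,
) -> tuple[str, float]:
    """Simulate one same/different trial; returns (response, rt_ms)."""
    rng = rng or state.rng
    p = p_correct_same_different(state, word, duration_ms, tier)
    correct = rng.random() < p
    response = ("same" if is_same else "different") if correct else (
        "different" if is_same else "same"
    )
    cfg = state.config
    loc = cfg.rt_base_ms + cfg.rt_span_ms * (1.0 - state.f(word))
    rt = float(np.exp(rng.normal(np.log(loc), cfg.rt_noise_sd)))
    return response, rt


def read_aloud(
    state: LearnerState, word: str, rng: np.random.Generator | None = None
) -> tuple[float, float | None]:
    """Simulate one oral reading trial.

    Returns (score, rt_ms): score 1 for correct, 0.5 for a self-correction,
    0 for incorrect; RT is reported only for clean correct responses and a
    simulated onset beyond the 4-s display window scores 0 (timeout).
    """
    rng = rng or state.rng
    cfg = state.config
    f = state.f(word)
    p1 = float(_sigmoid(state.ability + cfg.read_slope * (f - 0.5)))
    if rng.random() >= p1:
        return 0.0, None
    if rng.random() < cfg.p_self_correct:
        return 0.5, None
    loc = cfg.rt_base_ms + cfg.rt_span_ms * (1.0 - f)
    rt = float(np.exp(rng.normal(np.log(loc), cfg.rt_noise_sd)))
    if rt > READ_TIMEOUT_MS:
        return 0.0, None
    return 1.0, rt


def read_aloud_battery(
    state: LearnerState, words: list[str], rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized oral-reading assessment over a word list.

    Returns (scores, rts); rts are NaN where no clean correct RT exists.
    Statistically identical to calling :func:`read_aloud` per item.
    """
    rng = rng or state.rng
    cfg = state.config
    idx = np.array([state.idx(w) for w in words])
    f = state.familiarity[idx]
    p1 = _sigmoid(state.ability + cfg.read_slope * (f - 0.5))
    correct = rng.random(len(words)) < p1
    selfc = rng.random(len(words)) < cfg.p_self_correct
    loc = cfg.rt_base_ms + cfg.rt_span_ms * (1.0 - f)
    rt = np.exp(rng.normal(np.log(loc), cfg.rt_noise_sd))
    timeout = rt > READ_TIMEOUT_MS

    scores = np.where(correct, np.where(selfc, 0.5, 1.0), 0.0)
    scores = np.where(correct & ~selfc & timeout, 0.0, scores)
    rts = np.where(correct & ~selfc & ~timeout, rt, np.nan)
    return scores, rts


# ---------------------------------------------------------------------------
# learning, spillover, forgetting


def update_familiarity(state: LearnerState, word: str, condition: str = "sham") -> None:
    """One exposure event: saturating update of the target word, plus
    spillover to all other words when the stimulation condition is anodal."""
    cfg = state.config
    i = state.idx(word)
    m = cfg.tdcs_multiplier if condition == "anodal" else 1.0
    if condition == "anodal" and cfg.generalization_rate > 0 and m > 1.0:
        spill = cfg.generalization_rate * cfg.learning_rate * (m - 1.0)
        target_f = state.familiarity[i]
        state.familiarity += spill * (1.0 - state.familiarity)
        state.familiarity[i] = target_f  # target gets the full update below, not spillover
    state.familiarity[i] += cfg.learning_rate * m * (1.0 - state.familiarity[i])
    np.clip(state.familiarity, 0.0, 1.0, out=state.familiarity)


def apply_aggregate_training(
    state: LearnerState,
    exposure_counts: dict[str, tuple[int, int]],
    total_stimulated_events: int,
) -> None:
    """Closed-form equivalent of a sequence of exposure events.

    ``exposure_counts`` maps each trained word to (n_stimulated,
    n_unstimulated) targeted exposures; ``total_stimulated_events`` is the
    total number of anodal exposure events in the block (source of spillover
    to every word).  Because each update multiplies the deficit (1 - f) by a
    constant factor, the aggregate is exact regardless of event order.
    """
    cfg = state.config
    eta, m, g = cfg.learning_rate, cfg.tdcs_multiplier, cfg.generalization_rate
    log_keep = np.zeros_like(state.familiarity)
    spill = g * eta * (m - 1.0)
    if total_stimulated_events > 0 and spill > 0:
        log_keep += np.log1p(-spill) * total_stimulated_events
    for word, (k_stim, k_unstim) in exposure_counts.items():
        i = state.idx(word)
        if k_stim:
            log_keep[i] += (np.log1p(-eta * m) - np.log1p(-spill)) * k_stim
        if k_unstim:
            log_keep[i] += np.log1p(-eta) * k_unstim
    state.familiarity = 1.0 - (1.0 - state.familiarity) * np.exp(log_keep)
    np.clip(state.familiarity, 0.0, 1.0, out=state.familiarity)


def decay_familiarity(state: LearnerState, days: float) -> None:
    """Exponential relaxation toward the pre-training baseline familiarity."""
    if days < 0:
        raise ValueError("days must be >= 0")
    lam = state.config.decay_rate
    keep = np.exp(-lam * days)
    state.familiarity = state.baseline_familiarity + (
        state.familiarity - state.baseline_familiarity
    ) * keep
    np.clip(state.familiarity, 0.0, 1.0, out=state.familiarity)


def apply_practice_effect(state: LearnerState) -> None:
    """Small global familiarity bump from taking an assessment (test-retest)."""
    eps = state.config.practice_effect
    state.familiarity += eps * (1.0 - state.familiarity)
    np.clip(state.familiarity, 0.0, 1.0, out=state.familiarity)


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(
    words: list[str],
    n: int = 21,
    seed: int = 0,
    config: LearnerConfig | None = None,
    mean_accuracy_target: float = 0.57,
    severity_spread: float = 0.22,
    item_concentration: float = 8.0,
) -> list[LearnerState]:
    """Generate ``n`` learners spanning a realistic severity range.

    Per-learner mean familiarity mu is drawn around the value that produces
    the target cohort mean reading accuracy; per-word baseline familiarity is
    Beta(mu * kappa, (1 - mu) * kappa).  The resulting baseline accuracies
    span roughly 5-95%, matching the heterogeneity of chronic central alexia.
    """
    cfg = config or LearnerConfig()
    rng = np.random.default_rng(seed)
    # invert the reading model at ability 0 to centre the severity scale
    mu_centre = 0.5 + np.log(mean_accuracy_target / (1 - mean_accuracy_target)) / cfg.read_slope
    learners = []
    for i in range(n):
        mu = float(np.clip(rng.normal(mu_centre, severity_spread), 0.05, 0.92))
        a = mu * item_concentration
        b = (1 - mu) * item_concentration
        fam = rng.beta(a, b, size=len(words))
        child_seed = int(rng.integers(0, 2**31 - 1))
        learners.append(
            LearnerState(
                ability=0.0,
                words=list(words),
                familiarity=fam,
                baseline_familiarity=fam.copy(),
                config=cfg,
                seed=child_seed,
                participant_id=f"P{i + 1:02d}",
            )
        )
    return learners
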