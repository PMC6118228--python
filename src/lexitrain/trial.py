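"""Crossover-trial simulation.

Simulates the full baseline-controlled, repeated-measures crossover design:
minimization-randomized allocation to the two stimulation-order groups,
counterbalanced assignment of the A/B/C word lists to training roles, six
assessment timepoints (T1-T6 at 4-week spacing, with a 3-month follow-up),
two 4-week training blocks with the stimulation condition crossed between
groups, and forgetting over the follow-up interval.

Two fidelities are available.  ``engine`` runs the adaptive training engine
trial by trial; ``aggregate`` applies the exact closed form of the learner's
familiarity updates implied by the deterministic round-robin exposure
schedule (deficits transform multiplicatively, so event order is
irrelevant), which makes large Monte-Carlo studies of the design tractable.

Outcome records never carry the stimulation condition; analyses join the
allocation record explicitly, mirroring the blinding of outcome assessment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import engine as eng
from . import learner as lrn
from . import lexicon as lex
from . import outcomes as out
from . import stimuli as stm

__all__ = [
    "TrialSchedule",
    "TrialConfig",
    "Participant",
    "CrossoverResult",
    "StudyMaterials",
    "minimize_allocation",
    "assign_word_lists",
    "build_study_materials",
    "run_crossover_trial",
    "change_scores",
    "therapy_anova",
    "effect_size_table",
    "tdcs_contrast",
]

ROLE_PERMUTATIONS = list(itertools.permutations(stm.ROLES))


@dataclass(frozen=True)
class TrialSchedule:
    """Timepoint offsets in days.  T2-T5 are spaced 28 days; the follow-up
    T6 is 90 days after T5."""

    t1: int = 0
    t2: int = 28
    t3: int = 56
    t4: int = 84
    t5: int = 112
    t6: int = 202

    def __post_init__(self) -> None:
        days = [self.t1, self.t2, self.t3, self.t4, self.t5, self.t6]
        if sorted(days) != days or len(set(days)) != 6:
            raise ValueError("timepoints must be strictly increasing")
        for a, b in ((self.t2, self.t3), (self.t3, self.t4), (self.t4, self.t5)):
            if b - a != 28:
                raise ValueError("T2-T5 must be spaced 28 days apart")
        if self.t6 - self.t5 != 90:
            raise ValueError("T6 must be 90 days after T5")

    @property
    def followup_days(self) -> int:
        return self.t6 - self.t5


@dataclass
class TrialConfig:
    """All knobs of a simulated trial run."""

    n_participants: int = 21
    # stimulus materials
    lexicon_n: int = 8000
    zipf_tail_exponent: float = 0.6
    min_word_frequency: float = 50.0
    n_triplets: int = 180
    core_k: int = 50
    customized_m: int = 150
    test_k: int = 90
    test_core_k: int = 30
    customize: str = "anneal"  # "anneal" | "first" (skip baseline matching)
    # dose
    target_hours: float = 35.0
    face_to_face_sessions: int = 11
    session_minutes: float = 40.0
    stimulated_minutes: float = 20.0
    # simulation fidelity
    fidelity: str = "aggregate"  # "aggregate" | "engine"
    avg_challenge_trials: float = 20.0  # aggregate-mode session composition
    # learner population
    learner: lrn.LearnerConfig = field(default_factory=lrn.LearnerConfig)
    # allocation
    minimization_p: float = 0.8
    schedule: TrialSchedule = field(default_factory=TrialSchedule)
    include_followup: bool = True  # Monte-Carlo studies of T3-T5 may skip T6

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.fidelity not in ("aggregate", "engine"):
            raise ValueError(f"unknown fidelity {self.fidelity!r}")
        if self.customize not in ("anneal", "first"):
            raise ValueError(f"unknown customize mode {self.customize!r}")
        if self.target_hours <= 0 or self.session_minutes <= 0:
            raise ValueError("dose must be positive")
        if self.test_k > self.customized_m or self.test_core_k > self.core_k:
            raise ValueError("testing subsets cannot exceed their parent lists")


@dataclass
class Participant:
    id: str
    learner: lrn.LearnerState
    baseline_accuracy_pct: float = float("nan")
    baseline_rt_ms: float = float("nan")
    group: int | None = None  # 1: anodal first; 2: sham first
    assignment: stm.PatientListAssignment | None = None

    def block_condition(self, block: int) -> str:
        if self.group is None:
            raise ValueError(f"participant {self.id} not yet allocated")
        anodal_block = 1 if self.group == 1 else 2
        return "anodal" if block == anodal_block else "sham"


@dataclass
class StudyMaterials:
    lexicon: lex.Lexicon
    candidates: list[lex.WordEntry]
    listset: stm.WordListSet
    distractor_pool: lex.Lexicon  # high-frequency pool used for distractors


@dataclass
class CrossoverResult:
    results: pd.DataFrame  # participant, timepoint, wordlist (role), item, score, rt_ms
    allocation: pd.DataFrame  # participant, group, baseline acc/rt, counterbalance index
    participants: list[Participant]
    block_logs: dict[tuple[str, int], eng.BlockLog] = field(default_factory=dict)
    schedule: TrialSchedule = field(default_factory=TrialSchedule)


# ---------------------------------------------------------------------------
# allocation


def _terciles(values: np.ndarray) -> np.ndarray:
    q1, q2 = np.quantile(values, [1 / 3, 2 / 3])
    return np.digitize(values, [q1, q2])


def minimize_allocation(
    baselines: list[tuple[float, float]],
    seed: int = 0,
    p_assign: float = 0.8,
) -> np.ndarray:
    """Pocock-Simon minimization over severity strata.

    Participants arrive in order with known baseline (accuracy, RT); strata
    are accuracy terciles x RT terciles.  Each arrival goes to the arm
    minimizing the summed within-stratum imbalance (range method) with
    probability ``p_assign``, at random on ties, under a hard cap of
    ceil(N/2) per arm (the block-randomization component, which fixes the
    final group sizes).  Returns group labels 1/2, deterministic under seed.
    """
    n = len(baselines)
    acc = np.array([b[0] for b in baselines], float)
    rt = np.array([b[1] for b in baselines], float)
    acc_t = _terciles(acc)
    rt_t = _terciles(rt)
    rng = np.random.default_rng(seed)
    cap = int(np.ceil(n / 2))
    counts = {f: np.zeros((3, 2)) for f in ("acc", "rt")}
    sizes = np.zeros(2, int)
    groups = np.empty(n, int)
    for i in range(n):
        if sizes[0] >= cap:
            arm = 1
        elif sizes[1] >= cap:
            arm = 0
        else:
            imb = np.zeros(2)
            for arm_try in (0, 1):
                for fname, stratum in (("acc", acc_t[i]), ("rt", rt_t[i])):
                    row = counts[fname][stratum].copy()
                    row[arm_try] += 1
                    imb[arm_try] += row.max() - row.min()
            if imb[0] == imb[1]:
                arm = int(rng.integers(2))
            else:
                best = int(np.argmin(imb))
                arm = best if rng.random() < p_assign else 1 - best
        groups[i] = arm + 1
        sizes[arm] += 1
        counts["acc"][acc_t[i], arm] += 1
        counts["rt"][rt_t[i], arm] += 1
    return groups


def assign_word_lists(assignment: stm.PatientListAssignment, participant_index: int) -> stm.PatientListAssignment:
    """Counterbalance the A/B/C -> role mapping by cycling the six
    permutations with participant index."""
    perm = ROLE_PERMUTATIONS[participant_index % len(ROLE_PERMUTATIONS)]
    assignment.roles = dict(zip(stm.LIST_LABELS, perm))
    assignment.counterbalance_index = participant_index % len(ROLE_PERMUTATIONS)
    return assignment


# ---------------------------------------------------------------------------
# materials


def build_study_materials(config: TrialConfig, seed: int) -> StudyMaterials:
    """Generate the lexicon and the matched word lists shared by a study."""
    rng = np.random.default_rng(seed)
    lex_seed = int(rng.integers(2**31 - 1))
    list_seed = int(rng.integers(2**31 - 1))
    lexicon = lex.generate_lexicon(
        config.lexicon_n,
        lex_seed,
        lex.LexiconConfig(zipf_tail_exponent=config.zipf_tail_exponent),
    )
    candidates = lex.filter_training_candidates(lexicon, min_freq=config.min_word_frequency)
    listset = stm.build_matched_triplets(
        candidates,
        n_triplets=config.n_triplets,
        seed=list_seed,
        core_k=config.core_k,
    )
    pool = lex.Lexicon(entries=list(candidates), seed=lex_seed)
    return StudyMaterials(lexicon=lexicon, candidates=candidates, listset=listset, distractor_pool=pool)


# ---------------------------------------------------------------------------
# assessments


def _assess(
    participant: Participant,
    words: dict[str, list[lex.WordEntry]],
    timepoint: str,
    rows: list,
    practice: bool = True,
) -> None:
    state = participant.learner
    for wordlist, entries in words.items():
        orths = [w.orth for w in entries]
        scores, rts = lrn.read_aloud_battery(state, orths)
        for o, s, r in zip(orths, scores, rts):
            rows.append(
                (participant.id, timepoint, wordlist, o, float(s), float(r) if np.isfinite(r) else np.nan)
            )
    if practice:
        lrn.apply_practice_effect(state)


def _baseline_maps(participant: Participant, corpus: list[lex.WordEntry], rows: list) -> dict:
    """Baseline administration of the full corpus, split over the T1 and T2
    sessions; returns per-item (score, rt) plus summary accuracy/RT."""
    orths = [w.orth for w in corpus]
    state = participant.learner
    half = len(orths) // 2
    order = state.rng.permutation(len(orths))
    baseline: dict[str, tuple[float, float | None]] = {}
    all_scores: list[float] = []
    all_rts: list[float] = []
    for tp, idx in (("T1", order[:half]), ("T2", order[half:])):
        sub = [orths[i] for i in idx]
        scores, rts = lrn.read_aloud_battery(state, sub)
        for o, s, r in zip(sub, scores, rts):
            rr = float(r) if np.isfinite(r) else None
            baseline[o] = (float(s), rr)
            rows.append((participant.id, tp, "corpus", o, float(s), rr if rr is not None else np.nan))
        all_scores.extend(scores)
        all_rts.extend(rts[np.isfinite(rts)])
        lrn.apply_practice_effect(state)
    trimmed = out.trim_reaction_times(all_rts) if all_rts else []
    participant.baseline_accuracy_pct = float(100 * np.mean(all_scores))
    participant.baseline_rt_ms = float(np.mean(trimmed)) if trimmed else 2000.0
    return baseline


# ---------------------------------------------------------------------------
# training


def _aggregate_block(
    participant: Participant,
    trained: list[str],
    condition: str,
    config: TrialConfig,
) -> None:
    """Closed-form block training (see module docstring)."""
    cfg = config
    pair_s = 10 * eng.TrainingConfig.exposure_trial_s + cfg.avg_challenge_trials * eng.TrainingConfig.challenge_trial_s
    total_minutes = cfg.target_hours * 60.0
    n_sessions = int(np.ceil(total_minutes / cfg.session_minutes))
    pairs_per_session = cfg.session_minutes * 60.0 / pair_s
    total_pairs = pairs_per_session * n_sessions
    total_events = total_pairs * 10.0
    stim_sessions = min(cfg.face_to_face_sessions, n_sessions) if condition == "anodal" else 0
    stim_events = stim_sessions * min(cfg.stimulated_minutes, cfg.session_minutes) * 60.0 / pair_s * 10.0
    phi = stim_events / total_events if total_events else 0.0
    per_word = total_events / len(trained)
    counts = {w: (per_word * phi, per_word * (1 - phi)) for w in trained}
    lrn.apply_aggregate_training(participant.learner, counts, stim_events)


def _engine_block(
    participant: Participant,
    trained: list[str],
    condition: str,
    config: TrialConfig,
    materials: StudyMaterials,
    rng: np.random.Generator,
) -> eng.BlockLog:
    tcfg = eng.TrainingConfig(stimulated_minutes=config.stimulated_minutes)
    params0 = eng.AdaptiveParams(
        base_duration_ms=max(participant.baseline_rt_ms, tcfg.duration_floor_ms),
        base_fast_rt_ms=max(participant.baseline_rt_ms, tcfg.fast_rt_floor_ms),
        config=tcfg,
    )
    distractors = {
        w: stm.build_distractor_set(
            materials.distractor_pool[w] if w in materials.distractor_pool else w,
            materials.distractor_pool,
        )
        for w in trained
    }
    return eng.run_block(
        participant.learner,
        trained,
        condition,
        params0,
        rng,
        distractors,
        target_hours=config.target_hours,
        face_to_face_sessions=config.face_to_face_sessions,
        session_minutes=config.session_minutes,
    )


# ---------------------------------------------------------------------------
# the full trial


def run_crossover_trial(
    config: TrialConfig | None = None,
    seed: int = 0,
    materials: StudyMaterials | None = None,
    cohort: list[lrn.LearnerState] | None = None,
) -> CrossoverResult:
    """Simulate the complete crossover trial and return tidy outcome data."""
    config = config or TrialConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    mat_seed = int(rng.integers(2**31 - 1))
    cohort_seed = int(rng.integers(2**31 - 1))
    alloc_seed = int(rng.integers(2**31 - 1))
    train_seed = int(rng.integers(2**31 - 1))

    if materials is None:
        materials = build_study_materials(config, mat_seed)
    listset = materials.listset
    corpus = listset.all_words()
    corpus_orths = [w.orth for w in corpus]

    if cohort is None:
        cohort = lrn.generate_cohort(
            corpus_orths, n=config.n_participants, seed=cohort_seed, config=config.learner
        )
    participants = [Participant(id=s.participant_id, learner=s) for s in cohort]

    rows: list = []
    baselines: dict[str, dict] = {}
    for p in participants:
        baselines[p.id] = _baseline_maps(p, corpus, rows)

    groups = minimize_allocation(
        [(p.baseline_accuracy_pct, p.baseline_rt_ms) for p in participants],
        seed=alloc_seed,
        p_assign=config.minimization_p,
    )
    for p, g in zip(participants, groups):
        p.group = int(g)

    train_rng = np.random.default_rng(train_seed)
    for i, p in enumerate(participants):
        if config.customize == "anneal":
            asg = stm.customize_patient_lists(
                listset, baselines[p.id], m=config.customized_m, seed=int(train_rng.integers(2**31 - 1))
            )
            asg = stm.select_testing_subsets(
                asg,
                baselines[p.id],
                k=config.test_k,
                core_k=config.test_core_k,
                seed=int(train_rng.integers(2**31 - 1)),
            )
        else:
            asg = stm.PatientListAssignment(
                listset=listset,
                triplet_indices=list(range(config.customized_m)),
                permutations=[(0, 1, 2)] * config.customized_m,
            )
            asg.test_triplet_positions = list(range(config.test_k))
            asg.test_core = listset.core[: config.test_core_k]
        assign_word_lists(asg, i)
        p.assignment = asg

    block_logs: dict[tuple[str, int], eng.BlockLog] = {}
    for p in participants:
        battery = p.assignment.battery()
        _assess(p, battery, "T3", rows)
        for block in (1, 2):
            trained_words = [
                w.orth
                for w in (p.assignment.trained_block1 if block == 1 else p.assignment.trained_block2)
            ] + [w.orth for w in p.assignment.core]
            condition = p.block_condition(block)
            if config.fidelity == "engine":
                log = _engine_block(
                    p, trained_words, condition, config, materials,
                    np.random.default_rng(int(train_rng.integers(2**31 - 1))),
                )
                block_logs[(p.id, block)] = log
            else:
                _aggregate_block(p, trained_words, condition, config)
            _assess(p, battery, f"T{3 + block}", rows)
        if config.include_followup:
            lrn.decay_familiarity(p.learner, config.schedule.followup_days)
            _assess(p, battery, "T6", rows, practice=False)

    results = pd.DataFrame(rows, columns=["participant", "timepoint", "wordlist", "item", "score", "rt_ms"])
    allocation = pd.DataFrame(
        {
            "participant": [p.id for p in participants],
            "group": [p.group for p in participants],
            "baseline_accuracy_pct": [p.baseline_accuracy_pct for p in participants],
            "baseline_rt_ms": [p.baseline_rt_ms for p in participants],
            "counterbalance_index": [p.assignment.counterbalance_index for p in participants],
        }
    )
    return CrossoverResult(
        results=results,
        allocation=allocation,
        participants=participants,
        block_logs=block_logs,
        schedule=config.schedule,
    )


# ---------------------------------------------------------------------------
# analyses over trial results


def accuracy_by_cell(results: pd.DataFrame) -> pd.DataFrame:
    """Per participant x timepoint x wordlist accuracy (%) and mean RT."""
    def agg(g):
        rts = g["rt_ms"].dropna()
        return pd.Series(
            {"accuracy_pct": 100 * g["score"].mean(), "rt_ms": rts.mean() if len(rts) else np.nan}
        )
    return (
        results.groupby(["participant", "timepoint", "wordlist"])  # noqa: PD010
        .apply(agg, include_groups=False)
        .reset_index()
    )


def change_scores(results: pd.DataFrame, measure: str = "accuracy_pct") -> pd.DataFrame:
    """Per-participant change in each block: block 1 = T4 - T3, block 2 =
    T5 - T4, for the three matched word lists."""
    cells = accuracy_by_cell(results)
    wide = cells.pivot_table(index=["participant", "wordlist"], columns="timepoint", values=measure)
    out_rows = []
    for (pid, wl), row in wide.iterrows():
        if wl not in stm.ROLES:
            continue
        out_rows.append((pid, wl, 1, row["T4"] - row["T3"]))
        out_rows.append((pid, wl, 2, row["T5"] - row["T4"]))
    return pd.DataFrame(out_rows, columns=["participant", "wordlist", "block", "change"])


def therapy_anova(results: pd.DataFrame, allocation: pd.DataFrame, measure: str = "accuracy_pct") -> out.AnovaResult:
    """The Therapy analysis: repeated-measures ANOVA on block-wise change
    scores with within factors Block and Word list and between factor tDCS
    group."""
    ch = change_scores(results, measure=measure)
    ch = ch.merge(allocation[["participant", "group"]], on="participant")
    return out.mixed_anova(ch, dv="change", subject="participant", within=["block", "wordlist"], between="group")


def effect_size_table(results: pd.DataFrame) -> pd.DataFrame:
    """Table of unstandardized and standardized effect sizes for the primary
    outcomes, shaped like the trial report's effect-size table."""
    rows = []
    for measure, col in (("accuracy", "accuracy_pct"), ("rt", "rt_ms")):
        ch = change_scores(results, measure=col)
        cells = accuracy_by_cell(results)
        core = cells[cells.wordlist == "core"].pivot_table(index="participant", columns="timepoint", values=col)

        def add(label, interval, values):
            values = np.asarray(values, float)
            values = values[np.isfinite(values)]
            if values.size < 2 or values.std(ddof=1) == 0:
                return
            es = out.effect_size(values)
            rows.append((measure, label, interval, es.mean_change, es.ci_low, es.ci_high, es.cohens_d, es.n))

        b1 = ch[(ch.wordlist == "trained_block1") & (ch.block == 1)]["change"]
        b2 = ch[(ch.wordlist == "trained_block2") & (ch.block == 2)]["change"]
        u1 = ch[(ch.wordlist == "untrained") & (ch.block == 1)]["change"]
        u2 = ch[(ch.wordlist == "untrained") & (ch.block == 2)]["change"]
        add("trained_block1", "T4-T3", b1)
        add("untrained", "T4-T3", u1)
        add("trained_block2", "T5-T4", b2)
        add("untrained", "T5-T4", u2)
        both = (b1.to_numpy() + b2.to_numpy()) / 2.0
        add("trained_both", "after-before", both)
        add("core", "T4-T3", core["T4"] - core["T3"])
        add("core", "T5-T4", core["T5"] - core["T4"])
        add("core", "T5-T3", core["T5"] - core["T3"])
    return pd.DataFrame(
        rows, columns=["measure", "wordlist", "interval", "mean", "ci_low", "ci_high", "d", "n"]
    )


def tdcs_contrast(results: pd.DataFrame, allocation: pd.DataFrame) -> out.EffectSize:
    """Per-participant anodal-minus-sham trained-word accuracy gain (the
    stimulation facilitation), averaged over word lists, as an effect size."""
    ch = change_scores(results)
    ch = ch.merge(allocation[["participant", "group"]], on="participant")
    trained = ch[
        ((ch.wordlist == "trained_block1") & (ch.block == 1))
        | ((ch.wordlist == "trained_block2") & (ch.block == 2))
    ].copy()
    trained["condition"] = np.where(
        ((trained.group == 1) & (trained.block == 1)) | ((trained.group == 2) & (trained.block == 2)),
        "anodal",
        "sham",
    )
    wide = trained.pivot_table(index="participant", columns="condition", values="change")
    diff = (wide["anodal"] - wide["sham"]).dropna()
    return out.effect_size(diff.to_numpy())


# ---------------------------------------------------------------------------
# Monte-Carlo design studies


def _mc_config(config: TrialConfig | None) -> TrialConfig:
    cfg = config or TrialConfig(
        fidelity="aggregate", customize="first", include_followup=False
    )
    cfg.validate()
    return cfg


def null_interaction_rejection_rate(
    n_cohorts: int,
    seed: int = 0,
    alpha: float = 0.05,
    config: TrialConfig | None = None,
    materials: StudyMaterials | None = None,
) -> float:
    """Type-I-error study of the Therapy analysis.

    Simulates cohorts with the stimulation multiplier forced to 1 (no anodal
    effect of any kind) and returns the fraction in which the Block x tDCS
    group interaction is rejected at ``alpha``.  Stimulus materials are built
    once and shared; cohorts are independent.
    """
    cfg = _mc_config(config)
    cfg.learner = replace(cfg.learner, tdcs_multiplier=1.0, generalization_rate=0.0)
    rng = np.random.default_rng(seed)
    if materials is None:
        materials = build_study_materials(cfg, int(rng.integers(2**31 - 1)))
    hits = 0
    for _ in range(n_cohorts):
        res = run_crossover_trial(cfg, seed=int(rng.integers(2**31 - 1)), materials=materials)
        anova = therapy_anova(res.results, res.allocation)
        if float(anova.effect("block:group")["p"]) < alpha:
            hits += 1
    return hits / n_cohorts


def tdcs_superiority_rate(
    n_cohorts: int,
    seed: int = 0,
    multiplier: float | None = None,
    config: TrialConfig | None = None,
    materials: StudyMaterials | None = None,
) -> float:
    """Fraction of simulated cohorts whose mean trained-word gain is larger
    under anodal than under sham stimulation (a directionality check of the
    stimulation mechanism)."""
    cfg = _mc_config(config)
    if multiplier is not None:
        cfg.learner = replace(cfg.learner, tdcs_multiplier=multiplier)
    if cfg.learner.tdcs_multiplier <= 1.0:
        raise ValueError("superiority study needs a stimulation multiplier > 1")
    rng = np.random.default_rng(seed)
    if materials is None:
        materials = build_study_materials(cfg, int(rng.integers(2**31 - 1)))
    hits = 0
    for _ in range(n_cohorts):
        res = run_crossover_trial(cfg, seed=int(rng.integers(2**31 - 1)), materials=materials)
        if tdcs_contrast(res.results, res.allocation).mean_change > 0:
            hits += 1
    return hits / n_cohorts
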