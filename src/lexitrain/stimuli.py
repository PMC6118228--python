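"""Matched stimulus-list construction and distractor banks.

Builds three psycholinguistically matched word lists (A/B/C) plus a separate
high-frequency "core" list; customizes the lists per patient so that they are
also matched on that patient's baseline reading accuracy and speed; selects
testing subsets whose expected accuracy matches the baseline corpus (a guard
against regression to the mean); and constructs easy/medium/hard distractor
tiers for the same/different training task.

Matching strategy: words are stratified by (length, syllable count) so those
two covariates match exactly within a triplet; frequency (log scale) and
imageability are z-scored and matched greedily by nearest neighbour, followed
by swap-based local search.  Baseline-performance selection uses seeded
simulated annealing.  All randomness flows through explicit seeds.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .lexicon import CONSONANTS, VOWELS, Lexicon, WordEntry

__all__ = [
    "MatchedTriplet",
    "WordListSet",
    "PatientListAssignment",
    "DistractorSet",
    "MatchingError",
    "LIST_LABELS",
    "ROLES",
    "select_core_words",
    "build_matched_triplets",
    "customize_patient_lists",
    "select_testing_subsets",
    "shared_letter_count",
    "build_distractor_set",
    "triplet_cost",
    "list_balance_report",
]

LIST_LABELS = ("A", "B", "C")
ROLES = ("trained_block1", "trained_block2", "untrained")


class MatchingError(RuntimeError):
    """Raised when the candidate pool cannot support the requested lists."""


@dataclass(frozen=True)
class MatchedTriplet:
    """Three words matched exactly on length and syllables, closely on
    frequency and imageability."""

    a: WordEntry
    b: WordEntry
    c: WordEntry

    def __post_init__(self) -> None:
        words = (self.a, self.b, self.c)
        if len({len(w.orth) for w in words}) != 1:
            raise ValueError(f"triplet letter lengths differ: {[w.orth for w in words]}")
        if len({w.syllables for w in words}) != 1:
            raise ValueError(f"triplet syllable counts differ: {[w.orth for w in words]}")

    def members(self) -> tuple[WordEntry, WordEntry, WordEntry]:
        return (self.a, self.b, self.c)


@dataclass
class WordListSet:
    """The A/B/C matched lists (triplet projections) plus the core list."""

    triplets: list[MatchedTriplet]
    core: list[WordEntry]

    @property
    def listA(self) -> list[WordEntry]:
        return [t.a for t in self.triplets]

    @property
    def listB(self) -> list[WordEntry]:
        return [t.b for t in self.triplets]

    @property
    def listC(self) -> list[WordEntry]:
        return [t.c for t in self.triplets]

    def list_for(self, label: str) -> list[WordEntry]:
        return {"A": self.listA, "B": self.listB, "C": self.listC}[label]

    def all_words(self) -> list[WordEntry]:
        out = []
        for t in self.triplets:
            out.extend(t.members())
        out.extend(self.core)
        return out

    def validate_disjoint(self) -> None:
        sets = [set(w.orth for w in self.list_for(l)) for l in LIST_LABELS]
        sets.append({w.orth for w in self.core})
        union = set().union(*sets)
        if len(union) != sum(len(s) for s in sets):
            raise ValueError("A/B/C/core lists are not mutually disjoint")


@dataclass
class PatientListAssignment:
    """Per-patient customized 150-item lists, testing subsets and role map."""

    listset: WordListSet
    triplet_indices: list[int]  # 150 indices into listset.triplets
    permutations: list[tuple[int, int, int]]  # per triplet: column (A,B,C) -> member index
    counterbalance_index: int = 0
    roles: dict[str, str] = field(default_factory=dict)  # list label -> role
    test_triplet_positions: list[int] | None = None  # 90 positions into triplet_indices
    test_core: list[WordEntry] | None = None
    non_conforming: bool = False
    diagnostics: str = ""

    def sublist(self, label: str) -> list[WordEntry]:
        """The customized 150-item list carrying the given label."""
        col = LIST_LABELS.index(label)
        out = []
        for idx, perm in zip(self.triplet_indices, self.permutations):
            members = self.listset.triplets[idx].members()
            out.append(members[perm[col]])
        return out

    def _role_label(self, role: str) -> str:
        inv = {r: l for l, r in self.roles.items()}
        if role not in inv:
            raise ValueError(f"role {role!r} not assigned (roles: {self.roles})")
        return inv[role]

    @property
    def trained_block1(self) -> list[WordEntry]:
        return self.sublist(self._role_label("trained_block1"))

    @property
    def trained_block2(self) -> list[WordEntry]:
        return self.sublist(self._role_label("trained_block2"))

    @property
    def untrained(self) -> list[WordEntry]:
        return self.sublist(self._role_label("untrained"))

    @property
    def core(self) -> list[WordEntry]:
        return self.listset.core

    def test_sublist(self, label: str) -> list[WordEntry]:
        if self.test_triplet_positions is None:
            raise ValueError("testing subsets not yet selected")
        full = self.sublist(label)
        return [full[p] for p in self.test_triplet_positions]

    @property
    def test_block1(self) -> list[WordEntry]:
        return self.test_sublist(self._role_label("trained_block1"))

    @property
    def test_block2(self) -> list[WordEntry]:
        return self.test_sublist(self._role_label("trained_block2"))

    @property
    def test_untrained(self) -> list[WordEntry]:
        return self.test_sublist(self._role_label("untrained"))

    def battery(self) -> dict[str, list[WordEntry]]:
        """The personal 300-item testing battery, keyed by role."""
        if self.test_core is None:
            raise ValueError("testing subsets not yet selected")
        return {
            "trained_block1": self.test_block1,
            "trained_block2": self.test_block2,
            "untrained": self.test_untrained,
            "core": self.test_core,
        }


@dataclass
class DistractorSet:
    """Tiered written distractors for one target word."""

    target: WordEntry
    easy: list[str]
    medium: list[str]
    hard: list[str]

    def tier(self, name: str) -> list[str]:
        return {"easy": self.easy, "medium": self.medium, "hard": self.hard}[name]


# ---------------------------------------------------------------------------
# elementary operations


def shared_letter_count(a: str, b: str) -> int:
    """Number of positions at which two equal-length strings share a letter."""
    if len(a) != len(b):
        raise ValueError(f"strings differ in length: {a!r} vs {b!r}")
    return sum(x == y for x, y in zip(a, b))


def select_core_words(candidates: list[WordEntry], k: int = 50) -> list[WordEntry]:
    """The ``k`` highest-frequency candidates; frequency ties broken
    alphabetically so the selection is deterministic."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if len(candidates) < k:
        raise MatchingError(f"need at least {k} candidates for the core list, got {len(candidates)}")
    return sorted(candidates, key=lambda e: (-e.frequency, e.orth))[:k]


# ---------------------------------------------------------------------------
# triplet matching


def _zscores(pool: list[WordEntry]) -> dict[str, tuple[float, float]]:
    logf = np.log([e.frequency for e in pool])
    imag = np.array([e.imageability for e in pool])
    zf = (logf - logf.mean()) / (logf.std() or 1.0)
    zi = (imag - imag.mean()) / (imag.std() or 1.0)
    return {e.orth: (float(f), float(i)) for e, f, i in zip(pool, zf, zi)}


def triplet_cost(words, z: dict[str, tuple[float, float]]) -> float:
    """Sum of pairwise Euclidean distances in (z log-frequency, z imageability)."""
    pts = [np.array(z[w.orth]) for w in words]
    return float(
        np.linalg.norm(pts[0] - pts[1])
        + np.linalg.norm(pts[0] - pts[2])
        + np.linalg.norm(pts[1] - pts[2])
    )


def _form_stratum_triplets(words, z, rng) -> list[list[WordEntry]]:
    """Greedy nearest-neighbour triplet formation within one stratum."""
    remaining = list(words)
    triplets = []
    while len(remaining) >= 3:
        pts = np.array([z[w.orth] for w in remaining])
        centroid = pts.mean(axis=0)
        seed_i = int(np.argmax(np.linalg.norm(pts - centroid, axis=1)))
        d = np.linalg.norm(pts - pts[seed_i], axis=1)
        d[seed_i] = np.inf
        nn = np.argsort(d)[:2]
        trip = [remaining[seed_i]] + [remaining[int(j)] for j in nn]
        for w in trip:
            remaining.remove(w)
        triplets.append(trip)
    return triplets


def build_matched_triplets(
    candidates: list[WordEntry],
    n_triplets: int = 180,
    tolerances: dict | None = None,
    seed: int = 0,
    core_k: int = 50,
    n_refine: int = 1000,
) -> WordListSet:
    """Build the core list and ``n_triplets`` matched triplets, assigning
    members to lists A/B/C so that list-level means stay balanced.

    Raises :class:`MatchingError` (reporting the achievable count) when the
    pool cannot supply ``n_triplets`` after core removal.
    """
    tol = {"smd": 0.1}
    if tolerances:
        tol.update(tolerances)
    rng = np.random.default_rng(seed)

    core = select_core_words(candidates, core_k)
    core_orths = {w.orth for w in core}
    pool = [e for e in candidates if e.orth not in core_orths]

    strata: dict[tuple[int, int], list[WordEntry]] = {}
    for e in pool:
        strata.setdefault((len(e.orth), e.syllables), []).append(e)
    achievable = sum(len(v) // 3 for v in strata.values())
    if achievable < n_triplets:
        raise MatchingError(
            f"pool of {len(pool)} candidates supports only {achievable} matched "
            f"triplets; {n_triplets} requested"
        )

    z = _zscores(pool)
    # scarcest strata first so rare length x syllable combinations are not
    # consumed as filler
    all_trips: list[list[WordEntry]] = []
    for key in sorted(strata, key=lambda k: (len(strata[k]), k)):
        members = sorted(strata[key], key=lambda e: e.orth)
        all_trips.extend(_form_stratum_triplets(members, z, rng))

    all_trips.sort(key=lambda t: triplet_cost(t, z))
    kept = all_trips[:n_triplets]
    spare = all_trips[n_triplets:]

    # swap-based local search: exchange members between kept triplets of the
    # same stratum, or swap a whole kept triplet for a spare one
    def stratum_of(t):
        return (len(t[0].orth), t[0].syllables)

    for _ in range(n_refine):
        if rng.random() < 0.8 and len(kept) >= 2:
            i, j = rng.integers(0, len(kept), size=2)
            if i == j or stratum_of(kept[i]) != stratum_of(kept[j]):
                continue
            mi, mj = int(rng.integers(3)), int(rng.integers(3))
            old = triplet_cost(kept[i], z) + triplet_cost(kept[j], z)
            a, b = list(kept[i]), list(kept[j])
            a[mi], b[mj] = b[mj], a[mi]
            if triplet_cost(a, z) + triplet_cost(b, z) < old:
                kept[int(i)], kept[int(j)] = a, b
        elif spare:
            i = int(rng.integers(len(kept)))
            s = int(rng.integers(len(spare)))
            if triplet_cost(spare[s], z) < triplet_cost(kept[i], z):
                kept[i], spare[s] = spare[s], kept[i]

    # assign members to lists A/B/C, greedily keeping running list sums of the
    # z-covariates balanced
    perms = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
    sums = np.zeros((3, 2))
    triplets: list[MatchedTriplet] = []
    order = rng.permutation(len(kept))
    assigned: list[tuple[list[WordEntry], tuple[int, int, int]]] = []
    for idx in order:
        trip = kept[int(idx)]
        pts = [np.array(z[w.orth]) for w in trip]
        best, best_cost = None, np.inf
        for p in perms:
            trial = sums.copy()
            for m, col in enumerate(p):
                trial[col] += pts[m]
            cost = float(((trial - trial.mean(axis=0)) ** 2).sum())
            if cost < best_cost:
                best, best_cost = p, cost
        for m, col in enumerate(best):
            sums[col] += pts[m]
        assigned.append((trip, best))
    # restore deterministic order (by stratum then first orth)
    assigned.sort(key=lambda tp: (len(tp[0][0].orth), tp[0][0].syllables, tp[0][0].orth))
    for trip, p in assigned:
        ordered = [None, None, None]
        for m, col in enumerate(p):
            ordered[col] = trip[m]
        triplets.append(MatchedTriplet(a=ordered[0], b=ordered[1], c=ordered[2]))

    listset = WordListSet(triplets=triplets, core=core)
    listset.validate_disjoint()
    return listset


def list_balance_report(listset: WordListSet) -> dict[str, float]:
    """Pairwise standardized mean differences of frequency and imageability
    across lists A/B/C (max over pairs, pooled-SD denominator)."""
    out = {}
    for attr in ("frequency", "imageability"):
        vals = [np.array([getattr(w, attr) for w in listset.list_for(l)]) for l in LIST_LABELS]
        pooled = np.sqrt(np.mean([v.var(ddof=1) for v in vals]))
        smds = [
            abs(vals[i].mean() - vals[j].mean()) / pooled
            for i in range(3)
            for j in range(i + 1, 3)
        ]
        out[attr] = float(max(smds))
    return out


# ---------------------------------------------------------------------------
# baseline-performance customization


def _baseline_arrays(words: list[WordEntry], baseline) -> tuple[np.ndarray, np.ndarray]:
    acc, rt = [], []
    for w in words:
        if w.orth not in baseline:
            raise KeyError(f"baseline missing item {w.orth!r}")
        a, r = baseline[w.orth]
        acc.append(a)
        rt.append(r if r is not None else np.nan)
    return np.array(acc, float), np.array(rt, float)


def _selection_cost(acc_by_list, rt_by_list, acc_tol_pp, rt_tol_ms) -> tuple[float, float, float]:
    acc_means = [100 * a.mean() for a in acc_by_list]
    with np.errstate(invalid="ignore"):
        rt_means = [np.nanmean(r) if np.any(~np.isnan(r)) else 0.0 for r in rt_by_list]
    acc_gap = max(
        abs(acc_means[i] - acc_means[j]) for i in range(3) for j in range(i + 1, 3)
    )
    rt_gap = max(abs(rt_means[i] - rt_means[j]) for i in range(3) for j in range(i + 1, 3))
    cost = (acc_gap / max(acc_tol_pp, 0.25)) ** 2 + (rt_gap / max(rt_tol_ms, 5.0)) ** 2
    return cost, acc_gap, rt_gap


def customize_patient_lists(
    listset: WordListSet,
    baseline,
    m: int = 150,
    seed: int = 0,
    acc_tol_pp: float = 2.0,
    rt_tol_ms: float = 50.0,
    max_iter: int = 4000,
) -> PatientListAssignment:
    """Select ``m`` whole triplets (and within-triplet list rotations) so the
    three customized lists match the patient's baseline accuracy and RT.

    ``baseline`` maps orth -> (score in [0,1], rt_ms or None) and must cover
    every word in the list set (540 list words + core).  If the tolerances are
    unreachable within ``max_iter`` annealing steps the best assignment found
    is returned with ``non_conforming=True`` and a diagnostic message.
    """
    n = len(listset.triplets)
    if m > n:
        raise MatchingError(f"cannot select {m} triplets from {n}")
    for w in listset.all_words():
        if w.orth not in baseline:
            raise KeyError(f"baseline missing item {w.orth!r}")

    rng = np.random.default_rng(seed)
    acc_all = np.empty((n, 3))
    rt_all = np.empty((n, 3))
    for i, t in enumerate(listset.triplets):
        acc_all[i], rt_all[i] = _baseline_arrays(list(t.members()), baseline)

    included = list(range(m))
    excluded = list(range(m, n))
    perms = [[0, 1, 2] for _ in range(n)]  # member index occupying columns A,B,C

    def lists_from_state():
        accs, rts = [], []
        for col in range(3):
            a = np.array([acc_all[i][perms[i][col]] for i in included])
            r = np.array([rt_all[i][perms[i][col]] for i in included])
            accs.append(a)
            rts.append(r)
        return accs, rts

    accs, rts = lists_from_state()
    cost, acc_gap, rt_gap = _selection_cost(accs, rts, acc_tol_pp, rt_tol_ms)
    best_state = (list(included), [list(p) for p in perms], cost, acc_gap, rt_gap)

    temp0 = max(cost, 1.0)
    for it in range(max_iter):
        temp = temp0 * (1.0 - it / max_iter) + 1e-3
        if excluded and rng.random() < 0.5:
            ii = int(rng.integers(len(included)))
            jj = int(rng.integers(len(excluded)))
            included[ii], excluded[jj] = excluded[jj], included[ii]
            undo = ("swap", ii, jj)
        else:
            ti = included[int(rng.integers(len(included)))]
            a, b = rng.choice(3, size=2, replace=False)
            perms[ti][a], perms[ti][b] = perms[ti][b], perms[ti][a]
            undo = ("perm", ti, int(a), int(b))
        accs, rts = lists_from_state()
        new_cost, new_acc_gap, new_rt_gap = _selection_cost(accs, rts, acc_tol_pp, rt_tol_ms)
        if new_cost <= cost or rng.random() < np.exp((cost - new_cost) / temp):
            cost, acc_gap, rt_gap = new_cost, new_acc_gap, new_rt_gap
            if cost < best_state[2]:
                best_state = (list(included), [list(p) for p in perms], cost, acc_gap, rt_gap)
            if acc_gap <= acc_tol_pp and rt_gap <= rt_tol_ms:
                break
        else:  # revert
            if undo[0] == "swap":
                _, ii, jj = undo
                included[ii], excluded[jj] = excluded[jj], included[ii]
            else:
                _, ti, a, b = undo
                perms[ti][a], perms[ti][b] = perms[ti][b], perms[ti][a]

    included, perms_all, cost, acc_gap, rt_gap = best_state
    ok = acc_gap <= acc_tol_pp and rt_gap <= rt_tol_ms
    assignment = PatientListAssignment(
        listset=listset,
        triplet_indices=sorted(included),
        permutations=[tuple(perms_all[i]) for i in sorted(included)],
        non_conforming=not ok,
        diagnostics=(
            ""
            if ok
            else f"tolerance unreachable: accuracy gap {acc_gap:.2f} pp "
            f"(tol {acc_tol_pp}), RT gap {rt_gap:.1f} ms (tol {rt_tol_ms})"
        ),
    )
    return assignment


def select_testing_subsets(
    assignment: PatientListAssignment,
    baseline,
    k: int = 90,
    core_k: int = 30,
    tol_pp: float = 2.0,
    seed: int = 0,
    max_iter: int = 4000,
) -> PatientListAssignment:
    """Select the 90-item testing subset of each customized list plus a core
    subset, matching each subset's mean baseline accuracy to the full-corpus
    mean (regression-to-the-mean guard)."""
    if len(assignment.triplet_indices) < k:
        raise MatchingError(f"cannot select {k} test triplets from {len(assignment.triplet_indices)}")
    if len(assignment.core) < core_k:
        raise MatchingError(f"cannot select {core_k} core test words from {len(assignment.core)}")
    rng = np.random.default_rng(seed)

    corpus_words = assignment.listset.all_words()
    corpus_acc, _ = _baseline_arrays(corpus_words, baseline)
    target = 100 * corpus_acc.mean()

    m = len(assignment.triplet_indices)
    acc_cols = np.empty((m, 3))
    for pos in range(m):
        idx = assignment.triplet_indices[pos]
        perm = assignment.permutations[pos]
        a, _ = _baseline_arrays(list(assignment.listset.triplets[idx].members()), baseline)
        acc_cols[pos] = a[list(perm)]

    core_acc, _ = _baseline_arrays(assignment.core, baseline)

    pos_included = list(range(k))
    pos_excluded = list(range(k, m))
    core_inc = list(range(core_k))
    core_exc = list(range(core_k, len(assignment.core)))

    def cost_of():
        means = [100 * acc_cols[pos_included, col].mean() for col in range(3)]
        cmean = 100 * core_acc[core_inc].mean()
        dev = sum((mu - target) ** 2 for mu in means) + (cmean - target) ** 2
        gap = max(abs(means[i] - means[j]) for i in range(3) for j in range(i + 1, 3))
        return dev + gap**2, max(abs(mu - target) for mu in means + [cmean]), gap

    cost, dev, gap = cost_of()
    best = (list(pos_included), list(core_inc), cost, dev, gap)
    temp0 = max(cost, 1.0)
    for it in range(max_iter):
        temp = temp0 * (1.0 - it / max_iter) + 1e-3
        if core_exc and rng.random() < 0.25:
            ii = int(rng.integers(len(core_inc)))
            jj = int(rng.integers(len(core_exc)))
            core_inc[ii], core_exc[jj] = core_exc[jj], core_inc[ii]
            undo = ("core", ii, jj)
        elif pos_excluded:
            ii = int(rng.integers(len(pos_included)))
            jj = int(rng.integers(len(pos_excluded)))
            pos_included[ii], pos_excluded[jj] = pos_excluded[jj], pos_included[ii]
            undo = ("trip", ii, jj)
        else:
            continue
        new_cost, new_dev, new_gap = cost_of()
        if new_cost <= cost or rng.random() < np.exp((cost - new_cost) / temp):
            cost, dev, gap = new_cost, new_dev, new_gap
            if cost < best[2]:
                best = (list(pos_included), list(core_inc), cost, dev, gap)
            if dev <= tol_pp and gap <= tol_pp:
                break
        else:
            if undo[0] == "core":
                _, ii, jj = undo
                core_inc[ii], core_exc[jj] = core_exc[jj], core_inc[ii]
            else:
                _, ii, jj = undo
                pos_included[ii], pos_excluded[jj] = pos_excluded[jj], pos_included[ii]

    pos_included, core_inc, cost, dev, gap = best
    ok = dev <= tol_pp and gap <= tol_pp
    assignment.test_triplet_positions = sorted(pos_included)
    assignment.test_core = [assignment.core[i] for i in sorted(core_inc)]
    if not ok:
        assignment.non_conforming = True
        assignment.diagnostics = (
            assignment.diagnostics
            + f" testing-subset tolerance unreachable: max deviation from corpus mean "
            f"{dev:.2f} pp, pairwise gap {gap:.2f} pp (tol {tol_pp})"
        ).strip()
    return assignment


# ---------------------------------------------------------------------------
# distractors


def _tier_of(shared: int, length: int) -> str | None:
    if shared == 1:
        return "easy"
    if shared == length - 1:
        return "hard"
    if 1 < shared < length - 1:
        return "medium"
    return None


def _synth_distractor(target: str, shared: int, rng: np.random.Generator, avoid: set[str]) -> str:
    """Synthesize a pseudoword sharing exactly ``shared`` positional letters
    (always including the first) with the target."""
    length = len(target)
    for _ in range(500):
        keep = {0}
        if shared > 1:
            extra = rng.choice(np.arange(1, length), size=shared - 1, replace=False)
            keep.update(int(i) for i in extra)
        chars = []
        for i, ch in enumerate(target):
            if i in keep:
                chars.append(ch)
            else:
                pool = VOWELS if ch in VOWELS else CONSONANTS
                alt = ch
                while alt == ch:
                    alt = pool[int(rng.integers(len(pool)))]
                chars.append(alt)
        cand = "".join(chars)
        if cand != target and cand not in avoid:
            return cand
    raise MatchingError(f"could not synthesize a distractor for target {target!r}")


def build_distractor_set(target: WordEntry | str, lexicon: Lexicon, max_per_tier: int = 8) -> DistractorSet:
    """Build easy/medium/hard distractor tiers for one target.

    All distractors share the target's length and first letter; tiers are
    ordered by the number of positionally shared letters (easy = first letter
    only; hard = all but one; medium in between, counts nearest to half the
    word length preferred).  Tiers with no real-word candidate are filled with
    synthesized pseudowords having the required positional overlap, so every
    target is trainable.  Deterministic: the fallback stream is seeded from
    the target's orthography.
    """
    if isinstance(target, str):
        target = lexicon[target] if target in lexicon else WordEntry(
            orth=target, frequency=1.0, imageability=4.0, syllables=1, regularity="regular"
        )
    orth = target.orth
    length = len(orth)
    tiers: dict[str, list[tuple[int, str]]] = {"easy": [], "medium": [], "hard": []}
    for cand in lexicon:
        if cand.orth == orth or len(cand.orth) != length or cand.orth[0] != orth[0]:
            continue
        shared = shared_letter_count(orth, cand.orth)
        tier = _tier_of(shared, length)
        if tier:
            tiers[tier].append((shared, cand.orth))

    mid = int(np.ceil(length / 2))
    tiers["medium"].sort(key=lambda sw: (abs(sw[0] - mid), sw[1]))
    tiers["easy"].sort(key=lambda sw: sw[1])
    tiers["hard"].sort(key=lambda sw: sw[1])

    rng = np.random.default_rng(zlib.crc32(orth.encode()) & 0x7FFFFFFF)
    avoid = set(lexicon.orths())
    out: dict[str, list[str]] = {}
    # three-letter words admit no count strictly between 1 and L-1; their
    # medium tier degenerates to the hard count
    required = {"easy": 1, "medium": mid if 1 < mid < length - 1 else length - 1, "hard": length - 1}
    for name in ("easy", "medium", "hard"):
        words = [w for _, w in tiers[name][:max_per_tier]]
        if not words and name == "medium" and length == 3:
            words = [w for _, w in tiers["hard"][:max_per_tier]]
        if not words:
            try:
                words = sorted({_synth_distractor(orth, required[name], rng, avoid) for _ in range(3)})
            except MatchingError:
                raise MatchingError(f"no distractor possible for target {orth!r} at tier {name}")
        out[name] = words

    return DistractorSet(target=target, easy=out["easy"], medium=out["medium"], hard=out["hard"])
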