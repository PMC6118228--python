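"""Synthetic SUBTLEX-like lexicon generation, filtering, pseudowords, and TSV persistence.

The lexicon emulates the statistical shape of a film-subtitle frequency corpus:
per-million word frequencies with a Zipfian (power-law) tail, 3-6 letter words,
graded 1-7 imageability ratings drawn from a two-component mixture, and a
high-frequency closed-class ("function word") stratum concentrated at the top
of the frequency distribution.  Nothing here ingests real corpus data; every
entry is generated from a seeded random stream so that stimulus construction,
training simulation and analysis are fully reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "WordEntry",
    "Lexicon",
    "LexiconConfig",
    "CapacityError",
    "LexiconFormatError",
    "generate_lexicon",
    "filter_training_candidates",
    "generate_pseudowords",
    "read_lexicon",
    "write_lexicon",
    "count_syllables",
    "strip_morphological_variants",
]

VOWELS = "aeiou"
CONSONANTS = "bcdfghjklmnpqrstvwyz"  # x left out: rare onset, keeps strings plausible
MIN_LEN, MAX_LEN = 3, 6

#: suffixes treated as regular morphological variants of a base form
VARIANT_SUFFIXES = ("ing", "es", "ed", "en", "s")

REGULARITY_VALUES = ("regular", "irregular")


class CapacityError(RuntimeError):
    """Raised when more unique strings are requested than can be generated."""


class LexiconFormatError(ValueError):
    """Raised on malformed lexicon TSV input; message names the offending row."""


@dataclass(frozen=True)
class WordEntry:
    """A single lexical item with its psycholinguistic covariates."""

    orth: str
    frequency: float  # occurrences per million
    imageability: float  # 1-7 rating scale
    syllables: int
    regularity: str  # "regular" | "irregular"
    is_function_word: bool = False

    def __post_init__(self) -> None:
        if not (MIN_LEN <= len(self.orth) <= MAX_LEN):
            raise ValueError(f"orth {self.orth!r}: length must be in [{MIN_LEN},{MAX_LEN}]")
        if not self.orth.islower() or not self.orth.isalpha():
            raise ValueError(f"orth {self.orth!r}: must be lowercase letters only")
        if self.frequency <= 0:
            raise ValueError(f"orth {self.orth!r}: frequency must be > 0")
        if not (1.0 <= self.imageability <= 7.0):
            raise ValueError(f"orth {self.orth!r}: imageability must be in [1,7]")
        if self.syllables < 1:
            raise ValueError(f"orth {self.orth!r}: syllables must be >= 1")
        if self.regularity not in REGULARITY_VALUES:
            raise ValueError(f"orth {self.orth!r}: regularity must be one of {REGULARITY_VALUES}")


@dataclass
class Lexicon:
    """Ordered, duplicate-free collection of :class:`WordEntry`."""

    entries: list[WordEntry]
    seed: int = 0

    def __post_init__(self) -> None:
        orths = [e.orth for e in self.entries]
        if len(set(orths)) != len(orths):
            dupes = sorted({o for o in orths if orths.count(o) > 1})
            raise ValueError(f"duplicate orthographies in lexicon: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, orth: str) -> WordEntry:
        return self._index()[orth]

    def __contains__(self, orth: str) -> bool:
        return orth in self._index()

    def _index(self) -> dict[str, WordEntry]:
        idx = getattr(self, "_idx", None)
        if idx is None or len(idx) != len(self.entries):
            idx = {e.orth: e for e in self.entries}
            object.__setattr__(self, "_idx", idx)
        return idx

    def orths(self) -> list[str]:
        return [e.orth for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "orth": [e.orth for e in self.entries],
                "frequency": [e.frequency for e in self.entries],
                "imageability": [e.imageability for e in self.entries],
                "syllables": [e.syllables for e in self.entries],
                "regularity": [e.regularity for e in self.entries],
                "is_function_word": [e.is_function_word for e in self.entries],
            }
        )

    def bigrams(self) -> set[str]:
        """Set of all adjacent letter pairs attested in the lexicon."""
        out: set[str] = set()
        for e in self.entries:
            out.update(e.orth[i : i + 2] for i in range(len(e.orth) - 1))
        return out


@dataclass(frozen=True)
class LexiconConfig:
    """Distribution settings for :func:`generate_lexicon`.

    zipf_tail_exponent
        Pareto tail index ``alpha`` of the per-million frequency distribution
        (survival function ~ f**-alpha).  SUBTLEX-like corpora have a heavy
        tail; the default 1.1 gives a realistic dynamic range.
    min_frequency
        Lower truncation point (per million) of the frequency distribution.
    function_word_fraction
        Fraction of entries flagged as closed-class words.  Flags are given to
        the highest-frequency entries, mirroring the dominance of functors at
        the top of real frequency lists.
    imageability mixture
        Function words draw from a low normal component, content words from a
        broad high component; both clipped to the 1-7 rating scale.  This
        supports downstream analyses that split words at the 40th
        imageability percentile.
    """

    zipf_tail_exponent: float = 1.1
    min_frequency: float = 1.0
    function_word_fraction: float = 0.05
    imageability_function_mean: float = 2.0
    imageability_function_sd: float = 0.5
    imageability_content_mean: float = 4.5
    imageability_content_sd: float = 1.2
    p_regular: float = 0.75


def count_syllables(orth: str) -> int:
    """Syllable count of a synthetic word = number of vowel groups (min 1)."""
    groups = sum(
        1 for i, ch in enumerate(orth) if ch in VOWELS and (i == 0 or orth[i - 1] not in VOWELS)
    )
    return max(1, groups)


def _random_word(rng: np.random.Generator) -> str:
    """Draw a pronounceable-ish letter string of length 3-6.

    Words are built from alternating consonant/vowel chunks so that the bigram
    inventory resembles a natural orthography (needed for pseudoword
    generation, which samples attested bigrams).
    """
    length = int(rng.integers(MIN_LEN, MAX_LEN + 1))
    start_with_vowel = rng.random() < 0.25
    out: list[str] = []
    use_vowel = start_with_vowel
    while len(out) < length:
        pool = VOWELS if use_vowel else CONSONANTS
        n = 1
        if not use_vowel and rng.random() < 0.2 and len(out) + 2 <= length:
            n = 2  # occasional consonant cluster
        for _ in range(n):
            out.append(pool[int(rng.integers(len(pool)))])
        use_vowel = not use_vowel
    return "".join(out[:length])


def generate_lexicon(n: int, seed: int, config: LexiconConfig | None = None) -> Lexicon:
    """Generate ``n`` unique synthetic word entries from a seeded stream.

    Raises :class:`CapacityError` if ``n`` unique strings cannot be produced.
    Equal seeds produce byte-identical lexicons.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    # far below the raw string-count bound: the CV-pattern generator revisits
    # short strings heavily, so the practical unique-string yield is limited
    if n > 500_000:
        raise CapacityError(f"cannot generate {n} unique 3-6 letter strings")
    cfg = config or LexiconConfig()
    rng = np.random.default_rng(seed)

    seen: set[str] = set()
    orths: list[str] = []
    attempts = 0
    max_attempts = 200 * n + 10_000
    while len(orths) < n:
        if attempts >= max_attempts:
            raise CapacityError(
                f"could not generate {n} unique strings after {max_attempts} attempts "
                f"(got {len(orths)})"
            )
        attempts += 1
        w = _random_word(rng)
        if w in seen:
            continue
        seen.add(w)
        orths.append(w)

    # i.i.d. truncated-Pareto frequencies (per million), one draw per word
    alpha = cfg.zipf_tail_exponent
    u = rng.random(n)
    freqs = cfg.min_frequency * (1.0 - u) ** (-1.0 / alpha)

    # function-word stratum: highest-frequency entries
    n_fw = int(round(cfg.function_word_fraction * n))
    fw_flags = np.zeros(n, dtype=bool)
    if n_fw > 0:
        fw_flags[np.argsort(-freqs)[:n_fw]] = True

    imag = np.where(
        fw_flags,
        rng.normal(cfg.imageability_function_mean, cfg.imageability_function_sd, n),
        rng.normal(cfg.imageability_content_mean, cfg.imageability_content_sd, n),
    )
    imag = np.clip(imag, 1.0, 7.0)
    regular = rng.random(n) < cfg.p_regular

    entries = [
        WordEntry(
            orth=o,
            frequency=float(f),
            imageability=float(round(im, 3)),
            syllables=count_syllables(o),
            regularity="regular" if reg else "irregular",
            is_function_word=bool(fw),
        )
        for o, f, im, reg, fw in zip(orths, freqs, imag, regular, fw_flags)
    ]
    return Lexicon(entries=entries, seed=seed)


def _is_variant(base: str, longer: str) -> bool:
    """True if ``longer`` is a regular suffixed form of ``base``.

    Covers plain suffixation (eat/eaten), e-drop (bake/baking) and final
    consonant doubling (run/running).
    """
    for suf in VARIANT_SUFFIXES:
        if longer == base + suf:
            return True
        if base.endswith("e") and longer == base[:-1] + suf:
            return True
        if longer == base + base[-1] + suf:
            return True
    return False


def _variants(a: str, b: str) -> bool:
    if len(a) == len(b):
        return False
    short, long_ = (a, b) if len(a) < len(b) else (b, a)
    return _is_variant(short, long_)


def strip_morphological_variants(entries: list[WordEntry]) -> list[WordEntry]:
    """Keep at most one member of each regular morphological family.

    Entries are scanned in descending frequency (ties broken alphabetically);
    an entry is dropped if a retained entry is a suffixed variant of it or
    vice versa.
    """
    kept: list[WordEntry] = []
    for e in sorted(entries, key=lambda x: (-x.frequency, x.orth)):
        if any(_variants(e.orth, k.orth) for k in kept):
            continue
        kept.append(e)
    order = {e.orth: i for i, e in enumerate(entries)}
    kept.sort(key=lambda e: order[e.orth])
    return kept


def filter_training_candidates(lexicon: Lexicon, min_freq: float = 50.0) -> list[WordEntry]:
    """Apply the training-pool selection rules.

    Retains entries with per-million frequency strictly above ``min_freq``,
    3-6 letters, no hyphen/apostrophe characters, and at most one member of
    each regular morphological family.  An empty result is signalled with a
    warning, not an error.
    """
    if len(lexicon) == 0:
        raise ValueError("lexicon is empty")
    pool = [
        e
        for e in lexicon
        if e.frequency > min_freq
        and MIN_LEN <= len(e.orth) <= MAX_LEN
        and "-" not in e.orth
        and "'" not in e.orth
    ]
    pool = strip_morphological_variants(pool)
    if not pool:
        import warnings

        warnings.warn(f"no candidates above frequency threshold {min_freq}", stacklevel=2)
    return pool


def generate_pseudowords(lexicon: Lexicon, n: int = 20, seed: int = 0) -> list[str]:
    """Generate ``n`` pronounceable non-words with attested letter bigrams.

    Every adjacent letter pair of each pseudoword occurs in at least one real
    lexicon word, lengths are 3-6, and no pseudoword collides with a lexicon
    orthography.  Deterministic for a fixed (lexicon, seed).
    """
    if len(lexicon) < 10:
        raise ValueError("lexicon too small to estimate bigram statistics")
    # frequency-weighted bigram statistics keep the letter walk plausible
    bigram_counts: dict[str, int] = {}
    start_counts: dict[str, int] = {}
    for e in lexicon:
        start_counts[e.orth[:2]] = start_counts.get(e.orth[:2], 0) + 1
        for i in range(len(e.orth) - 1):
            bg = e.orth[i : i + 2]
            bigram_counts[bg] = bigram_counts.get(bg, 0) + 1
    continuations: dict[str, tuple[list[str], np.ndarray]] = {}
    for bg in sorted(bigram_counts):
        continuations.setdefault(bg[0], ([], []))[0].append(bg[1])
        continuations[bg[0]][1].append(bigram_counts[bg])
    continuations = {
        k: (letters, np.array(w, float) / sum(w)) for k, (letters, w) in continuations.items()
    }
    starts = sorted(start_counts)
    start_p = np.array([start_counts[s] for s in starts], float)
    start_p /= start_p.sum()
    real = set(lexicon.orths())
    rng = np.random.default_rng(seed)

    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 2000 * n + 10_000
    while len(out) < n:
        if attempts >= max_attempts:
            raise CapacityError(
                f"could not generate {n} pseudowords under bigram constraints (got {len(out)})"
            )
        attempts += 1
        length = int(rng.integers(MIN_LEN, MAX_LEN + 1))
        word = starts[int(rng.choice(len(starts), p=start_p))]
        ok = True
        while len(word) < length:
            nxt = continuations.get(word[-1])
            if nxt is None:
                ok = False
                break
            letters, p = nxt
            word += letters[int(rng.choice(len(letters), p=p))]
        if not ok or word in real or word in seen:
            continue
        seen.add(word)
        out.append(word)
    return out


_COLUMNS = ["orth", "frequency", "imageability", "syllables", "regularity", "is_function_word"]


def write_lexicon(lexicon: Lexicon, path) -> None:
    """Write a lexicon as UTF-8 TSV with the canonical header."""
    df = lexicon.to_frame()
    df["is_function_word"] = df["is_function_word"].map({True: "true", False: "false"})
    df.to_csv(path, sep="\t", index=False)


def read_lexicon(path, seed: int = 0) -> Lexicon:
    """Read a TSV lexicon, validating every row; errors name the row number."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise LexiconFormatError(f"{path}: empty lexicon file") from None
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise LexiconFormatError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise LexiconFormatError(f"{path}: lexicon has no entries")

    entries: list[WordEntry] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # row 1 is the header
        try:
            orth = row.orth
            if orth in seen:
                raise ValueError(f"duplicate orth {orth!r}")
            fw = row.is_function_word.strip().lower()
            if fw not in ("true", "false"):
                raise ValueError(f"is_function_word must be true/false, got {row.is_function_word!r}")
            entries.append(
                WordEntry(
                    orth=orth,
                    frequency=float(row.frequency),
                    imageability=float(row.imageability),
                    syllables=int(row.syllables),
                    regularity=row.regularity,
                    is_function_word=fw == "true",
                )
            )
            seen.add(orth)
        except ValueError as exc:
            raise LexiconFormatError(f"{path}: row {i}: {exc}") from None
    return Lexicon(entries=entries, seed=seed)
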