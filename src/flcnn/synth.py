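"""Seeded synthetic lexicon + corpus generator.

The generator emulates the statistical structure that makes lattice NER with
long entities hard: entity mentions are concatenations of lexicon words of
one entity type, the entity-length distribution has a tunable share of
"very long" entities (> 10 characters), and lexicon words also occur as
distractors outside entities and across entity boundaries, so the flat
lattice contains competing word spans.

Entities are flanked by type-specific cue characters (drawn from a CJK
block disjoint from the word alphabet).  The cues make the tagging task
solvable by a small model, which is what an end-to-end training check
needs; they are the main idealization relative to real clinical dialogue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import EntityMention, LabeledSentence

__all__ = ["SynthConfig", "generate_corpus", "train_test_split",
           "entity_length_distribution", "analytic_mean_entity_length"]

_ALPHABET_BASE = 0x4E00  # CJK unified ideographs: word/background characters
_CUE_BASE = 0x3400  # CJK extension A: entity cue characters

VERY_LONG_THRESHOLD = 10  # entities strictly longer than this are "very long"


@dataclass
class SynthConfig:
    """Knobs of the generator; defaults give a generic mixed-length corpus."""

    seed: int = 0
    n_sentences: int = 100
    n_entity_types: int = 3
    char_alphabet_size: int = 60
    lexicon_size: int = 120
    words_per_entity: tuple[int, int] = (1, 4)
    words_per_entity_weights: tuple[float, ...] | None = None
    word_length: tuple[int, int] = (2, 4)
    very_long_target: float = 0.05
    sentence_length: tuple[int, int] = (10, 30)
    entities_per_sentence: tuple[int, int] = (1, 3)
    distractor_rate: float = 0.3

    def __post_init__(self):
        for name in ("words_per_entity", "word_length", "sentence_length",
                     "entities_per_sentence"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if not (0.0 <= self.very_long_target <= 1.0):
            raise ValueError("very_long_target must be in [0, 1]")
        if self.word_length[0] < 2:
            raise ValueError("lexicon words must have at least 2 characters")
        max_len = self.words_per_entity[1] * self.word_length[1]
        if self.very_long_target > 0 and max_len <= VERY_LONG_THRESHOLD:
            raise ValueError(
                "infeasible very_long_target: maximum entity length "
                f"{max_len} cannot exceed {VERY_LONG_THRESHOLD}"
            )
        min_len = self.words_per_entity[0] * self.word_length[0]
        if self.very_long_target < 1 and min_len > VERY_LONG_THRESHOLD:
            raise ValueError(
                "infeasible very_long_target: minimum entity length "
                f"{min_len} already exceeds {VERY_LONG_THRESHOLD}"
            )
    @staticmethod
    def long_entity_benchmark(seed: int = 0, n_sentences: int = 2500) -> "SynthConfig":
        """Profile emulating a long-entity clinical-dialogue corpus: average
        entity length around 4.3 characters with ~5% very long entities."""
        return SynthConfig(
            seed=seed,
            n_sentences=n_sentences,
            n_entity_types=3,
            char_alphabet_size=60,
            lexicon_size=120,
            words_per_entity=(1, 3),
            words_per_entity_weights=(0.65, 0.30, 0.05),
            word_length=(2, 4),
            very_long_target=0.05,
            sentence_length=(12, 30),
            entities_per_sentence=(1, 3),
            distractor_rate=0.3,
        )

    def _word_count_pmf(self) -> np.ndarray:
        lo, hi = self.words_per_entity
        n = hi - lo + 1
        if self.words_per_entity_weights is not None:
            w = np.asarray(self.words_per_entity_weights, dtype=float)
            if len(w) != n or np.any(w < 0) or w.sum() == 0:
                raise ValueError("words_per_entity_weights must match the range")
            return w / w.sum()
        return np.full(n, 1.0 / n)


def entity_length_distribution(config: SynthConfig) -> dict[int, float]:
    """Exact pmf of generated entity lengths (characters).

    The sampler draws a word count and word lengths uniformly, then rejects
    into the short branch (<= 10 chars) or the very-long branch (> 10) so the
    very-long share equals ``very_long_target``.  This function convolves the
    same distributions and renormalizes each branch analytically.
    """
    lo_w, hi_w = config.word_length
    word_pmf = {l: 1.0 / (hi_w - lo_w + 1) for l in range(lo_w, hi_w + 1)}
    count_pmf = config._word_count_pmf()
    lo_n = config.words_per_entity[0]

    total: dict[int, float] = {}
    conv: dict[int, float] = {0: 1.0}
    order = 0
    for n_words, p_n in enumerate(count_pmf, start=lo_n):
        while order < n_words:
            nxt: dict[int, float] = {}
            for tot, p in conv.items():
                for l, q in word_pmf.items():
                    nxt[tot + l] = nxt.get(tot + l, 0.0) + p * q
            conv = nxt
            order += 1
        for tot, p in conv.items():
            total[tot] = total.get(tot, 0.0) + p_n * p

    short = {l: p for l, p in total.items() if l <= VERY_LONG_THRESHOLD}
    long_ = {l: p for l, p in total.items() if l > VERY_LONG_THRESHOLD}
    p_vl = config.very_long_target
    out: dict[int, float] = {}
    if short:
        z = sum(short.values())
        for l, p in short.items():
            out[l] = out.get(l, 0.0) + (1.0 - p_vl) * p / z
    if p_vl > 0:
        z = sum(long_.values())
        for l, p in long_.items():
            out[l] = out.get(l, 0.0) + p_vl * p / z
    return out


def analytic_mean_entity_length(config: SynthConfig) -> float:
    pmf = entity_length_distribution(config)
    return sum(l * p for l, p in pmf.items())


def _alphabet(config: SynthConfig) -> list[str]:
    return [chr(_ALPHABET_BASE + i) for i in range(config.char_alphabet_size)]


def _cues(config: SynthConfig) -> list[tuple[str, str]]:
    return [
        (chr(_CUE_BASE + 2 * t), chr(_CUE_BASE + 2 * t + 1))
        for t in range(config.n_entity_types)
    ]


def generate_corpus(
    config: SynthConfig,
) -> tuple[list[LabeledSentence], list[str]]:
    """Generate a labeled corpus and its lexicon, deterministically by seed.

    Returns ``(corpus, lexicon_words)``.  The lexicon contains the entity
    word pools (one per entity type), and boundary-crossing words formed
    from entity-word suffixes plus the closing cue character, which create
    lattice word spans straddling entity boundaries.
    """
    rng = np.random.default_rng(config.seed)
    alphabet = _alphabet(config)
    cues = _cues(config)

    # lexicon word pools per entity type
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < config.lexicon_size:
        ln = int(rng.integers(config.word_length[0], config.word_length[1] + 1))
        w = "".join(rng.choice(alphabet, size=ln))
        if w not in seen:
            seen.add(w)
            words.append(w)
    pools: list[list[str]] = [[] for _ in range(config.n_entity_types)]
    for i, w in enumerate(words):
        pools[i % config.n_entity_types].append(w)

    crossing = sorted(
        {
            w[-2:] + cues[t][1]
            for t in range(config.n_entity_types)
            for w in pools[t]
        }
        - seen
    )
    lexicon = sorted(words) + crossing

    count_pmf = config._word_count_pmf()
    counts = np.arange(config.words_per_entity[0], config.words_per_entity[1] + 1)

    def draw_entity(t: int) -> str:
        want_long = rng.random() < config.very_long_target
        for _ in range(10_000):
            n_words = int(rng.choice(counts, p=count_pmf))
            parts = [pools[t][int(rng.integers(len(pools[t])))] for _ in range(n_words)]
            surface = "".join(parts)
            if (len(surface) > VERY_LONG_THRESHOLD) == want_long:
                return surface
        raise RuntimeError("entity rejection sampling did not converge")

    def bg_run(lo: int = 1, hi: int = 4) -> str:
        n = int(rng.integers(lo, hi + 1))
        run = "".join(rng.choice(alphabet, size=n))
        if rng.random() < config.distractor_rate:
            run += words[int(rng.integers(len(words)))]
        return run

    corpus: list[LabeledSentence] = []
    types = [f"T{t}" for t in range(config.n_entity_types)]
    for _ in range(config.n_sentences):
        target = int(rng.integers(config.sentence_length[0], config.sentence_length[1] + 1))
        n_ent = int(
            rng.integers(config.entities_per_sentence[0], config.entities_per_sentence[1] + 1)
        )
        text = bg_run()
        mentions: list[EntityMention] = []
        for j in range(n_ent):
            t = int(rng.integers(config.n_entity_types))
            ent = draw_entity(t)
            open_c, close_c = cues[t]
            start = len(text) + 1  # after the opening cue
            text += open_c + ent + close_c
            mentions.append(EntityMention(types[t], start, start + len(ent) - 1))
            text += bg_run()
            if j + 1 < n_ent and len(text) > target:
                break
        while len(text) < config.sentence_length[0]:
            text += bg_run()
        corpus.append(LabeledSentence(text, mentions))
    return corpus, lexicon


def train_test_split(
    corpus: list[LabeledSentence], fractions: tuple[float, ...], seed: int
) -> tuple[list[LabeledSentence], ...]:
    """Seed-deterministic disjoint sentence-level partition.

    ``fractions`` must each lie in (0, 1) and sum to 1; sizes are assigned by
    rounding the cumulative fractions, so the parts are exhaustive.
    """
    fr = np.asarray(fractions, dtype=float)
    if np.any(fr <= 0) or np.any(fr >= 1):
        raise ValueError("each fraction must lie strictly between 0 and 1")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(corpus)
    order = np.random.default_rng(seed).permutation(n)
    bounds = np.rint(np.cumsum(fr) * n).astype(int)
    bounds[-1] = n
    parts = []
    start = 0
    for b in bounds:
        parts.append([corpus[i] for i in order[start:b]])
        start = b
    return tuple(parts)
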