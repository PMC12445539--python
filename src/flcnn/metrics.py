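"""Entity-level evaluation: precision/recall/F1, error typology, corpus stats.

Scores follow the strict convention used throughout the NER literature: a
predicted mention is correct only on an exact (type, start, end) match.
Percentages are on a 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus import EntityMention, LabeledSentence

__all__ = [
    "PRF",
    "ErrorBreakdown",
    "CorpusStats",
    "entity_prf",
    "tag_accuracy",
    "classify_errors",
    "corpus_stats",
    "length_stratified_prf",
]

ERROR_CATEGORIES = (
    "incorrect_entity_recognition",
    "entity_omission",
    "boundary_error",
    "entity_type_error",
)


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f1: float
    n_gold: int
    n_pred: int
    n_correct: int

    @staticmethod
    def from_counts(n_gold: int, n_pred: int, n_correct: int) -> "PRF":
        p = 100.0 * n_correct / n_pred if n_pred else 0.0
        r = 100.0 * n_correct / n_gold if n_gold else 0.0
        f1 = 2 * p * r / (p + r) if (p + r) else 0.0
        return PRF(p, r, f1, n_gold, n_pred, n_correct)


@dataclass
class ErrorBreakdown:
    """Counts and percentage shares of the four error categories."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in ERROR_CATEGORIES}
    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict[str, float]:
        """Share of each category among all categorized errors, in percent."""
        tot = self.total
        return {c: (100.0 * n / tot if tot else 0.0) for c, n in self.counts.items()}


@dataclass(frozen=True)
class CorpusStats:
    n_entities: int
    avg_entity_length: float
    tagged_char_ratio: float
    very_long_ratio: float
    n_chars: int


def _check_aligned(gold: list[LabeledSentence], pred) -> None:
    if len(gold) != len(pred):
        raise ValueError(f"corpus length mismatch: {len(gold)} vs {len(pred)}")


def _mentions(x) -> list[EntityMention]:
    return list(x.entities) if isinstance(x, LabeledSentence) else list(x)


def entity_prf(gold: list, pred: list) -> PRF:
    """Exact-match entity precision, recall and F1 over aligned corpora.

    ``gold`` and ``pred`` are parallel lists of sentences (or of mention
    lists).  F1 is the harmonic mean of precision and recall; empty
    denominators yield 0.
    """
    _check_aligned(gold, pred)
    n_gold = n_pred = n_correct = 0
    for g, p in zip(gold, pred):
        gset, pset = set(_mentions(g)), set(_mentions(p))
        n_gold += len(gset)
        n_pred += len(pset)
        n_correct += len(gset & pset)
    return PRF.from_counts(n_gold, n_pred, n_correct)


def tag_accuracy(gold: list[LabeledSentence], pred: list[LabeledSentence]) -> float:
    """Per-character tag accuracy in percent (the ACC column companion to F1)."""
    _check_aligned(gold, pred)
    hit = tot = 0
    for g, p in zip(gold, pred):
        for tg, tp in zip(g.tags(), p.tags()):
            hit += tg == tp
            tot += 1
    return 100.0 * hit / tot if tot else 0.0


def classify_errors(gold: list, pred: list) -> ErrorBreakdown:
    """Categorize mismatches into the four-way error typology.

    Exact matches are removed first.  Remaining mentions are assigned, in
    precedence order, at most one category each:

    1. ``entity_type_error`` — same boundary, different type (pair consumed);
    2. ``boundary_error`` — overlap with a same-type gold mention but a wrong
       boundary (pair consumed, greedy left-to-right);
    3. ``incorrect_entity_recognition`` — every remaining predicted mention;
    4. ``entity_omission`` — every remaining gold mention.
    """
    _check_aligned(gold, pred)
    out = ErrorBreakdown()
    for g, p in zip(gold, pred):
        gset, pset = set(_mentions(g)), set(_mentions(p))
        grem = sorted(gset - pset)
        prem = sorted(pset - gset)
        # type errors: same boundary, wrong type
        for pm in list(prem):
            hit = next(
                (gm for gm in grem if gm.start == pm.start and gm.end == pm.end), None
            )
            if hit is not None:
                out.counts["entity_type_error"] += 1
                grem.remove(hit)
                prem.remove(pm)
        # boundary errors: overlap, same type, wrong boundary
        for pm in list(prem):
            hit = next(
                (gm for gm in grem if gm.type == pm.type and gm.overlaps(pm)), None
            )
            if hit is not None:
                out.counts["boundary_error"] += 1
                grem.remove(hit)
                prem.remove(pm)
        out.counts["incorrect_entity_recognition"] += len(prem)
        out.counts["entity_omission"] += len(grem)
    return out


def corpus_stats(corpus: list[LabeledSentence], very_long_threshold: int = 10) -> CorpusStats:
    """Descriptive statistics: entity count, average length in characters,
    tagged-character ratio, and the share of very long entities
    (strictly more than ``very_long_threshold`` characters)."""
    if not corpus:
        raise ValueError("empty corpus")
    lengths = [m.length for s in corpus for m in s.entities]
    n_chars = sum(len(s.text) for s in corpus)
    n_tagged = sum(l for l in lengths)
    n = len(lengths)
    return CorpusStats(
        n_entities=n,
        avg_entity_length=(sum(lengths) / n if n else 0.0),
        tagged_char_ratio=(100.0 * n_tagged / n_chars if n_chars else 0.0),
        very_long_ratio=(
            100.0 * sum(l > very_long_threshold for l in lengths) / n if n else 0.0
        ),
        n_chars=n_chars,
    )


def length_stratified_prf(
    gold: list, pred: list, bins: list[tuple[int, float]]
) -> dict[tuple[int, float], PRF]:
    """Per-length-bin metrics: recall over gold mentions whose length falls in
    the bin, precision over predicted mentions in the bin.

    ``bins`` is a list of inclusive (lo, hi) character-length ranges; use
    ``float('inf')`` for an open upper end.
    """
    _check_aligned(gold, pred)
    out: dict[tuple[int, float], PRF] = {}
    for lo, hi in bins:
        n_gold = n_pred = c_gold = c_pred = 0
        for g, p in zip(gold, pred):
            gset, pset = set(_mentions(g)), set(_mentions(p))
            hits = gset & pset
            for gm in gset:
                if lo <= gm.length <= hi:
                    n_gold += 1
                    c_gold += gm in hits
            for pm in pset:
                if lo <= pm.length <= hi:
                    n_pred += 1
                    c_pred += pm in hits
        p_ = 100.0 * c_pred / n_pred if n_pred else 0.0
        r_ = 100.0 * c_gold / n_gold if n_gold else 0.0
        f1 = 2 * p_ * r_ / (p_ + r_) if (p_ + r_) else 0.0
        out[(lo, hi)] = PRF(p_, r_, f1, n_gold, n_pred, min(c_gold, c_pred))
    return out
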