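"""Lexicon matching and flat-lattice construction.

A Chinese sentence is represented as a *flat lattice*: one span per
character, plus one span per lexicon word matched anywhere in the sentence.
Each span records the character indices of its first (head) and last (tail)
character, which losslessly encodes the original character-word lattice
graph and supports relative-position geometry between any two spans.
"""

from __future__ import annotations

import enum
import logging
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "SpanKind",
    "Span",
    "FlatLattice",
    "RelativeDistances",
    "SpanRelation",
    "LexiconIndex",
    "build_lexicon",
    "load_lexicon",
    "build_flat_lattice",
    "relative_distances",
    "span_relation",
]


class SpanKind(enum.Enum):
    CHAR = "char"
    WORD = "word"


@dataclass(frozen=True, order=False)
class Span:
    """A character or matched lexicon word, with inclusive 0-based offsets."""

    surface: str
    head: int
    tail: int
    kind: SpanKind

    def __post_init__(self):
        if not (0 <= self.head <= self.tail):
            raise ValueError(f"invalid span offsets ({self.head}, {self.tail})")
        if self.kind is SpanKind.CHAR and (
            self.head != self.tail or len(self.surface) != 1
        ):
            raise ValueError("CHAR span must cover exactly one character")

    @property
    def length(self) -> int:
        return self.tail - self.head + 1

    def sort_key(self) -> tuple[int, int, int]:
        # chars precede words on (head, tail) ties
        return (self.head, self.tail, 0 if self.kind is SpanKind.CHAR else 1)


@dataclass(frozen=True)
class RelativeDistances:
    """The four signed head/tail distances between an ordered span pair."""

    dhh: int
    dht: int
    dth: int
    dtt: int

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.dhh, self.dht, self.dth, self.dtt)


class SpanRelation(enum.Enum):
    INTERSECTING = "intersecting"
    CONTAINING = "containing"
    SEPARATING = "separating"


@dataclass
class FlatLattice:
    """Ordered span sequence for one sentence.

    Invariants: exactly one CHAR span per sentence position; spans sorted by
    (head, tail, CHAR-before-WORD); no duplicate (head, tail, kind) triples.
    """

    sentence: str
    spans: list[Span] = field(default_factory=list)

    def __post_init__(self):
        self.spans = sorted(self.spans, key=Span.sort_key)
        char_heads = [s.head for s in self.spans if s.kind is SpanKind.CHAR]
        if char_heads != list(range(len(self.sentence))):
            raise ValueError("lattice must contain one CHAR span per position")
        keys = [(s.head, s.tail, s.kind) for s in self.spans]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate spans in lattice")

    def __len__(self) -> int:
        return len(self.spans)

    def __iter__(self) -> Iterator[Span]:
        return iter(self.spans)

    @property
    def n_chars(self) -> int:
        return len(self.sentence)

    def char_positions(self) -> list[int]:
        """Index of the CHAR span of each sentence position, in order."""
        out = [0] * len(self.sentence)
        for i, s in enumerate(self.spans):
            if s.kind is SpanKind.CHAR:
                out[s.head] = i
        return out

    def word_spans(self) -> list[Span]:
        return [s for s in self.spans if s.kind is SpanKind.WORD]


class LexiconIndex:
    """Prefix trie over lexicon words for left-anchored match enumeration."""

    def __init__(self, words: Iterable[str]):
        self._root: dict = {}
        self._size = 0
        seen: set[str] = set()
        for raw in words:
            word = unicodedata.normalize("NFC", raw.strip())
            if not word or word in seen:
                continue
            if len(word) < 2:
                logger.warning("dropping 1-character lexicon word %r", word)
                continue
            seen.add(word)
            node = self._root
            for ch in word:
                node = node.setdefault(ch, {})
            node[None] = word
            self._size += 1
        if self._size == 0:
            raise ValueError("empty lexicon")

    def __len__(self) -> int:
        return self._size

    def __contains__(self, word: str) -> bool:
        node = self._root
        for ch in word:
            node = node.get(ch)
            if node is None:
                return False
        return None in node

    def matches_at(self, sentence: str, start: int) -> list[str]:
        """All lexicon words that occur in ``sentence`` starting at ``start``."""
        out: list[str] = []
        node = self._root
        for pos in range(start, len(sentence)):
            node = node.get(sentence[pos])
            if node is None:
                break
            if None in node:
                out.append(node[None])
        return out

    def words(self) -> list[str]:
        out: list[str] = []
        stack = [self._root]
        while stack:
            node = stack.pop()
            for key, child in node.items():
                if key is None:
                    out.append(child)
                else:
                    stack.append(child)
        return sorted(out)


def build_lexicon(words: Iterable[str]) -> LexiconIndex:
    """Build a prefix-trie index; deduplicates, drops 1-character words."""
    return LexiconIndex(words)


def load_lexicon(path) -> LexiconIndex:
    """Read a UTF-8 lexicon file, one word per line; '#' lines are comments."""
    with open(path, encoding="utf-8") as fh:
        words = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    return build_lexicon(words)


def build_flat_lattice(sentence: str, lexicon: LexiconIndex | None) -> FlatLattice:
    """Flatten the character-word lattice of ``sentence`` into span order.

    Every lexicon match is kept (not only maximal ones): the lattice's
    purpose is to expose all segmentation alternatives to the encoder.
    """
    if not sentence:
        raise ValueError("empty sentence")
    sentence = unicodedata.normalize("NFC", sentence)
    spans = [Span(ch, i, i, SpanKind.CHAR) for i, ch in enumerate(sentence)]
    if lexicon is not None:
        for start in range(len(sentence)):
            for word in lexicon.matches_at(sentence, start):
                spans.append(
                    Span(word, start, start + len(word) - 1, SpanKind.WORD)
                )
    return FlatLattice(sentence, spans)


def relative_distances(a: Span, b: Span) -> RelativeDistances:
    """The four signed head/tail distances from span ``a`` to span ``b``."""
    return RelativeDistances(
        dhh=a.head - b.head,
        dht=a.head - b.tail,
        dth=a.tail - b.head,
        dtt=a.tail - b.tail,
    )


def span_relation(a: Span, b: Span) -> SpanRelation:
    """Classify an ordered span pair: separating, containing or intersecting.

    Equal intervals count as containing (mutual containment); partial
    overlap is intersecting.
    """
    if a.tail < b.head or b.tail < a.head:
        return SpanRelation.SEPARATING
    if (a.head <= b.head and b.tail <= a.tail) or (
        b.head <= a.head and a.tail <= b.tail
    ):
        return SpanRelation.CONTAINING
    return SpanRelation.INTERSECTING
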