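"""NER corpus I/O and tag-scheme conversion.

Supports CoNLL-style two-column files (character TAB tag, blank line between
sentences) and JSONL (one object per line with ``text`` and ``entities``).
Entity offsets are 0-based with **inclusive** end, matching the span
convention used by the lattice module.
"""

from __future__ import annotations

import json
import logging
import unicodedata
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

__all__ = [
    "EntityMention",
    "LabeledSentence",
    "tags_to_entities",
    "entities_to_tags",
    "read_conll",
    "write_conll",
    "read_jsonl",
    "write_jsonl",
]


@dataclass(frozen=True, order=True)
class EntityMention:
    """A typed mention: (type, start, end) with inclusive character offsets."""

    type: str
    start: int
    end: int

    def __post_init__(self):
        if not self.type:
            raise ValueError("entity type must be non-empty")
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid mention offsets ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "EntityMention") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class LabeledSentence:
    """A sentence with non-overlapping (flat) entity mentions."""

    text: str
    entities: list[EntityMention] = field(default_factory=list)

    def __post_init__(self):
        self.entities = sorted(self.entities, key=lambda m: (m.start, m.end, m.type))
        for m in self.entities:
            if m.end >= len(self.text):
                raise ValueError(f"mention {m} out of bounds for {self.text!r}")
        for a, b in zip(self.entities, self.entities[1:]):
            if a.overlaps(b):
                raise ValueError(f"overlapping mentions {a} and {b}")

    def tags(self, scheme: str = "bio") -> list[str]:
        return entities_to_tags(self, scheme=scheme)


def tags_to_entities(tags: list[str]) -> list[EntityMention]:
    """Decode a BIO (or BIOES) tag sequence into mentions.

    Orphan ``I-T`` tags (no preceding ``B-T``/``I-T`` of the same type) are
    repaired as ``B-T`` and logged; this is the conventional lenient reading.
    """
    mentions: list[EntityMention] = []
    start, cur_type = None, None

    def flush(end: int):
        nonlocal start, cur_type
        if start is not None:
            mentions.append(EntityMention(cur_type, start, end))
        start, cur_type = None, None

    for i, tag in enumerate(tags):
        if tag == "O":
            flush(i - 1)
            continue
        if "-" not in tag or tag.split("-", 1)[0] not in ("B", "I", "E", "S"):
            raise ValueError(f"unknown tag {tag!r} at position {i}")
        prefix, etype = tag.split("-", 1)
        if prefix in ("B", "S"):
            flush(i - 1)
            start, cur_type = i, etype
            if prefix == "S":
                flush(i)
        else:  # I or E
            if cur_type != etype:
                if cur_type is not None:
                    flush(i - 1)
                logger.debug("orphan %s at position %d repaired as B-%s", tag, i, etype)
                start, cur_type = i, etype
            if prefix == "E":
                flush(i)
    flush(len(tags) - 1)
    return mentions


def entities_to_tags(sentence: LabeledSentence, scheme: str = "bio") -> list[str]:
    """Encode mentions as per-character tags (``bio`` or ``bioes``)."""
    if scheme not in ("bio", "bioes"):
        raise ValueError(f"unknown scheme {scheme!r}")
    tags = ["O"] * len(sentence.text)
    for m in sentence.entities:
        if scheme == "bioes" and m.start == m.end:
            tags[m.start] = f"S-{m.type}"
            continue
        tags[m.start] = f"B-{m.type}"
        for i in range(m.start + 1, m.end + 1):
            tags[i] = f"I-{m.type}"
        if scheme == "bioes":
            tags[m.end] = f"E-{m.type}"
    return tags


def read_conll(path) -> list[LabeledSentence]:
    """Parse a two-column CoNLL-style file into labeled sentences."""
    sentences: list[LabeledSentence] = []
    chars: list[str] = []
    tags: list[str] = []

    def flush():
        nonlocal chars, tags
        if chars:
            text = unicodedata.normalize("NFC", "".join(chars))
            sentences.append(LabeledSentence(text, tags_to_entities(tags)))
        chars, tags = [], []

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            cols = line.split()
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            chars.append(cols[0])
            tags.append(cols[1])
    flush()
    return sentences


def write_conll(path, corpus: list[LabeledSentence], scheme: str = "bio") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in corpus:
            for ch, tag in zip(sent.text, sent.tags(scheme)):
                fh.write(f"{ch}\t{tag}\n")
            fh.write("\n")


def read_jsonl(path) -> list[LabeledSentence]:
    """Read JSONL with fields ``text`` and ``entities: [{type, start, end}]``."""
    out: list[LabeledSentence] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            mentions = [
                EntityMention(e["type"], e["start"], e["end"])
                for e in obj.get("entities", [])
            ]
            out.append(
                LabeledSentence(unicodedata.normalize("NFC", obj["text"]), mentions)
            )
    return out


def write_jsonl(path, corpus: list[LabeledSentence]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in corpus:
            obj = {
                "text": sent.text,
                "entities": [
                    {"type": m.type, "start": m.start, "end": m.end}
                    for m in sent.entities
                ],
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
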