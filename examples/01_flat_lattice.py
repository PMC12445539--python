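"""Build a flat lattice: match a sentence against a word lexicon and list
every span with its head/tail offsets and pairwise geometry.

The lattice is the model's input representation: one span per character
plus one span per dictionary match, so alternative segmentations coexist.
"""

from flcnn import (
    build_flat_lattice,
    build_lexicon,
    relative_distances,
    span_relation,
)

lexicon = build_lexicon(["月经", "月经量", "血块", "子宫内膜"])
sentence = "月经量大有血块"
lattice = build_flat_lattice(sentence, lexicon)

print(f"sentence: {sentence}")
print(f"{len(lattice)} spans (7 characters + dictionary matches):")
for span in lattice:
    print(f"  {span.kind.value:5s} [{span.head},{span.tail}] {span.surface}")

a, b = lattice.spans[1], lattice.spans[2]  # 月经 vs 月经量
d = relative_distances(a, b)
print(f"\n{a.surface} vs {b.surface}: relation={span_relation(a, b).value},"
      f" distances (dhh,dht,dth,dtt)={d.as_tuple()}")
print("Contained spans and signed head/tail distances are what the encoder's"
      " relative positional attention consumes.")
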