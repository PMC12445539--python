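"""Entity-level metrics, error typology, corpus statistics."""

import numpy as np
import pytest

from flcnn.corpus import EntityMention, LabeledSentence, entities_to_tags
from flcnn.metrics import (
    classify_errors,
    corpus_stats,
    entity_prf,
    length_stratified_prf,
    tag_accuracy,
)
from flcnn.synth import SynthConfig, generate_corpus


# --- independent conlleval-style oracle (chunk extraction from raw tags) ----

def conlleval_chunks(tags):
    """Classic chunk extractor over BIO tags: state machine on tag pairs."""
    chunks = []
    start, ctype = None, None
    for i, tag in enumerate(tags + ["O"]):
        prefix, _, etype = tag.partition("-")
        end_prev = ctype is not None and (
            prefix in ("O", "B") or (prefix == "I" and etype != ctype)
        )
        if end_prev:
            chunks.append((ctype, start, i - 1))
            start, ctype = None, None
        if prefix == "B" or (prefix == "I" and ctype is None and etype):
            start, ctype = i, etype
    return set(chunks)


def conlleval_prf(gold_tag_seqs, pred_tag_seqs):
    n_gold = n_pred = n_correct = 0
    for g, p in zip(gold_tag_seqs, pred_tag_seqs):
        gc, pc = conlleval_chunks(g), conlleval_chunks(p)
        n_gold += len(gc)
        n_pred += len(pc)
        n_correct += len(gc & pc)
    prec = 100.0 * n_correct / n_pred if n_pred else 0.0
    rec = 100.0 * n_correct / n_gold if n_gold else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def perturb_predictions(corpus, rng):
    """Synthetic predictions: drop, retype, shift and hallucinate mentions."""
    pred = []
    for sent in corpus:
        mentions = []
        occupied = []
        for m in sent.entities:
            r = rng.random()
            if r < 0.15:
                continue  # omission
            if r < 0.30:
                m = EntityMention("T9", m.start, m.end)  # type error
            elif r < 0.45 and m.end + 1 < len(sent.text):
                m = EntityMention(m.type, m.start + 1, m.end + 1)  # boundary
            if all(not m.overlaps(o) for o in occupied):
                mentions.append(m)
                occupied.append(m)
        if rng.random() < 0.2 and len(sent.text) > 3:
            extra = EntityMention("T0", len(sent.text) - 2, len(sent.text) - 1)
            if all(not extra.overlaps(o) for o in occupied):
                mentions.append(extra)
        pred.append(LabeledSentence(sent.text, mentions))
    return pred


class TestEntityPRF:
    def test_perfect_prediction(self, tiny_labeled):
        prf = entity_prf(tiny_labeled, tiny_labeled)
        assert prf.precision == prf.recall == prf.f1 == 100.0

    def test_one_spurious_prediction(self):
        gold = [[EntityMention("A", 0, 1)]]
        pred = [[EntityMention("A", 0, 1), EntityMention("B", 3, 4)]]
        prf = entity_prf(gold, pred)
        assert prf.precision == 50.0
        assert prf.recall == 100.0
        assert prf.f1 == pytest.approx(66.67, abs=0.01)

    def test_empty_denominators_are_zero(self):
        prf = entity_prf([[]], [[]])
        assert prf.precision == prf.recall == prf.f1 == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            entity_prf([[]], [[], []])

    def test_swap_symmetry(self, rng):
        corpus, _ = generate_corpus(SynthConfig(seed=5, n_sentences=40))
        pred = perturb_predictions(corpus, rng)
        a = entity_prf(corpus, pred)
        b = entity_prf(pred, corpus)
        assert a.precision == pytest.approx(b.recall)
        assert a.recall == pytest.approx(b.precision)
        assert a.f1 == pytest.approx(b.f1)

    def test_matches_independent_chunk_evaluator(self, rng):
        """200 synthetic sentences: exact agreement with a conlleval-style
        reference computed from raw BIO tag sequences."""
        corpus, _ = generate_corpus(
            SynthConfig(seed=6, n_sentences=200)
        )
        pred = perturb_predictions(corpus, rng)
        prf = entity_prf(corpus, pred)
        ref_p, ref_r, ref_f1 = conlleval_prf(
            [s.tags() for s in corpus], [s.tags() for s in pred]
        )
        assert prf.precision == ref_p
        assert prf.recall == ref_r
        assert prf.f1 == ref_f1


class TestErrorTypology:
    def test_type_error(self):
        out = classify_errors([[EntityMention("SYM", 0, 2)]], [[EntityMention("DIS", 0, 2)]])
        assert out.counts == {
            "incorrect_entity_recognition": 0,
            "entity_omission": 0,
            "boundary_error": 0,
            "entity_type_error": 1,
        }

    def test_boundary_error(self):
        out = classify_errors([[EntityMention("SYM", 0, 2)]], [[EntityMention("SYM", 1, 2)]])
        assert out.counts["boundary_error"] == 1 and out.total == 1

    def test_spurious_and_omission(self):
        out = classify_errors([[]], [[EntityMention("SYM", 0, 1)]])
        assert out.counts["incorrect_entity_recognition"] == 1
        out = classify_errors([[EntityMention("SYM", 0, 1)]], [[]])
        assert out.counts["entity_omission"] == 1

    def test_exact_matches_not_counted(self):
        m = EntityMention("SYM", 0, 1)
        assert classify_errors([[m]], [[m]]).total == 0

    def test_hand_enumerated_mismatch_fixture(self):
        """Twelve mismatch cases with known category assignments."""
        E = EntityMention
        cases = [
            # (gold, pred, expected category counts as a 4-tuple:
            #  incorrect, omission, boundary, type)
            ([E("A", 0, 2)], [E("B", 0, 2)], (0, 0, 0, 1)),
            ([E("A", 0, 2)], [E("A", 0, 1)], (0, 0, 1, 0)),
            ([E("A", 0, 2)], [E("A", 1, 3)], (0, 0, 1, 0)),
            ([E("A", 0, 2)], [], (0, 1, 0, 0)),
            ([], [E("A", 4, 5)], (1, 0, 0, 0)),
            ([E("A", 0, 2)], [E("A", 4, 5)], (1, 1, 0, 0)),
            ([E("A", 0, 2)], [E("B", 0, 1)], (1, 1, 0, 0)),
            ([E("A", 0, 2), E("B", 4, 5)], [E("B", 0, 2)], (0, 1, 0, 1)),
            # the exact match consumes the gold; the wrong-typed duplicate
            # overlaps no *unmatched* gold and is spurious
            ([E("A", 0, 2)], [E("B", 0, 2), E("A", 0, 2)], (1, 0, 0, 0)),
            ([E("A", 0, 1), E("A", 3, 4)], [E("A", 0, 4)], (0, 1, 1, 0)),
            ([E("A", 0, 5)], [E("A", 0, 1), E("A", 3, 5)], (1, 0, 1, 0)),
            ([E("A", 0, 2), E("B", 4, 6)], [E("A", 1, 2), E("A", 4, 6)], (0, 0, 1, 1)),
        ]
        assert len(cases) == 12
        for gold, pred, (inc, omi, bnd, typ) in cases:
            out = classify_errors([gold], [pred])
            got = (
                out.counts["incorrect_entity_recognition"],
                out.counts["entity_omission"],
                out.counts["boundary_error"],
                out.counts["entity_type_error"],
            )
            assert got == (inc, omi, bnd, typ), (gold, pred, got)

    def test_proportions_sum_to_100(self, rng):
        corpus, _ = generate_corpus(SynthConfig(seed=7, n_sentences=60))
        pred = perturb_predictions(corpus, rng)
        out = classify_errors(corpus, pred)
        if out.total:
            assert sum(out.proportions.values()) == pytest.approx(100.0)


class TestCorpusStats:
    def test_average_length(self):
        corpus = [
            LabeledSentence("甲乙丙丁戊己庚辛", [EntityMention("A", 0, 1), EntityMention("B", 2, 7)])
        ]
        s = corpus_stats(corpus)
        assert s.avg_entity_length == 4.0
        assert s.very_long_ratio == 0.0

    def test_very_long_threshold_strict(self):
        text = "甲乙丙丁戊己庚辛壬癸甲乙"  # 12 chars
        ten = LabeledSentence(text, [EntityMention("A", 0, 9)])     # length 10
        eleven = LabeledSentence(text, [EntityMention("A", 0, 10)])  # length 11
        assert corpus_stats([ten]).very_long_ratio == 0.0
        assert corpus_stats([eleven]).very_long_ratio == 100.0
        mixed = [eleven] + [ten] * 9
        assert corpus_stats(mixed).very_long_ratio == pytest.approx(10.0)

    def test_tagged_char_ratio(self):
        sents = [LabeledSentence("甲乙丙丁戊" * 2, [EntityMention("A", 0, 1)])
                 for _ in range(10)]
        s = corpus_stats(sents)
        assert s.tagged_char_ratio == pytest.approx(20.0)

    def test_generator_stats_recover_configured_mean(self):
        """At >= 2000 entities the realized average entity length is within
        0.2 of the analytic mean of the configured sampling scheme."""
        from flcnn.synth import analytic_mean_entity_length

        cfg = SynthConfig.long_entity_benchmark(seed=9, n_sentences=1500)
        corpus, _ = generate_corpus(cfg)
        s = corpus_stats(corpus)
        assert s.n_entities >= 2000
        assert s.avg_entity_length == pytest.approx(
            analytic_mean_entity_length(cfg), abs=0.2
        )


class TestLengthStratified:
    def test_empty_bin_has_zero_gold(self):
        gold = [[EntityMention("A", 0, 1)]]
        out = length_stratified_prf(gold, gold, [(1, 3), (4, float("inf"))])
        assert out[(4, float("inf"))].n_gold == 0
        assert out[(1, 3)].recall == 100.0

    def test_perfect_predictions_everywhere(self):
        gold = [[EntityMention("A", 0, 1), EntityMention("B", 3, 8)]]
        out = length_stratified_prf(gold, gold, [(1, 3), (4, float("inf"))])
        for prf in out.values():
            if prf.n_gold:
                assert prf.recall == prf.precision == 100.0

    def test_missed_long_entity_only_hits_long_bin(self):
        gold = [[EntityMention("A", 0, 1), EntityMention("A", 3, 14)]]
        pred = [[EntityMention("A", 0, 1)]]
        out = length_stratified_prf(gold, pred, [(1, 10), (11, float("inf"))])
        assert out[(11, float("inf"))].recall == 0.0
        assert out[(1, 10)].recall == 100.0


def test_tag_accuracy_counts_characters():
    gold = [LabeledSentence("甲乙丙丁", [EntityMention("A", 0, 1)])]
    pred = [LabeledSentence("甲乙丙丁", [EntityMention("A", 0, 0)])]
    # tags: gold B I O O vs pred B O O O -> 3/4 correct
    assert tag_accuracy(gold, pred) == pytest.approx(75.0)


def test_corpus_stats_entity_free_corpus_reports_zero_ratios():
    stats = corpus_stats([LabeledSentence("甲乙丙", [])])
    assert stats.n_entities == 0
    assert stats.avg_entity_length == 0.0
    assert stats.tagged_char_ratio == 0.0
    assert stats.very_long_ratio == 0.0
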