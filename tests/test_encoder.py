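"""Sinusoidal encodings, relative fusion, attention and character projection."""

import math

import numpy as np
import pytest

from flcnn.autograd import Tensor
from flcnn.encoder import (
    EncoderConfig,
    MultiHeadAttention,
    RelativeFuser,
    TransformerLayer,
    fuse_relative_encoding,
    load_word2vec_text,
    project_to_characters,
    sinusoidal_encoding,
    sinusoid_table,
)
from flcnn.lattice import RelativeDistances, build_flat_lattice, build_lexicon


class TestSinusoid:
    def test_zero_distance(self):
        assert np.allclose(sinusoidal_encoding(0, 4), [0, 1, 0, 1])

    def test_closed_form_scalar(self):
        # d_model=2: the single frequency is 1, so P(1) = (sin 1, cos 1)
        got = sinusoidal_encoding(1, 2)
        assert got == pytest.approx([math.sin(1.0), math.cos(1.0)], abs=1e-12)

    @pytest.mark.parametrize("d_model", [4, 8, 64])
    def test_closed_form_all_components(self, d_model):
        for d in (-7, -1, 0, 3, 12):
            got = sinusoidal_encoding(d, d_model)
            for k in range(d_model // 2):
                angle = d / 10000 ** (2 * k / d_model)
                assert got[2 * k] == pytest.approx(math.sin(angle), abs=1e-12)
                assert got[2 * k + 1] == pytest.approx(math.cos(angle), abs=1e-12)
            assert np.all(np.abs(got) <= 1.0)

    def test_sign_parity(self):
        plus, minus = sinusoidal_encoding(5, 8), sinusoidal_encoding(-5, 8)
        assert np.allclose(plus[0::2], -minus[0::2])
        assert np.allclose(plus[1::2], minus[1::2])

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError):
            sinusoidal_encoding(1, 5)

    def test_table_rows_match_scalar(self):
        tab = sinusoid_table(3, 8, dtype=np.float64)
        assert tab.shape == (7, 8)
        assert np.allclose(tab[3 + 2], sinusoidal_encoding(2, 8))
        assert np.allclose(tab[3 - 1], sinusoidal_encoding(-1, 8))


class TestRelativeFusion:
    def test_zero_projection_gives_zero(self):
        d = 8
        out = fuse_relative_encoding(
            RelativeDistances(1, -2, 3, 0), np.zeros((d, 4 * d)), d
        )
        assert np.all(out == 0)

    def test_rectifier_clips_negatives(self):
        d = 4
        w = -np.tile(np.eye(d), (1, 4))
        out = fuse_relative_encoding(RelativeDistances(0, 0, 0, 0), w, d)
        # cosine components of P(0) are 1; negated stack makes them negative
        assert np.all(out >= 0) and np.any(out == 0)

    def test_output_nonnegative_for_random_weights(self, rng):
        d = 6
        w = rng.standard_normal((d, 4 * d))
        out = fuse_relative_encoding(RelativeDistances(2, -1, 4, 1), w, d)
        assert out.shape == (d,) and np.min(out) >= 0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_relative_encoding(RelativeDistances(0, 0, 0, 0), np.zeros((4, 8)), 4)

    def test_batched_fuser_matches_reference(self, rng):
        """Table-gather fusion equals projecting concatenated encodings."""
        d = 8
        fuser = RelativeFuser(d, rng, dtype=np.float64)
        max_dist = 5
        table = sinusoid_table(max_dist, d, dtype=np.float64)
        dists = [(1, -2, 3, 0), (0, 0, 0, 0), (-4, -5, 2, 1)]
        idx = np.array([[dh + max_dist for dh in dd] for dd in dists]).T.reshape(4, 3)
        got = fuser(idx, table).data
        w_ref = fuser.w_r_matrix()
        for i, (dhh, dth, dht, dtt) in enumerate(dists):
            ref = fuse_relative_encoding(
                RelativeDistances(dhh=dhh, dht=dht, dth=dth, dtt=dtt), w_ref, d
            )
            assert np.allclose(got[i], ref, atol=1e-12)


def vanilla_attention_oracle(x, w_q, w_k, w_v, w_o, n_heads):
    """Dense per-head scaled dot-product attention, computed directly."""
    n, d = x.shape
    dh = d // n_heads
    q, k, v = x @ w_q, x @ w_k, x @ w_v
    outs = []
    for h in range(n_heads):
        sl = slice(h * dh, (h + 1) * dh)
        logits = q[:, sl] @ k[:, sl].T / math.sqrt(dh)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        outs.append(a @ v[:, sl])
    return np.concatenate(outs, axis=1) @ w_o


class TestAttention:
    def make(self, d=8, h=2, mode="xl", dtype=np.float64, seed=3):
        cfg = EncoderConfig(d_model=d, n_heads=h, d_head=d // h, dropout=0.0,
                            relative_mode=mode)
        rng = np.random.default_rng(seed)
        return cfg, MultiHeadAttention(cfg, rng, dtype=dtype)

    def test_singleton_softmax(self, rng):
        cfg, attn = self.make()
        x = Tensor(rng.standard_normal((1, 1, 8)))
        out = attn(x)
        expected = vanilla_attention_oracle(
            x.data[0], attn.w_q.data, attn.w_k.data, attn.w_v.data, attn.w_o.data, 2
        )
        assert np.allclose(out.data[0], expected, atol=1e-12)

    def test_reduces_to_vanilla_when_relative_terms_vanish(self, rng):
        """R = 0 and u = v = 0 recover plain scaled dot-product attention."""
        cfg, attn = self.make()
        n = 5
        x = Tensor(rng.standard_normal((1, n, 8)))
        rel = Tensor(np.zeros((1, n, n, 8)))
        out = attn(x, rel=rel)
        expected = vanilla_attention_oracle(
            x.data[0], attn.w_q.data, attn.w_k.data, attn.w_v.data, attn.w_o.data, 2
        )
        assert np.allclose(out.data[0], expected, atol=1e-6)

    @pytest.mark.parametrize("mode", ["xl", "bias"])
    def test_attention_rows_are_probabilities(self, mode, rng):
        cfg, attn = self.make(mode=mode)
        n = 3
        x = Tensor(rng.standard_normal((2, n, 8)))
        rel = Tensor(rng.standard_normal((2, n, n, 8)))
        attn.u.data += 0.3
        attn.v.data -= 0.2
        attn.w_bias.data += 0.1
        q = (x @ attn.w_q).reshape(2, n, 2, 4)
        k = (x @ attn.w_k).reshape(2, n, 2, 4)
        # recompute logits exactly as the layer does, then check the softmax
        from flcnn.autograd import einsum

        if mode == "xl":
            logits = einsum("bihd,bjhd->bhij", q + attn.u.reshape(1, 1, 2, 4), k)
            rw = (rel @ attn.w_kr).reshape(2, n, n, 2, 4)
            logits = logits + einsum("bihd,bijhd->bhij", q + attn.v.reshape(1, 1, 2, 4), rw)
        else:
            logits = einsum("bihd,bjhd->bhij", q, k) + einsum(
                "bijd,d->bij", rel, attn.w_bias
            ).reshape(2, 1, n, n)
        a = (logits * (4**-0.5)).softmax(axis=-1)
        assert np.allclose(a.data.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(a.data >= 0)

    def test_mask_excludes_padded_keys(self, rng):
        cfg, attn = self.make()
        x = Tensor(rng.standard_normal((1, 4, 8)))
        mask = np.array([[1.0, 1.0, 0.0, 0.0]])
        out_m = attn(x, mask=mask)
        x2 = Tensor(x.data[:, :2, :].copy())
        out_2 = attn(x2)
        assert np.allclose(out_m.data[0, :2], out_2.data[0], atol=1e-10)


class TestTransformerLayer:
    @pytest.mark.parametrize("n", [1, 7, 40])
    def test_shape_preserved(self, n, rng):
        cfg = EncoderConfig(d_model=8, n_heads=2, d_head=4, dropout=0.0)
        layer = TransformerLayer(cfg, np.random.default_rng(0), dtype=np.float64)
        x = Tensor(rng.standard_normal((1, n, 8)))
        assert layer(x).shape == (1, n, 8)

    def test_deterministic_without_dropout(self, rng):
        cfg = EncoderConfig(d_model=8, n_heads=2, d_head=4, dropout=0.0)
        layer = TransformerLayer(cfg, np.random.default_rng(0), dtype=np.float64)
        x = Tensor(rng.standard_normal((2, 5, 8)))
        a, b = layer(x), layer(x)
        assert np.array_equal(a.data, b.data)

    def test_zero_ffn_passes_normalized_residual(self, rng):
        cfg = EncoderConfig(d_model=8, n_heads=2, d_head=4, dropout=0.0)
        layer = TransformerLayer(cfg, np.random.default_rng(0), dtype=np.float64)
        layer.w1.data[...] = 0.0
        layer.b1.data[...] = 0.0
        layer.w2.data[...] = 0.0
        layer.b2.data[...] = 0.0
        x = Tensor(rng.standard_normal((1, 4, 8)))
        a = layer.attn(x)
        manual = (x + a).layer_norm(layer.ln1_g, layer.ln1_b)
        manual = manual.layer_norm(layer.ln2_g, layer.ln2_b)
        assert np.allclose(layer(x).data, manual.data, atol=1e-12)


class TestCharacterProjection:
    def test_keeps_char_rows_in_sentence_order(self, rng):
        lex = build_lexicon(["甲乙", "乙丙"])
        lat = build_flat_lattice("甲乙丙丁", lex)
        H = rng.standard_normal((len(lat), 5))
        out = project_to_characters(H, lat)
        assert out.shape == (4, 5)
        # oracle: index rows by (head, kind)
        from flcnn.lattice import SpanKind

        rows = {s.head: i for i, s in enumerate(lat) if s.kind is SpanKind.CHAR}
        expected = H[[rows[i] for i in range(4)]]
        assert np.array_equal(out, expected)

    def test_all_char_lattice_is_identity(self, rng):
        lat = build_flat_lattice("丁戊己", None)
        H = rng.standard_normal((3, 4))
        assert np.array_equal(project_to_characters(H, lat), H)

    def test_row_count_mismatch_rejected(self, rng):
        lat = build_flat_lattice("丁戊", None)
        with pytest.raises(ValueError):
            project_to_characters(rng.standard_normal((5, 4)), lat)


def test_word2vec_text_roundtrip(tmp_path):
    path = tmp_path / "vec.txt"
    path.write_text("2 3\n月经 0.1 0.2 0.3\n血块 -1 0 1\n", encoding="utf-8")
    vecs = load_word2vec_text(path)
    assert set(vecs) == {"月经", "血块"}
    assert np.allclose(vecs["血块"], [-1, 0, 1])
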