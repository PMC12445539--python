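"""Flat-lattice transformer encoder.

Spans are embedded, every ordered span pair (i, j) receives a fused relative
positional encoding

    R_ij = ReLU(W_r [P(d_hh) (+) P(d_th) (+) P(d_ht) (+) P(d_tt)])

built from sinusoidal encodings P of the four signed head/tail distances,
and a Transformer-XL style self-attention consumes both content and relative
terms.  A position-wise feed-forward block with post-norm residuals follows.
Only character rows are passed downstream (`project_to_characters`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Parameter, Tensor, concat, einsum
from .lattice import FlatLattice, RelativeDistances, SpanKind

__all__ = [
    "EncoderConfig",
    "sinusoidal_encoding",
    "sinusoid_table",
    "fuse_relative_encoding",
    "RelativeFuser",
    "MultiHeadAttention",
    "TransformerLayer",
    "project_to_characters",
    "load_word2vec_text",
]


@dataclass
class EncoderConfig:
    """Width/head/dropout settings of the attention encoder."""

    d_model: int = 160
    n_heads: int = 8
    d_head: int = 20
    dropout: float = 0.5
    n_layers: int = 1
    d_ff: int | None = None  # defaults to 2 * d_model
    relative_mode: str = "xl"  # "xl" (four-term logits) or "bias" (additive)

    def __post_init__(self):
        if self.n_heads * self.d_head != self.d_model:
            raise ValueError("n_heads * d_head must equal d_model")
        if self.relative_mode not in ("xl", "bias"):
            raise ValueError(f"unknown relative_mode {self.relative_mode!r}")
        if self.d_ff is None:
            self.d_ff = 2 * self.d_model


def sinusoidal_encoding(d: int | float, d_model: int) -> np.ndarray:
    """Sinusoidal positional encoding of a signed scalar distance.

    Component 2k is ``sin(d / 10000^(2k/d_model))``, component 2k+1 the
    matching cosine; all components lie in [-1, 1].
    """
    if d_model % 2 != 0:
        raise ValueError("d_model must be even")
    k = np.arange(d_model // 2, dtype=float)
    freq = 1.0 / (10000.0 ** (2.0 * k / d_model))
    out = np.empty(d_model, dtype=float)
    out[0::2] = np.sin(d * freq)
    out[1::2] = np.cos(d * freq)
    return out


def sinusoid_table(max_dist: int, d_model: int, dtype=np.float32) -> np.ndarray:
    """Stacked encodings for every signed distance in [-max_dist, max_dist].

    Row ``d + max_dist`` holds the encoding of distance ``d``.
    """
    return np.stack(
        [sinusoidal_encoding(d, d_model) for d in range(-max_dist, max_dist + 1)]
    ).astype(dtype)


def fuse_relative_encoding(
    dist: RelativeDistances, w_r: np.ndarray, d_model: int
) -> np.ndarray:
    """Reference single-pair fusion: ReLU(W_r . [P(dhh)+P(dth)+P(dht)+P(dtt)]).

    ``w_r`` must map the concatenation width 4*d_model down to d_model.
    """
    w_r = np.asarray(w_r, dtype=float)
    if w_r.shape != (d_model, 4 * d_model):
        raise ValueError(f"W_r must be ({d_model}, {4 * d_model}), got {w_r.shape}")
    p = np.concatenate(
        [
            sinusoidal_encoding(dist.dhh, d_model),
            sinusoidal_encoding(dist.dth, d_model),
            sinusoidal_encoding(dist.dht, d_model),
            sinusoidal_encoding(dist.dtt, d_model),
        ]
    )
    return np.maximum(w_r @ p, 0.0)


class RelativeFuser:
    """Learnable fusion of the four span-pair distances into R_ij.

    The 4*d -> d projection is applied per distance *value* first (four small
    table-times-block products), then gathered per pair and rectified — this
    is algebraically identical to projecting the concatenated encodings pair
    by pair, but costs O(max_dist * d^2) instead of O(n^2 * d^2).
    """

    def __init__(self, d_model: int, rng: np.random.Generator, dtype=np.float32):
        self.d_model = d_model
        scale = (4 * d_model) ** -0.5
        self.w_r = Parameter(
            (rng.standard_normal((4 * d_model, d_model)) * scale).astype(dtype)
        )
        self.dtype = dtype

    def parameters(self) -> list[Parameter]:
        return [self.w_r]

    def w_r_matrix(self) -> np.ndarray:
        """W_r in the (d_model, 4*d_model) layout of the reference function."""
        return self.w_r.data.T.copy()

    def __call__(
        self, dist_idx: np.ndarray, table: np.ndarray
    ) -> Tensor:
        """Fused encodings for index arrays into a sinusoid table.

        ``dist_idx``: int array (4, ...) of table rows for (dhh, dth, dht, dtt);
        ``table``: (n_rows, d_model) sinusoid table.  Returns a Tensor of
        shape ``dist_idx.shape[1:] + (d_model,)``.
        """
        d = self.d_model
        tab = Tensor(np.asarray(table, dtype=self.dtype))
        acc = None
        for k in range(4):
            proj = tab @ self.w_r[k * d : (k + 1) * d, :]  # (n_rows, d)
            term = proj[dist_idx[k]]
            acc = term if acc is None else acc + term
        return acc.relu()


def _linear_param(rng, fan_in: int, fan_out: int, dtype) -> Parameter:
    scale = fan_in**-0.5
    return Parameter((rng.standard_normal((fan_in, fan_out)) * scale).astype(dtype))


class MultiHeadAttention:
    """Scaled dot-product attention with optional relative-position terms.

    In ``xl`` mode the per-head logit is the four-term decomposition

        (Q_i K_j^T + Q_i (W_kR R_ij)^T + u K_j^T + v (W_kR R_ij)^T) / sqrt(d_k)

    with learnable global biases u, v; with R = 0 and u = v = 0 it reduces
    exactly to plain scaled dot-product attention.  ``bias`` mode adds a
    scalar learned projection of R_ij to the content logit instead.
    """

    def __init__(self, config: EncoderConfig, rng: np.random.Generator, dtype=np.float32):
        d, h, dh = config.d_model, config.n_heads, config.d_head
        self.config = config
        self.dtype = dtype
        self.w_q = _linear_param(rng, d, d, dtype)
        self.w_k = _linear_param(rng, d, d, dtype)
        self.w_v = _linear_param(rng, d, d, dtype)
        self.w_o = _linear_param(rng, d, d, dtype)
        self.w_kr = _linear_param(rng, d, d, dtype)
        self.u = Parameter(np.zeros((h, dh), dtype=dtype))
        self.v = Parameter(np.zeros((h, dh), dtype=dtype))
        self.w_bias = Parameter(np.zeros(d, dtype=dtype))

    def parameters(self) -> list[Parameter]:
        base = [self.w_q, self.w_k, self.w_v, self.w_o]
        if self.config.relative_mode == "xl":
            return base + [self.w_kr, self.u, self.v]
        return base + [self.w_bias]

    def __call__(
        self,
        x: Tensor,
        mask: np.ndarray | None = None,
        rel: Tensor | None = None,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """``x``: (B, n, d); ``mask``: (B, n) 1/0 validity; ``rel``: (B, n, n, d)."""
        B, n, d = x.shape
        h, dh = self.config.n_heads, self.config.d_head
        q = (x @ self.w_q).reshape(B, n, h, dh)
        k = (x @ self.w_k).reshape(B, n, h, dh)
        v = (x @ self.w_v).reshape(B, n, h, dh)

        if rel is not None and self.config.relative_mode == "xl":
            logits = einsum("bihd,bjhd->bhij", q + self.u.reshape(1, 1, h, dh), k)
            rw = (rel @ self.w_kr).reshape(B, n, n, h, dh)
            logits = logits + einsum(
                "bihd,bijhd->bhij", q + self.v.reshape(1, 1, h, dh), rw
            )
        else:
            logits = einsum("bihd,bjhd->bhij", q, k)
            if rel is not None:  # additive-bias variant
                bias = einsum("bijd,d->bij", rel, self.w_bias)
                logits = logits + bias.reshape(B, 1, n, n)
        logits = logits * (dh**-0.5)

        if mask is not None:
            neg = ((1.0 - mask[:, None, None, :]) * -1e9).astype(self.dtype)
            logits = logits + Tensor(neg)
        attn = logits.softmax(axis=-1)
        attn = attn.dropout(self.config.dropout, rng)
        out = einsum("bhij,bjhd->bihd", attn, v).reshape(B, n, d)
        return out @ self.w_o


class TransformerLayer:
    """Attention sublayer + two-layer FFN, each with post-norm residual."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator, dtype=np.float32):
        d, dff = config.d_model, config.d_ff
        self.config = config
        self.dtype = dtype
        self.attn = MultiHeadAttention(config, rng, dtype)
        self.w1 = _linear_param(rng, d, dff, dtype)
        self.b1 = Parameter(np.zeros(dff, dtype=dtype))
        self.w2 = _linear_param(rng, dff, d, dtype)
        self.b2 = Parameter(np.zeros(d, dtype=dtype))
        self.ln1_g = Parameter(np.ones(d, dtype=dtype))
        self.ln1_b = Parameter(np.zeros(d, dtype=dtype))
        self.ln2_g = Parameter(np.ones(d, dtype=dtype))
        self.ln2_b = Parameter(np.zeros(d, dtype=dtype))

    def parameters(self) -> list[Parameter]:
        return (
            self.attn.parameters()
            + [self.w1, self.b1, self.w2, self.b2]
            + [self.ln1_g, self.ln1_b, self.ln2_g, self.ln2_b]
        )

    def __call__(
        self,
        x: Tensor,
        mask: np.ndarray | None = None,
        rel: Tensor | None = None,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        a = self.attn(x, mask=mask, rel=rel, rng=rng)
        x = (x + a.dropout(self.config.dropout, rng)).layer_norm(self.ln1_g, self.ln1_b)
        f = ((x @ self.w1 + self.b1).relu()).dropout(self.config.dropout, rng)
        f = f @ self.w2 + self.b2
        x = (x + f.dropout(self.config.dropout, rng)).layer_norm(self.ln2_g, self.ln2_b)
        if mask is not None:
            x = x * Tensor(mask[:, :, None].astype(self.dtype))
        return x


def project_to_characters(H, lattice: FlatLattice):
    """Keep only the CHAR-span rows of span embeddings, in sentence order.

    Accepts a numpy matrix or an autograd Tensor of shape (n_spans, d).
    """
    if H.shape[0] != len(lattice):
        raise ValueError("row count must equal span count")
    idx = lattice.char_positions()
    if len(idx) != lattice.n_chars:
        raise ValueError("lattice is missing CHAR spans")
    if isinstance(H, Tensor):
        return H[np.asarray(idx)]
    return np.asarray(H)[idx]


def load_word2vec_text(path) -> dict[str, np.ndarray]:
    """Read word2vec text format: header 'count dim', then 'token v1 .. vdim'."""
    out: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("word2vec text file must start with 'count dim'")
        dim = int(header[1])
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) < dim + 1:
                continue
            out[parts[0]] = np.asarray(parts[1 : dim + 1], dtype=float)
    return out
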