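"""Full model assembly: flat-lattice encoder -> dilated CNN -> character
projection -> attention/FFN layer -> CRF emissions.

Pipeline order for one sentence:

1. ``build_flat_lattice`` matches the lexicon and flattens the lattice;
2. span embeddings plus the relative-position self-attention sublayer
   produce the span representations W_F;
3. the basic convolution layer and the multi-dilation block extract the
   multi-token co-occurrence features W_C over the span sequence;
4. [W_F; W_C] is fused back to model width and only character rows continue;
5. a second self-attention + FFN layer contextualizes the character rows;
6. a linear map yields per-character CRF emission scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autograd import Parameter, Tensor
from .corpus import LabeledSentence, tags_to_entities
from .crf import CRFLayer
from .dilated import BasicConvLayer, ConcatFusion, ConvSpec, MultiDilationBlock
from .encoder import EncoderConfig, RelativeFuser, TransformerLayer, sinusoid_table
from .lattice import FlatLattice, LexiconIndex, SpanKind, build_flat_lattice

__all__ = ["ModelConfig", "Vocabulary", "FlatLatticeCNN", "tag_set"]

UNK = "<unk>"


@dataclass
class ModelConfig:
    """Hyperparameters; the defaults are the reference parameterization
    (learning rate 6e-4, batch 10, 50 epochs, 8 heads of width 20,
    model width 160, 160 channels, dropout 0.5, dilation rates [1, 2, 4])."""

    d_model: int = 160
    n_heads: int = 8
    dropout: float = 0.5
    n_layers: int = 1
    relative_mode: str = "xl"
    kernel_size: int = 3
    dilations: list[int] = field(default_factory=lambda: [1, 2, 4])
    channels: int = 160
    conv_dropout: float = 0.0
    cnn_scope: str = "spans"
    cnn_enabled: bool = True
    learning_rate: float = 6e-4
    batch_size: int = 10
    epochs: int = 50
    patience: int = 10
    seed: int = 0
    scheme: str = "bio"
    constrain_bio: bool = False
    max_len: int = 160

    @property
    def d_head(self) -> int:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        return self.d_model // self.n_heads

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(
            d_model=self.d_model,
            n_heads=self.n_heads,
            d_head=self.d_head,
            dropout=self.dropout,
            n_layers=self.n_layers,
            relative_mode=self.relative_mode,
        )

    def conv_spec(self) -> ConvSpec:
        return ConvSpec(
            kernel_size=self.kernel_size,
            dilations=list(self.dilations),
            channels=self.channels,
            dropout=self.conv_dropout,
            scope=self.cnn_scope,
        )

    @staticmethod
    def small(**overrides) -> "ModelConfig":
        """A light configuration for quick experiments and tests."""
        base = dict(d_model=32, n_heads=4, dropout=0.1, channels=32, max_len=160)
        base.update(overrides)
        return ModelConfig(**base)


class Vocabulary:
    """Bidirectional token/id map with an <unk> fallback at id 0."""

    def __init__(self, tokens: list[str]):
        self.itos = [UNK] + sorted(set(tokens))
        self.stoi = {t: i for i, t in enumerate(self.itos)}

    def __len__(self) -> int:
        return len(self.itos)

    def id(self, token: str) -> int:
        return self.stoi.get(token, 0)


def tag_set(entity_types: list[str], scheme: str = "bio") -> list[str]:
    """Canonical tag list: O first, then B-/I-(/E-/S-) per type, sorted."""
    tags = ["O"]
    prefixes = ("B", "I") if scheme == "bio" else ("B", "I", "E", "S")
    for t in sorted(set(entity_types)):
        for p in prefixes:
            tags.append(f"{p}-{t}")
    return tags


class FlatLatticeCNN:
    """The lattice NER tagger; holds all parameters and the CRF head."""

    def __init__(
        self,
        config: ModelConfig,
        lexicon: LexiconIndex | None,
        tag_names: list[str],
        chars: list[str],
        word_vectors: dict[str, np.ndarray] | None = None,
        dtype=np.float32,
    ):
        self.config = config
        self.lexicon = lexicon
        self.tag_names = list(tag_names)
        self.dtype = dtype
        self.trained = False
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(config.seed + 0x5EED)

        self.char_vocab = Vocabulary(chars)
        words = lexicon.words() if lexicon is not None else []
        self.word_vocab = Vocabulary(words)

        d = config.d_model
        scale = d**-0.5
        self.char_emb = Parameter(
            (rng.standard_normal((len(self.char_vocab), d)) * scale).astype(dtype)
        )
        self.word_emb = Parameter(
            (rng.standard_normal((len(self.word_vocab), d)) * scale).astype(dtype)
        )
        if word_vectors:
            for w, vec in word_vectors.items():
                i = self.word_vocab.stoi.get(w)
                if i is None:
                    continue
                if len(vec) != d:
                    raise ValueError(
                        f"pretrained vector width {len(vec)} != d_model {d}"
                    )
                self.word_emb.data[i] = np.asarray(vec, dtype=dtype)

        enc = config.encoder_config()
        self.fuser = RelativeFuser(d, rng, dtype)
        self.flat_layers = [TransformerLayer(enc, rng, dtype) for _ in range(enc.n_layers)]
        spec = config.conv_spec()
        self.basic_conv = BasicConvLayer(d, spec, rng, dtype)
        self.dilation_block = MultiDilationBlock(spec, rng, dtype)
        self.fusion = ConcatFusion(d, self.dilation_block.out_width, rng, dtype)
        self.char_layer = TransformerLayer(enc, rng, dtype)
        n_tags = len(tag_names)
        self.w_out = Parameter((rng.standard_normal((d, n_tags)) * scale).astype(dtype))
        self.b_out = Parameter(np.zeros(n_tags, dtype=dtype))
        self.crf = CRFLayer(
            n_tags, rng, tag_names=self.tag_names,
            constrain_bio=config.constrain_bio, dtype=dtype,
        )
        self._table_cache: dict[int, np.ndarray] = {}

    # -- plumbing ----------------------------------------------------------

    def parameters(self) -> list[Parameter]:
        params = [self.char_emb, self.word_emb, self.w_out, self.b_out]
        params += self.fuser.parameters()
        for layer in self.flat_layers:
            params += layer.parameters()
        if self.config.cnn_enabled:
            params += self.basic_conv.parameters()
            params += self.dilation_block.parameters()
            params += self.fusion.parameters()
        params += self.char_layer.parameters()
        params += self.crf.parameters()
        return params

    def lattices(self, sentences: list[str]) -> list[FlatLattice]:
        for s in sentences:
            if len(s) > self.config.max_len:
                raise ValueError(
                    f"sentence length {len(s)} exceeds max_len {self.config.max_len}"
                )
        return [build_flat_lattice(s, self.lexicon) for s in sentences]

    def _sin_table(self, max_dist: int) -> np.ndarray:
        if max_dist not in self._table_cache:
            self._table_cache[max_dist] = sinusoid_table(
                max_dist, self.config.d_model, self.dtype
            )
        return self._table_cache[max_dist]

    # -- forward -----------------------------------------------------------

    def _emissions(
        self, lattices: list[FlatLattice], train: bool = False
    ) -> tuple[Tensor, np.ndarray]:
        """Padded emissions (B, Lc_max, n_tags) and character lengths (B,)."""
        B = len(lattices)
        N = max(len(lat) for lat in lattices)
        Lc = max(lat.n_chars for lat in lattices)
        d = self.config.d_model
        rng = self._dropout_rng if train else None

        char_ids = np.zeros((B, N), dtype=int)
        word_ids = np.zeros((B, N), dtype=int)
        is_char = np.zeros((B, N), dtype=self.dtype)
        heads = np.zeros((B, N), dtype=int)
        tails = np.zeros((B, N), dtype=int)
        mask = np.zeros((B, N), dtype=self.dtype)
        char_rows = np.zeros((B, Lc), dtype=int)
        lengths = np.array([lat.n_chars for lat in lattices], dtype=int)
        for b, lat in enumerate(lattices):
            for i, sp in enumerate(lat):
                heads[b, i] = sp.head
                tails[b, i] = sp.tail
                mask[b, i] = 1.0
                if sp.kind is SpanKind.CHAR:
                    char_ids[b, i] = self.char_vocab.id(sp.surface)
                    is_char[b, i] = 1.0
                else:
                    word_ids[b, i] = self.word_vocab.id(sp.surface)
            char_rows[b, : lat.n_chars] = lat.char_positions()

        emb = self.char_emb[char_ids] * Tensor(is_char[:, :, None]) + self.word_emb[
            word_ids
        ] * Tensor((1.0 - is_char)[:, :, None])
        emb = emb * Tensor(mask[:, :, None])
        emb = emb.dropout(self.config.dropout, rng)

        # fused relative encodings from the four signed head/tail distances
        max_dist = int(max(lat.n_chars for lat in lattices))
        table = self._sin_table(max_dist)
        dhh = heads[:, :, None] - heads[:, None, :]
        dht = heads[:, :, None] - tails[:, None, :]
        dth = tails[:, :, None] - heads[:, None, :]
        dtt = tails[:, :, None] - tails[:, None, :]
        dist_idx = np.stack([dhh, dth, dht, dtt]) + max_dist
        rel = self.fuser(dist_idx, table)

        x = emb
        for layer in self.flat_layers:
            x = layer(x, mask=mask, rel=rel, rng=rng)
        w_f = x  # span representations from the flat-lattice sublayer

        b_idx = np.arange(B)[:, None]
        char_valid = (np.arange(Lc)[None, :] < lengths[:, None]).astype(self.dtype)
        if self.config.cnn_enabled:
            if self.config.cnn_scope == "chars":
                conv_in = w_f[b_idx, char_rows] * Tensor(char_valid[:, :, None])
                conv_mask = char_valid
            else:
                conv_in = w_f
                conv_mask = mask
            # re-mask after bias+ReLU so padded rows stay out of later
            # branches' receptive fields
            cx = self.basic_conv(conv_in, rng) * Tensor(conv_mask[:, :, None])
            w_c = self.dilation_block(cx, rng)
            if self.config.cnn_scope == "chars":
                w_f_chars = w_f[b_idx, char_rows]
                fused = self.fusion(w_f_chars, w_c)
                y = fused
            else:
                fused = self.fusion(w_f, w_c)
                y = fused[b_idx, char_rows]
        else:
            y = w_f[b_idx, char_rows]

        char_mask = char_valid
        y = y * Tensor(char_mask[:, :, None])
        y = self.char_layer(y, mask=char_mask, rel=None, rng=rng)
        emissions = y @ self.w_out + self.b_out
        return emissions, lengths

    def emissions(self, sentence: str) -> np.ndarray:
        """Per-character CRF emission scores for one sentence (eval mode)."""
        lat = self.lattices([sentence])
        em, lengths = self._emissions(lat, train=False)
        return em.data[0, : lengths[0]].astype(float)

    def loss(self, sentences: list[LabeledSentence], train: bool = True) -> Tensor:
        """Mean CRF negative log-likelihood of a batch."""
        lats = self.lattices([s.text for s in sentences])
        em, lengths = self._emissions(lats, train=train)
        L = em.shape[1]
        tags = np.zeros((len(sentences), L), dtype=int)
        for b, s in enumerate(sentences):
            ids = [self.tag_names.index(t) for t in s.tags(self.config.scheme)]
            tags[b, : len(ids)] = ids
        return self.crf.nll(em, tags, lengths)

    def predict(self, sentences: list[str], batch_size: int | None = None) -> list[LabeledSentence]:
        """Viterbi-decode sentences into labeled sentences."""
        bs = batch_size or self.config.batch_size
        out: list[LabeledSentence] = []
        for i in range(0, len(sentences), bs):
            chunk = sentences[i : i + bs]
            lats = self.lattices(chunk)
            em, lengths = self._emissions(lats, train=False)
            for text, ids in zip(chunk, self.crf.decode(em.data, lengths)):
                tags = [self.tag_names[t] for t in ids]
                out.append(LabeledSentence(text, tags_to_entities(tags)))
        return out

    # -- serialization -----------------------------------------------------

    CHECKPOINT_VERSION = 1

    def save(self, path) -> None:
        """Single-file checkpoint (npz) with config and vocabularies embedded."""
        meta = {
            "version": self.CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "tag_names": self.tag_names,
            "chars": self.char_vocab.itos[1:],
            "lexicon": self.lexicon.words() if self.lexicon else [],
            "trained": self.trained,
        }
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path, meta=json.dumps(meta, ensure_ascii=False), **arrays)

    @classmethod
    def load(cls, path) -> "FlatLatticeCNN":
        from .lattice import build_lexicon

        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta["version"] != cls.CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta['version']}")
            cfg = ModelConfig(**meta["config"])
            lex = build_lexicon(meta["lexicon"]) if meta["lexicon"] else None
            model = cls(cfg, lex, meta["tag_names"], meta["chars"])
            for i, p in enumerate(model.parameters()):
                p.data[...] = data[f"p{i}"]
        model.trained = meta["trained"]
        return model
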