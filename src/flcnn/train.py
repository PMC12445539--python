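"""Training loop, prediction helpers, dilation ablation, heatmap export."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np

from .autograd import Adam, Tensor
from .corpus import LabeledSentence
from .lattice import LexiconIndex
from .metrics import entity_prf, tag_accuracy
from .model import FlatLatticeCNN, ModelConfig, tag_set

logger = logging.getLogger(__name__)

__all__ = ["TrainLog", "train", "evaluate_model", "ablate_dilations", "export_heatmap"]


@dataclass
class TrainLog:
    """Per-epoch record of loss and dev score, plus the best epoch index."""

    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_dev_f1: float = -1.0

    def append(self, **kw) -> None:
        self.epochs.append(kw)


def _batches(sizes: np.ndarray, batch_size: int, rng: np.random.Generator):
    """Length-bucketed batches in shuffled order.

    Sentences are sorted by size with a random tie-break, chunked, and the
    chunk order is shuffled; this keeps padding waste low without fixing
    batch composition across epochs.
    """
    n = len(sizes)
    jitter = rng.random(n)
    order = np.lexsort((jitter, sizes))
    chunks = [order[i : i + batch_size] for i in range(0, n, batch_size)]
    for j in rng.permutation(len(chunks)):
        yield chunks[j]


def train(
    train_corpus: list[LabeledSentence],
    dev_corpus: list[LabeledSentence],
    lexicon: LexiconIndex | None,
    config: ModelConfig,
    word_vectors: dict[str, np.ndarray] | None = None,
    quiet: bool = True,
) -> tuple[FlatLatticeCNN, TrainLog]:
    """Mini-batch Adam training of the CRF negative log-likelihood.

    Logs per-epoch mean loss and dev entity-F1, keeps the best-dev weights,
    stops early after ``config.patience`` epochs without dev improvement.
    Fully deterministic for a fixed seed under single-threaded execution.
    """
    if not train_corpus:
        raise ValueError("empty training corpus")
    types = sorted({m.type for s in train_corpus for m in s.entities})
    tags = tag_set(types, config.scheme)
    chars = sorted({c for s in train_corpus for c in s.text})
    model = FlatLatticeCNN(config, lexicon, tags, chars, word_vectors=word_vectors)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 0xBA7C4)
    log = TrainLog()
    best_params: list[np.ndarray] | None = None
    since_best = 0
    sizes = np.array([len(s.text) for s in train_corpus])

    for epoch in range(config.epochs):
        t0 = time.time()
        losses = []
        for idx in _batches(sizes, config.batch_size, rng):
            batch = [train_corpus[i] for i in idx]
            opt.zero_grad()
            loss = model.loss(batch, train=True)
            val = loss.item()
            if not np.isfinite(val):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            loss.backward()
            opt.step()
            losses.append(val)
        dev_f1 = np.nan
        if dev_corpus:
            pred = model.predict([s.text for s in dev_corpus])
            dev_f1 = entity_prf(dev_corpus, pred).f1
        mean_loss = float(np.mean(losses))
        log.append(epoch=epoch, loss=mean_loss, dev_f1=float(dev_f1),
                   seconds=time.time() - t0)
        if not quiet:
            logger.info("epoch %d loss %.4f dev F1 %.2f", epoch, mean_loss, dev_f1)
        if dev_corpus and dev_f1 > log.best_dev_f1:
            log.best_dev_f1 = float(dev_f1)
            log.best_epoch = epoch
            best_params = [p.data.copy() for p in model.parameters()]
            since_best = 0
        else:
            since_best += 1
        if dev_corpus and since_best >= config.patience:
            break
        if dev_corpus and log.best_dev_f1 >= 100.0:
            break

    if best_params is not None:
        for p, w in zip(model.parameters(), best_params):
            p.data[...] = w
    model.trained = True
    return model, log


def evaluate_model(
    model: FlatLatticeCNN, corpus: list[LabeledSentence]
) -> dict[str, float]:
    """Entity PRF and tag accuracy of a model on a labeled corpus."""
    pred = model.predict([s.text for s in corpus])
    prf = entity_prf(corpus, pred)
    return {
        "precision": prf.precision,
        "recall": prf.recall,
        "f1": prf.f1,
        "accuracy": tag_accuracy(corpus, pred),
    }


def ablate_dilations(
    train_corpus: list[LabeledSentence],
    dev_corpus: list[LabeledSentence],
    eval_corpus: list[LabeledSentence],
    lexicon: LexiconIndex | None,
    dilation_sets: list[list[int]],
    seeds: list[int],
    config: ModelConfig,
    quiet: bool = True,
):
    """Train one model per (dilation set, seed); tabulate mean F1 and ACC.

    Returns a pandas DataFrame with one row per dilation set, mirroring the
    usual dilation-comparison layout (F1 % and tag accuracy %).
    """
    import pandas as pd

    if len(dilation_sets) < 2:
        raise ValueError("need at least two dilation sets to compare")
    rows = []
    for dset in dilation_sets:
        f1s, accs = [], []
        for seed in seeds:
            cfg = replace(config, dilations=list(dset), seed=seed)
            model, _ = train(train_corpus, dev_corpus, lexicon, cfg, quiet=quiet)
            scores = evaluate_model(model, eval_corpus)
            f1s.append(scores["f1"])
            accs.append(scores["accuracy"])
        rows.append(
            {
                "dilations": str(list(dset)),
                "f1_mean": float(np.mean(f1s)),
                "acc_mean": float(np.mean(accs)),
                "f1_per_seed": f1s,
            }
        )
    return pd.DataFrame(rows)


def export_heatmap(model: FlatLatticeCNN, sentence: str, path) -> None:
    """Write a per-branch activation-magnitude heatmap for one sentence.

    Rows are dilation branches, columns are positions of the span sequence;
    cell intensity is the mean absolute activation of the branch's rectified
    output at that position.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not model.trained:
        logger.warning("exporting heatmap from an untrained model")
    lat = model.lattices([sentence])[0]
    x = _span_representations(model, lat)
    cx = model.basic_conv(x)
    acts = model.dilation_block.branch_activations(cx)
    mat = np.stack([np.abs(a[0]).mean(axis=-1) for a in acts])  # (branches, n)
    fig, ax = plt.subplots(figsize=(max(4, 0.25 * mat.shape[1]), 1 + 0.5 * mat.shape[0]))
    im = ax.imshow(mat, aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(model.config.dilations)))
    ax.set_yticklabels([f"lambda={l}" for l in model.config.dilations])
    ax.set_xlabel("span position (lattice order)")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _span_representations(model: FlatLatticeCNN, lat) -> Tensor:
    """W_F of a single lattice (eval mode), as a (1, n, d) tensor."""
    import numpy as _np
    from .lattice import SpanKind

    n = len(lat)
    char_ids = _np.zeros((1, n), dtype=int)
    word_ids = _np.zeros((1, n), dtype=int)
    is_char = _np.zeros((1, n), dtype=model.dtype)
    heads = _np.zeros((1, n), dtype=int)
    tails = _np.zeros((1, n), dtype=int)
    for i, sp in enumerate(lat):
        heads[0, i], tails[0, i] = sp.head, sp.tail
        if sp.kind is SpanKind.CHAR:
            char_ids[0, i] = model.char_vocab.id(sp.surface)
            is_char[0, i] = 1.0
        else:
            word_ids[0, i] = model.word_vocab.id(sp.surface)
    emb = model.char_emb[char_ids] * Tensor(is_char[:, :, None]) + model.word_emb[
        word_ids
    ] * Tensor((1.0 - is_char)[:, :, None])
    max_dist = lat.n_chars
    table = model._sin_table(max_dist)
    dist_idx = _np.stack(
        [
            heads[:, :, None] - heads[:, None, :],
            tails[:, :, None] - heads[:, None, :],
            heads[:, :, None] - tails[:, None, :],
            tails[:, :, None] - tails[:, None, :],
        ]
    ) + max_dist
    rel = model.fuser(dist_idx, table)
    x = emb
    for layer in model.flat_layers:
        x = layer(x, mask=_np.ones((1, n), dtype=model.dtype), rel=rel, rng=None)
    return x
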