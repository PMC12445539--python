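"""Linear-chain conditional random field.

The label-sequence distribution is the standard globally normalized product
of potentials: per-position emission scores (state features, produced by the
network) plus a learned tag-transition matrix (transition features), with
explicit start and end weights.  This module provides

* plain-numpy reference functions (`sequence_score`, `log_partition`,
  `nll_loss`, `viterbi_decode`) defining the contract, and
* :class:`CRFLayer`, a batched autograd version of the negative
  log-likelihood used during training, plus batched Viterbi decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Parameter, Tensor

__all__ = [
    "CRFParams",
    "sequence_score",
    "log_partition",
    "nll_loss",
    "viterbi_decode",
    "CRFLayer",
    "bio_transition_mask",
]


@dataclass
class CRFParams:
    """Transition weights: ``transitions[y_prev, y]`` plus start/end weights."""

    transitions: np.ndarray
    start_weights: np.ndarray
    end_weights: np.ndarray

    def __post_init__(self):
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.start_weights = np.asarray(self.start_weights, dtype=float)
        self.end_weights = np.asarray(self.end_weights, dtype=float)
        n = self.transitions.shape[0]
        if self.transitions.shape != (n, n):
            raise ValueError("transition matrix must be square")
        if self.start_weights.shape != (n,) or self.end_weights.shape != (n,):
            raise ValueError("start/end weights must have length n_tags")
        if not (
            np.all(np.isfinite(self.transitions))
            and np.all(np.isfinite(self.start_weights))
            and np.all(np.isfinite(self.end_weights))
        ):
            raise ValueError("CRF parameters must be finite")

    @property
    def n_tags(self) -> int:
        return self.transitions.shape[0]

    @staticmethod
    def zeros(n_tags: int) -> "CRFParams":
        return CRFParams(
            np.zeros((n_tags, n_tags)), np.zeros(n_tags), np.zeros(n_tags)
        )


def _check(emissions: np.ndarray, params: CRFParams) -> np.ndarray:
    emissions = np.asarray(emissions, dtype=float)
    if emissions.ndim != 2 or emissions.shape[0] == 0:
        raise ValueError("emissions must be a non-empty (length, n_tags) matrix")
    if emissions.shape[1] != params.n_tags:
        raise ValueError("emission width must equal n_tags")
    return emissions


def sequence_score(
    emissions: np.ndarray, tags: list[int], params: CRFParams
) -> float:
    """Unnormalized log-potential of one tag sequence."""
    emissions = _check(emissions, params)
    if len(tags) != emissions.shape[0]:
        raise ValueError("tags length must match emissions rows")
    tags = list(tags)
    score = params.start_weights[tags[0]] + params.end_weights[tags[-1]]
    score += sum(emissions[i, t] for i, t in enumerate(tags))
    score += sum(params.transitions[a, b] for a, b in zip(tags, tags[1:]))
    return float(score)


def log_partition(emissions: np.ndarray, params: CRFParams) -> float:
    """log Z via the forward recursion in log space (log-sum-exp per step)."""
    emissions = _check(emissions, params)
    alpha = params.start_weights + emissions[0]
    for row in emissions[1:]:
        # alpha'[y] = logsumexp_y' (alpha[y'] + T[y', y]) + e[y]
        alpha = _lse_step(alpha, params.transitions) + row
    alpha = alpha + params.end_weights
    m = alpha.max()
    return float(m + np.log(np.exp(alpha - m).sum()))


def _lse_step(alpha: np.ndarray, transitions: np.ndarray) -> np.ndarray:
    scores = alpha[:, None] + transitions
    m = scores.max(axis=0)
    return m + np.log(np.exp(scores - m).sum(axis=0))


def nll_loss(emissions: np.ndarray, gold_tags: list[int], params: CRFParams) -> float:
    """Negative log-likelihood of the gold sequence; always >= 0."""
    return log_partition(emissions, params) - sequence_score(
        emissions, gold_tags, params
    )


def viterbi_decode(
    emissions: np.ndarray, params: CRFParams
) -> tuple[list[int], float]:
    """Globally optimal tag sequence and its score.

    Ties are broken toward the lowest tag index (``argmax`` takes the first
    maximum).
    """
    emissions = _check(emissions, params)
    L, n = emissions.shape
    delta = params.start_weights + emissions[0]
    back = np.zeros((L, n), dtype=int)
    for i in range(1, L):
        scores = delta[:, None] + params.transitions  # [prev, cur]
        back[i] = scores.argmax(axis=0)
        delta = scores.max(axis=0) + emissions[i]
    delta = delta + params.end_weights
    last = int(delta.argmax())
    tags = [last]
    for i in range(L - 1, 0, -1):
        tags.append(int(back[i, tags[-1]]))
    tags.reverse()
    # re-score the argmax path so the value is bit-identical to sequence_score
    return tags, sequence_score(emissions, tags, params)


def bio_transition_mask(tag_names: list[str]) -> np.ndarray:
    """Additive (n_tags, n_tags) mask, 0 or -1e4, forbidding invalid BIO
    transitions: ``I-X`` may only follow ``B-X`` or ``I-X``.  The matching
    start-position constraint is applied separately by :class:`CRFLayer`.
    """
    n = len(tag_names)
    mask = np.zeros((n, n))
    for j, tj in enumerate(tag_names):
        if not tj.startswith("I-"):
            continue
        ty = tj[2:]
        for i, ti in enumerate(tag_names):
            if ti not in (f"B-{ty}", f"I-{ty}"):
                mask[i, j] = -1e4
    return mask


class CRFLayer:
    """Batched CRF negative log-likelihood and decoding over autograd tensors."""

    def __init__(
        self,
        n_tags: int,
        rng: np.random.Generator,
        tag_names: list[str] | None = None,
        constrain_bio: bool = False,
        dtype=np.float32,
    ):
        self.n_tags = n_tags
        scale = 0.01
        self.transitions = Parameter(
            (rng.standard_normal((n_tags, n_tags)) * scale).astype(dtype)
        )
        self.start = Parameter((rng.standard_normal(n_tags) * scale).astype(dtype))
        self.end = Parameter((rng.standard_normal(n_tags) * scale).astype(dtype))
        self._mask = None
        self._start_mask = None
        if constrain_bio:
            if tag_names is None:
                raise ValueError("constrain_bio requires tag_names")
            self._mask = bio_transition_mask(tag_names).astype(dtype)
            self._start_mask = np.array(
                [-1e4 if t.startswith("I-") else 0.0 for t in tag_names], dtype=dtype
            )

    def parameters(self) -> list[Parameter]:
        return [self.transitions, self.start, self.end]

    def _trans(self) -> Tensor:
        t = self.transitions
        if self._mask is not None:
            t = t + Tensor(self._mask)
        return t

    def _start(self) -> Tensor:
        s = self.start
        if self._start_mask is not None:
            s = s + Tensor(self._start_mask)
        return s

    def numpy_params(self) -> CRFParams:
        """Snapshot as plain-numpy :class:`CRFParams` (masks applied)."""
        return CRFParams(
            self._trans().data.astype(float),
            self._start().data.astype(float),
            self.end.data.astype(float),
        )

    def nll(self, emissions: Tensor, tags: np.ndarray, lengths: np.ndarray) -> Tensor:
        """Mean per-sentence negative log-likelihood of a padded batch.

        ``emissions``: (B, L, n_tags); ``tags``: (B, L) int, padded
        arbitrarily beyond each length; ``lengths``: (B,) true lengths.
        """
        B, L, n = emissions.shape
        trans = self._trans()
        start = self._start()
        dtype = emissions.data.dtype
        b_idx = np.arange(B)

        # gold path score
        gold = emissions[b_idx[:, None], np.arange(L)[None, :], tags]  # (B, L)
        len_mask = (np.arange(L)[None, :] < lengths[:, None]).astype(dtype)
        gold_score = (gold * Tensor(len_mask)).sum(axis=1)
        gold_score = gold_score + start[tags[:, 0]]
        if L > 1:
            pair_mask = (np.arange(1, L)[None, :] < lengths[:, None]).astype(dtype)
            tr = trans[tags[:, :-1], tags[:, 1:]]  # (B, L-1)
            gold_score = gold_score + (tr * Tensor(pair_mask)).sum(axis=1)
        last = lengths - 1
        gold_score = gold_score + self.end[tags[b_idx, last]]

        # forward recursion
        alpha = start.reshape(1, n) + emissions[:, 0, :]  # (B, n)
        for i in range(1, L):
            step = alpha.reshape(B, n, 1) + trans.reshape(1, n, n)
            nxt = step.logsumexp(axis=1) + emissions[:, i, :]
            active = (i < lengths).astype(dtype)[:, None]
            alpha = nxt * Tensor(active) + alpha * Tensor(1.0 - active)
        alpha = alpha + self.end.reshape(1, n)
        logz = alpha.logsumexp(axis=1)  # (B,)

        return (logz - gold_score).sum() * (1.0 / B)

    def decode(self, emissions: np.ndarray, lengths: np.ndarray) -> list[list[int]]:
        """Viterbi decode each sentence of a padded batch of raw emissions."""
        params = self.numpy_params()
        out = []
        for row, ln in zip(emissions, lengths):
            tags, _ = viterbi_decode(np.asarray(row[:ln], dtype=float), params)
            out.append(tags)
        return out
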