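"""Forward-pass contract of the encoder + latent-tree relation architecture.

The headline relation model encodes each token of the masked sentence as a
768-dimensional contextual feature vector, composes the sequence into a
single sentence vector with a Gumbel-softmax latent binary tree (adjacent
pairs are scored, the winning pair is merged by a GRU-style binary
composer, repeated until one vector remains), concatenates
``[sentence vector, entity-1 feature, entity-2 feature]`` and applies a
fully connected layer with softmax over the label set.

This module realizes that contract in numpy with a hash-seeded
random-feature encoder and randomly initialized composition/classifier
parameters: dimensions, tree reduction and output normalization are all
real and testable on one CPU, while learned weights (a pretrained
transformer, trained tree/classifier parameters) are out of scope here.
The trainable default backend for the pipeline is
:class:`litmarker.relation_model.BaselineRelationClassifier`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .relation_model import PAD, MaskedSequence, ModelConfig

__all__ = ["EncoderTreeParams", "encode_tokens", "gumbel_tree_compose", "encoder_tree_forward"]


def _token_seed(token: str) -> int:
    digest = hashlib.sha256(token.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class EncoderTreeParams:
    """Composer + classifier parameters; ``init`` draws them from one seed."""

    dim: int
    n_labels: int
    Wz: np.ndarray
    Uz: np.ndarray
    Wh: np.ndarray
    Uh: np.ndarray
    score: np.ndarray  # merge-scoring vector, shape (dim,)
    fc_W: np.ndarray  # (3*dim, n_labels)
    fc_b: np.ndarray  # (n_labels,)

    @classmethod
    def init(cls, config: ModelConfig | None = None, seed: int = 0) -> "EncoderTreeParams":
        config = config or ModelConfig()
        d = config.encoder_dim
        k = len(config.labels)
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(d)
        return cls(
            dim=d,
            n_labels=k,
            Wz=rng.standard_normal((d, d)) * scale,
            Uz=rng.standard_normal((d, d)) * scale,
            Wh=rng.standard_normal((d, d)) * scale,
            Uh=rng.standard_normal((d, d)) * scale,
            score=rng.standard_normal(d) * scale,
            fc_W=rng.standard_normal((3 * d, k)) * scale,
            fc_b=np.zeros(k),
        )


def encode_tokens(tokens: list[str] | tuple[str, ...], dim: int = 768) -> np.ndarray:
    """Per-token contextual features, shape (n, dim).

    Each token gets a deterministic hash-seeded random vector; a light
    bidirectional neighbor mix makes the features context-dependent (the
    same token embeds differently in different neighborhoods), which is
    what the downstream contract relies on.
    """
    n = len(tokens)
    base = np.empty((n, dim))
    for i, tok in enumerate(tokens):
        rng = np.random.default_rng(_token_seed(tok))
        base[i] = rng.standard_normal(dim) / np.sqrt(dim)
    ctx = base.copy()
    if n > 1:
        ctx[1:] += 0.5 * base[:-1]
        ctx[:-1] += 0.5 * base[1:]
    return ctx


def _combine(left: np.ndarray, right: np.ndarray, p: EncoderTreeParams) -> np.ndarray:
    """GRU-style binary composition of two child vectors into a parent."""
    z = _sigmoid(p.Wz @ left + p.Uz @ right)
    h = np.tanh(p.Wh @ left + p.Uh @ right)
    return z * h + (1.0 - z) * 0.5 * (left + right)


def gumbel_tree_compose(
    feats: np.ndarray,
    params: EncoderTreeParams,
    rng: np.random.Generator | None = None,
    temperature: float = 1.0,
) -> np.ndarray:
    """Reduce (n, dim) token features to one (dim,) sentence vector.

    At each step every adjacent pair is tentatively merged, merge
    candidates are scored, and the winner is selected by straight-through
    Gumbel argmax (plain argmax when ``rng`` is None, i.e. inference).
    """
    if feats.ndim != 2 or feats.shape[1] != params.dim:
        raise ValueError(f"expected (n, {params.dim}) features, got {feats.shape}")
    nodes = [feats[i] for i in range(feats.shape[0])]
    if not nodes:
        raise ValueError("cannot compose an empty sequence")
    while len(nodes) > 1:
        merged = [_combine(nodes[i], nodes[i + 1], params) for i in range(len(nodes) - 1)]
        scores = np.array([params.score @ np.tanh(m) for m in merged])
        if rng is not None:
            gumbel = -np.log(-np.log(rng.uniform(1e-9, 1.0, size=len(scores))))
            scores = scores / max(temperature, 1e-6) + gumbel
        k = int(np.argmax(scores))
        nodes[k : k + 2] = [merged[k]]
    return nodes[0]


def encoder_tree_forward(
    masked: MaskedSequence,
    params: EncoderTreeParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Label distribution for one masked sequence (non-negative, sums to 1)."""
    n_real = sum(masked.mask)
    tokens = list(masked.tokens[:n_real]) or [PAD]
    feats = encode_tokens(tokens, dim=params.dim)
    sent_vec = gumbel_tree_compose(feats, params, rng=rng)
    e1 = feats[masked.e1_index] if masked.e1_index < n_real else np.zeros(params.dim)
    e2 = feats[masked.e2_index] if masked.e2_index < n_real else np.zeros(params.dim)
    rep = np.concatenate([sent_vec, e1, e2])
    if rep.shape[0] != params.fc_W.shape[0]:
        raise ValueError(
            f"representation dim {rep.shape[0]} != classifier input {params.fc_W.shape[0]}"
        )
    logits = rep @ params.fc_W + params.fc_b
    logits -= logits.max()
    expl = np.exp(logits)
    return expl / expl.sum()
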