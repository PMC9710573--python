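"""Sentence preprocessing and pluggable relation classification.

Every candidate pair is shaped into a fixed-length masked token sequence:
the two entity spans are replaced by type-specific marker tokens
(``DISEASE1``, ``MICROBIOME2``) so the classifier generalizes across entity
identities, and the sequence is truncated or padded to exactly
``max_len`` tokens (default 100). Truncation keeps a window containing both
markers, preferring the sentence prefix.

The default trainable backend is a lightweight linear model over sparse
token counts (logistic loss, epoch-wise SGD with per-epoch validation F1
and best-epoch selection) so the full pipeline trains and predicts on one
CPU in seconds. The transformer + latent-tree composition architecture is
an optional backend behind the same interface (see :mod:`litmarker.tree_composition`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from scipy import sparse
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import f1_score

from .entity_extraction import CandidatePair
from .weak_labeling import DatasetSplit, LabeledInstance

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "MaskedSequence",
    "RelationClassifier",
    "BaselineRelationClassifier",
    "Prediction",
    "mask_and_shape",
    "train",
    "predict_relation",
]

PAD = "[PAD]"


@dataclass(frozen=True)
class ModelConfig:
    """Shaping and training configuration.

    ``encoder_dim``, ``optimizer`` and ``learning_rate`` describe the
    transformer-backend contract (768-dim contextual features, AdamW); the
    sparse baseline consumes ``labels``, ``epochs``, ``batch_size`` and the
    seed and uses an optimal-schedule SGD internally.
    """

    max_len: int = 100
    encoder_dim: int = 768
    labels: tuple[str, ...] = ("negative", "positive")
    batch_size: int = 16
    learning_rate: float = 1e-5
    epochs: int = 50
    optimizer: str = "AdamW"

    def __post_init__(self) -> None:
        if self.max_len < 3:
            raise ValueError("max_len must be >= 3 (two markers + padding)")
        if len(self.labels) < 2:
            raise ValueError("label set must have >= 2 members")


@dataclass(frozen=True)
class MaskedSequence:
    """Fixed-length token sequence with entity markers and a padding mask."""

    tokens: tuple[str, ...]
    e1_index: int
    e2_index: int
    mask: tuple[int, ...]  # 1 = real token, 0 = padding (tail only)
    label: str | None = None

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.mask):
            raise ValueError("tokens and mask lengths differ")
        if not (0 <= self.e1_index < len(self.tokens)) or not (
            0 <= self.e2_index < len(self.tokens)
        ):
            raise ValueError("marker index out of range")


def _marker(entity_type, slot: int) -> str:
    return f"{entity_type.value.upper()}{slot}"


def mask_and_shape(
    instance: LabeledInstance | CandidatePair, config: ModelConfig | None = None
) -> MaskedSequence:
    """Replace entity spans with marker tokens; truncate/pad to max_len.

    The first-by-position span becomes marker 1. If tail truncation would
    drop the second marker, the window shifts right just enough to retain
    both; spans farther apart than max_len are an error.
    """
    config = config or ModelConfig()
    label: str | None = None
    if isinstance(instance, LabeledInstance):
        label = instance.label
        pair = instance.pair
    else:
        pair = instance
    m1, m2 = pair.mention1, pair.mention2
    if not (m1.token_end <= m2.token_start or m2.token_end <= m1.token_start):
        raise ValueError("entity spans overlap")
    if m2.token_start < m1.token_start:
        m1, m2 = m2, m1
    toks = pair.sentence.token_texts()
    out: list[str] = []
    out.extend(toks[: m1.token_start])
    e1 = len(out)
    out.append(_marker(m1.entity_type, 1))
    out.extend(toks[m1.token_end : m2.token_start])
    e2 = len(out)
    out.append(_marker(m2.entity_type, 2))
    out.extend(toks[m2.token_end :])
    if e2 - e1 + 1 > config.max_len:
        raise ValueError(
            f"entity markers {e2 - e1} tokens apart cannot both fit in max_len={config.max_len}"
        )
    start = 0 if e2 < config.max_len else e2 - config.max_len + 1
    window = out[start : start + config.max_len]
    e1 -= start
    e2 -= start
    n_real = len(window)
    window.extend([PAD] * (config.max_len - n_real))
    mask = (1,) * n_real + (0,) * (config.max_len - n_real)
    return MaskedSequence(
        tokens=tuple(window), e1_index=e1, e2_index=e2, mask=mask, label=label
    )


@dataclass(frozen=True)
class Prediction:
    label: str
    confidence: float
    distribution: dict[str, float]


class RelationClassifier(Protocol):
    """Interface every backend implements."""

    def fit(
        self,
        train: Sequence[MaskedSequence],
        validation: Sequence[MaskedSequence],
        seed: int = 0,
    ) -> list[dict]: ...

    def predict_proba(self, masked: MaskedSequence) -> np.ndarray: ...


class BaselineRelationClassifier:
    """Linear model on sparse token counts of the masked sequence.

    Unigram counts over non-pad tokens (markers included) feed a logistic
    regression trained by minibatch SGD; validation macro-F1 is recorded
    each epoch and the best-epoch weights are kept. Deterministic under a
    fixed seed.
    """

    def __init__(self, config: ModelConfig | None = None) -> None:
        self.config = config or ModelConfig()
        self.vocab_: dict[str, int] | None = None
        self.clf_: SGDClassifier | None = None
        self.history_: list[dict] = []

    def _featurize(self, seqs: Sequence[MaskedSequence]) -> sparse.csr_matrix:
        assert self.vocab_ is not None
        rows, cols, data = [], [], []
        for r, seq in enumerate(seqs):
            for tok, real in zip(seq.tokens, seq.mask):
                if not real:
                    break
                j = self.vocab_.get(tok.casefold())
                if j is not None:
                    rows.append(r)
                    cols.append(j)
                    data.append(1.0)
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(seqs), len(self.vocab_))
        )

    def fit(
        self,
        train: Sequence[MaskedSequence],
        validation: Sequence[MaskedSequence],
        seed: int = 0,
    ) -> list[dict]:
        labels = sorted({s.label for s in train if s.label is not None})
        if len(labels) < 2:
            raise ValueError("training data contains a single label")
        unknown = set(labels) - set(self.config.labels)
        if unknown:
            raise ValueError(f"labels {unknown} not in configured label set")
        vocab: dict[str, int] = {}
        for seq in train:
            for tok, real in zip(seq.tokens, seq.mask):
                if not real:
                    break
                vocab.setdefault(tok.casefold(), len(vocab))
        self.vocab_ = vocab
        X = self._featurize(train)
        y = np.array([s.label for s in train])
        Xv = self._featurize(validation) if len(validation) else None
        yv = np.array([s.label for s in validation]) if len(validation) else None
        rng = np.random.RandomState(seed)
        clf = SGDClassifier(
            loss="log_loss",
            alpha=1e-4,
            learning_rate="optimal",
            random_state=seed,
            warm_start=True,
        )
        classes = np.array(labels)
        self.history_ = []
        best = (-1.0, None, None)
        n = X.shape[0]
        bs = max(1, self.config.batch_size)
        for epoch in range(self.config.epochs):
            order = rng.permutation(n)
            for lo in range(0, n, bs):
                idx = order[lo : lo + bs]
                clf.partial_fit(X[idx], y[idx], classes=classes)
            if Xv is not None and Xv.shape[0]:
                val_f1 = float(f1_score(yv, clf.predict(Xv), average="macro"))
            else:
                val_f1 = float(f1_score(y, clf.predict(X), average="macro"))
            self.history_.append({"epoch": epoch, "val_f1": val_f1})
            if val_f1 > best[0]:
                best = (val_f1, clf.coef_.copy(), clf.intercept_.copy())
        if best[1] is not None:
            clf.coef_ = best[1]
            clf.intercept_ = best[2]
        self.clf_ = clf
        return self.history_

    def predict_proba(self, masked: MaskedSequence) -> np.ndarray:
        """Distribution over ``config.labels`` (zeros for labels unseen in training)."""
        if self.clf_ is None or self.vocab_ is None:
            raise RuntimeError("classifier is not fitted")
        if len(masked.tokens) != self.config.max_len:
            raise ValueError(
                f"sequence length {len(masked.tokens)} != configured max_len {self.config.max_len}"
            )
        X = self._featurize([masked])
        proba = self.clf_.predict_proba(X)[0]
        out = np.zeros(len(self.config.labels))
        for p, cls in zip(proba, self.clf_.classes_):
            out[self.config.labels.index(cls)] = p
        s = out.sum()
        return out / s if s > 0 else np.full(len(out), 1.0 / len(out))


def train(
    classifier: RelationClassifier,
    datasets: DatasetSplit,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> tuple[RelationClassifier, list[dict]]:
    """Mask/shape both splits and fit; returns (fitted classifier, F1 history)."""
    config = config or ModelConfig()
    if not datasets.train or not datasets.validation:
        raise ValueError("train and validation sets must both be non-empty")
    train_seqs = [mask_and_shape(i, config) for i in datasets.train]
    val_seqs = [mask_and_shape(i, config) for i in datasets.validation]
    history = classifier.fit(train_seqs, val_seqs, seed=seed)
    return classifier, history


def predict_relation(
    classifier: RelationClassifier, masked: MaskedSequence, config: ModelConfig | None = None
) -> Prediction:
    """Label distribution + argmax exported as the assertion confidence."""
    config = config or getattr(classifier, "config", None) or ModelConfig()
    proba = np.asarray(classifier.predict_proba(masked), dtype=float)
    if len(proba) != len(config.labels):
        raise ValueError("probability vector does not match configured label set")
    dist = {lab: float(p) for lab, p in zip(config.labels, proba)}
    best = int(np.argmax(proba))
    return Prediction(
        label=config.labels[best], confidence=float(proba[best]), distribution=dist
    )
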