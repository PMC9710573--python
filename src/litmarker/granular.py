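"""Granular relation typing of positive disease-biomarker pairs.

Once the binary stage asserts an association, sentences are screened with
cue-term lists (e.g. "risk", "survival"); screened pairs matching a
knowledge-base triple receive that triple's label by distant supervision,
yielding training data for a five-way classifier over
Predictive / Prognostic / Diagnostic / Predisposing / Treatment. Cue lists
can be expanded with nearest neighbors from any word-vector provider.
Screening is label-agnostic (any cue passes the gate); the classifier
decides the label, with an optional confidence-thresholded NA abstention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .entity_extraction import CandidatePair
from .relation_model import MaskedSequence, ModelConfig, Prediction, RelationClassifier, mask_and_shape, predict_relation
from .weak_labeling import LabeledInstance

logger = logging.getLogger(__name__)

__all__ = [
    "GranularLabel",
    "SearchTermList",
    "KnowledgeBase",
    "ScreenedCandidate",
    "screen_sentences",
    "expand_cues",
    "distant_label",
    "classify_granular",
    "load_cue_list",
    "load_knowledge_base",
    "granular_model_config",
]


class GranularLabel(str, Enum):
    """The five specific disease-biomarker relation types."""

    PREDICTIVE = "Predictive"
    PROGNOSTIC = "Prognostic"
    DIAGNOSTIC = "Diagnostic"
    PREDISPOSING = "Predisposing"
    TREATMENT = "Treatment"


def granular_model_config(**overrides) -> ModelConfig:
    """ModelConfig with the five granular labels."""
    defaults = dict(labels=tuple(l.value for l in GranularLabel), batch_size=32,
                    learning_rate=3e-5, epochs=10)
    defaults.update(overrides)
    return ModelConfig(**defaults)


@dataclass(frozen=True)
class SearchTermList:
    """Cue terms that flag a potentially specific relation.

    ``by_label`` optionally records which label a cue came from; screening
    itself ignores it.
    """

    terms: tuple[str, ...]
    by_label: Mapping[str, tuple[str, ...]] | None = None
    similarity_threshold: float = 0.8
    top_k: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "terms", tuple(dict.fromkeys(t.casefold() for t in self.terms))
        )

    def __contains__(self, token: str) -> bool:
        return token.casefold() in self.terms


def load_cue_list(path: str | Path) -> SearchTermList:
    """One cue per line; an optional tab-separated second column gives its label."""
    terms: list[str] = []
    by_label: dict[str, list[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        terms.append(parts[0])
        if len(parts) > 1:
            by_label.setdefault(parts[1], []).append(parts[0])
    if not terms:
        raise ValueError(f"{path}: empty cue list")
    return SearchTermList(
        terms=tuple(terms),
        by_label={k: tuple(v) for k, v in by_label.items()} or None,
    )


@dataclass(frozen=True)
class ScreenedCandidate:
    pair: CandidatePair
    cue: str


def screen_sentences(
    candidates: Sequence[CandidatePair], cues: SearchTermList
) -> list[ScreenedCandidate]:
    """Keep candidates whose sentence contains a cue token (case-insensitive).

    Matching is token-level, so a cue never fires as a substring of a
    longer word ("risk" does not match "risky"). The first firing cue per
    sentence is recorded.
    """
    if not cues.terms:
        raise ValueError("empty cue list")
    out: list[ScreenedCandidate] = []
    for cand in candidates:
        fired = next(
            (t.text for t in cand.sentence.tokens if t.text.casefold() in cues.terms),
            None,
        )
        if fired is not None:
            out.append(ScreenedCandidate(pair=cand, cue=fired))
    return out


def expand_cues(
    cues: SearchTermList,
    vectors: Mapping[str, np.ndarray],
    threshold: float | None = None,
    top_k: int | None = None,
) -> SearchTermList:
    """Add each cue's nearest word-vector neighbors above a cosine threshold.

    ``vectors`` is any mapping word -> 1-D array; cues absent from it are
    skipped with a warning; additions are deduplicated against the list.
    """
    threshold = cues.similarity_threshold if threshold is None else threshold
    top_k = cues.top_k if top_k is None else top_k
    vocab = sorted(vectors)
    added: list[str] = []
    for cue in cues.terms:
        if cue not in vectors:
            logger.warning("cue %r missing from vector vocabulary -- skipped", cue)
            continue
        v = np.asarray(vectors[cue], dtype=float)
        nv = np.linalg.norm(v)
        sims: list[tuple[float, str]] = []
        for word in vocab:
            if word.casefold() == cue:
                continue
            w = np.asarray(vectors[word], dtype=float)
            denom = nv * np.linalg.norm(w)
            if denom == 0:
                continue
            cos = float(v @ w / denom)
            if cos >= threshold:
                sims.append((cos, word))
        sims.sort(key=lambda t: (-t[0], t[1]))
        for _, word in sims[:top_k]:
            if word.casefold() not in cues.terms and word.casefold() not in added:
                added.append(word.casefold())
    return SearchTermList(
        terms=cues.terms + tuple(added),
        by_label=cues.by_label,
        similarity_threshold=cues.similarity_threshold,
        top_k=cues.top_k,
    )


@dataclass
class KnowledgeBase:
    """Known (entityA, relation, entityB) triples for distant supervision."""

    triples: set[tuple[str, str, str]] = field(default_factory=set)
    source: str = ""

    def __post_init__(self) -> None:
        valid = {l.value for l in GranularLabel}
        for a, label, b in self.triples:
            if label not in valid:
                raise ValueError(f"triple ({a}, {label}, {b}): unknown granular label")

    def labels_for(self, id_a: str, id_b: str) -> list[str]:
        out = {
            label
            for (a, label, b) in self.triples
            if {a, b} == {id_a, id_b} or (a == id_a and b == id_b)
        }
        return sorted(out)

    def __len__(self) -> int:
        return len(self.triples)


def load_knowledge_base(path: str | Path) -> KnowledgeBase:
    """TSV: entityA_id, label, entityB_id, source."""
    triples: set[tuple[str, str, str]] = set()
    sources: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            logger.warning("%s: malformed KB row %r skipped", path, line[:60])
            continue
        triples.add((parts[0], parts[1], parts[2]))
        if len(parts) > 3:
            sources.add(parts[3])
    return KnowledgeBase(triples=triples, source=",".join(sorted(sources)))


def distant_label(
    screened: Sequence[ScreenedCandidate], kb: KnowledgeBase
) -> list[LabeledInstance]:
    """Label screened sentences by KB lookup on their entity pair.

    Pairs carrying multiple KB labels are emitted once per label with a
    conflict flag; pairs absent from the KB yield nothing.
    """
    if len(kb) == 0:
        raise ValueError("empty knowledge base")
    out: list[LabeledInstance] = []
    for sc in screened:
        labels = kb.labels_for(sc.pair.mention1.term_id, sc.pair.mention2.term_id)
        for label in labels:
            out.append(
                LabeledInstance(
                    pair=sc.pair,
                    label=label,
                    provenance="distant",
                    cue=sc.cue,
                    conflict=len(labels) > 1,
                    kb_source=kb.source or None,
                )
            )
    return out


def classify_granular(
    classifier: RelationClassifier,
    screened: ScreenedCandidate | CandidatePair,
    config: ModelConfig | None = None,
    na_threshold: float | None = 0.5,
) -> Prediction:
    """Predict one of the five granular labels for a screened sentence.

    When the best probability falls below ``na_threshold`` the prediction
    abstains with label "NA" (set ``na_threshold=None`` to always commit).
    """
    config = config or getattr(classifier, "config", None) or granular_model_config()
    pair = screened.pair if isinstance(screened, ScreenedCandidate) else screened
    masked = mask_and_shape(pair, config)
    pred = predict_relation(classifier, masked, config)
    if na_threshold is not None and pred.confidence < na_threshold:
        return Prediction(label="NA", confidence=pred.confidence, distribution=pred.distribution)
    return pred
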