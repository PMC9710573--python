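"""Unsupervised training-data generation from sentence-level co-occurrence.

The generator turns an extracted corpus into binary training data with no
manual annotation. A sentence-level co-occurrence matrix is built over
typed entity pairs; pairs co-occurring at least ``t1`` times (default 10)
donate up to ``t2`` sentences (default 50) as positive instances, while
frequency-one pairs donate negatives — except sentences containing exactly
one disease and one biomarker mention, which are more likely true
positives and are excluded. The assembled dataset is balanced to a 6:4
positive:negative ratio and split 8:2 into training and validation sets,
all under one seeded random stream.
"""

from __future__ import annotations

import json
import logging
import random
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .entity_extraction import (
    CandidatePair,
    EntityMention,
    Sentence,
    candidate_pairs,
    split_and_tokenize,
)
from .lexicon import EntityType

logger = logging.getLogger(__name__)

__all__ = [
    "LabelingConfig",
    "LabeledInstance",
    "CooccurrenceMatrix",
    "build_matrix",
    "generate_positive",
    "generate_negative",
    "assemble_dataset",
    "DatasetSplit",
    "save_instances_jsonl",
    "load_instances_jsonl",
]

PairKey = tuple[tuple[str, str], tuple[str, str]]
SentKey = tuple[str, int]


@dataclass(frozen=True)
class LabelingConfig:
    """Thresholds and ratios of the automatic labeler.

    t1: minimum co-occurrence count for a pair to donate positives.
    t2: truncating quantity — at most this many sentences kept per pair,
        preventing bias toward very frequent pairs.
    """

    t1: int = 10
    t2: int = 50
    positive_ratio: int = 6
    negative_ratio: int = 4
    train_ratio: int = 8
    validation_ratio: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t1 < 1 or self.t2 < 1:
            raise ValueError("t1 and t2 must be >= 1")
        for v in (self.positive_ratio, self.negative_ratio, self.train_ratio, self.validation_ratio):
            if v <= 0:
                raise ValueError("ratio components must be positive")


@dataclass(frozen=True)
class LabeledInstance:
    """A (sentence, entity pair) unit with a binary or granular label."""

    pair: CandidatePair
    label: str
    provenance: str  # auto | distant | manual
    cue: str | None = None
    conflict: bool = False
    kb_source: str | None = None

    @property
    def sentence(self) -> Sentence:
        return self.pair.sentence


class CooccurrenceMatrix:
    """Sentence-level co-occurrence counts per unordered typed entity pair.

    ``count(a, b)`` is the number of distinct sentences containing both
    entities; each stored pair keeps one representative
    :class:`CandidatePair` per sentence plus the per-sentence mention
    census used by the negative rule.
    """

    def __init__(self) -> None:
        self._pairs: dict[PairKey, dict[SentKey, CandidatePair]] = {}
        self.sentence_census: dict[SentKey, Counter[EntityType]] = {}

    def add_pair(self, pair: CandidatePair) -> None:
        skey = (pair.sentence.doc_id, pair.sentence.sent_index)
        self._pairs.setdefault(pair.key(), {}).setdefault(skey, pair)

    def record_census(self, sentence: Sentence, mentions: Sequence[EntityMention]) -> None:
        skey = (sentence.doc_id, sentence.sent_index)
        self.sentence_census[skey] = Counter(m.entity_type for m in mentions)

    def count(self, key: PairKey) -> int:
        return len(self._pairs.get(key, {}))

    @property
    def counts(self) -> dict[PairKey, int]:
        return {k: len(v) for k, v in self._pairs.items()}

    def sentences_for(self, key: PairKey) -> list[CandidatePair]:
        return [self._pairs[key][sk] for sk in sorted(self._pairs[key])]

    def argmax(self) -> PairKey:
        return max(self._pairs, key=lambda k: (len(self._pairs[k]), k))

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, key: PairKey) -> bool:
        return key in self._pairs


def build_matrix(
    extracted: Iterable[tuple[Sentence, Sequence[EntityMention]]],
    type_pair: tuple[EntityType, EntityType],
) -> CooccurrenceMatrix:
    """Count pair co-occurrence at sentence granularity.

    Exactly one increment per (sentence, pair) no matter how many times the
    entities repeat within the sentence.
    """
    matrix = CooccurrenceMatrix()
    for sentence, mentions in extracted:
        matrix.record_census(sentence, mentions)
        for pair in candidate_pairs(mentions, sentence, type_pair):
            matrix.add_pair(pair)
    return matrix


def generate_positive(
    matrix: CooccurrenceMatrix, config: LabelingConfig | None = None
) -> list[LabeledInstance]:
    """Positive instances from pairs with count >= t1, truncated at t2 per pair.

    Selection beyond t2 is seeded uniform sampling without replacement.
    """
    config = config or LabelingConfig()
    rng = random.Random(config.seed)
    out: list[LabeledInstance] = []
    for key in sorted(matrix.counts):
        n = matrix.count(key)
        if n < config.t1:
            continue
        sentences = matrix.sentences_for(key)
        if n > config.t2:
            sentences = rng.sample(sentences, config.t2)
        out.extend(
            LabeledInstance(pair=p, label="positive", provenance="auto") for p in sentences
        )
    if not out:
        logger.warning("no pair reached t1=%d: empty positive set", config.t1)
    return out


def _is_excluded_negative(
    census: Counter[EntityType], type_pair: tuple[EntityType, EntityType]
) -> bool:
    """Exclusion predicate for negative sourcing.

    True when the sentence's entity content is exactly one mention of each
    pair type and nothing else (two entities total) — such sentences are
    more likely to express a true association. The alternative reading
    (count only the pair's own types) is a one-line change here.
    """
    ta, tb = type_pair
    return sum(census.values()) == 2 and census[ta] == 1 and census[tb] == 1


def generate_negative(
    matrix: CooccurrenceMatrix,
    type_pair: tuple[EntityType, EntityType],
) -> list[LabeledInstance]:
    """Negative instances from frequency-one pairs, minus the excluded census."""
    out: list[LabeledInstance] = []
    for key in sorted(matrix.counts):
        if matrix.count(key) != 1:
            continue
        for pair in matrix.sentences_for(key):
            skey = (pair.sentence.doc_id, pair.sentence.sent_index)
            census = matrix.sentence_census.get(skey, Counter())
            if _is_excluded_negative(census, type_pair):
                continue
            out.append(LabeledInstance(pair=pair, label="negative", provenance="auto"))
    return out


@dataclass
class DatasetSplit:
    train: list[LabeledInstance]
    validation: list[LabeledInstance]


def _instance_sort_key(inst: LabeledInstance) -> tuple:
    return (
        inst.sentence.doc_id,
        inst.sentence.sent_index,
        inst.pair.key(),
        inst.label,
    )


def assemble_dataset(
    positives: Sequence[LabeledInstance],
    negatives: Sequence[LabeledInstance],
    config: LabelingConfig | None = None,
) -> DatasetSplit:
    """Balance to the configured positive:negative ratio, then split stratified.

    The majority side is downsampled (seeded) to within one instance of the
    ratio; the result is split train:validation stratified by label.
    Deterministic under a fixed seed.
    """
    config = config or LabelingConfig()
    if not positives:
        raise ValueError("no positive instances: cannot assemble dataset")
    if not negatives:
        raise ValueError("no negative instances: cannot assemble dataset")
    rng = random.Random(config.seed + 1)
    pos = sorted(positives, key=_instance_sort_key)
    neg = sorted(negatives, key=_instance_sort_key)
    r = config.positive_ratio / config.negative_ratio
    # downsample whichever side exceeds the target ratio
    if len(neg) > round(len(pos) / r):
        neg = rng.sample(neg, max(1, round(len(pos) / r)))
    elif len(pos) > round(len(neg) * r):
        pos = rng.sample(pos, max(1, round(len(neg) * r)))
    train: list[LabeledInstance] = []
    val: list[LabeledInstance] = []
    frac = config.train_ratio / (config.train_ratio + config.validation_ratio)
    for side in (pos, neg):
        side = sorted(side, key=_instance_sort_key)
        rng.shuffle(side)
        cut = round(frac * len(side))
        train.extend(side[:cut])
        val.extend(side[cut:])
    rng.shuffle(train)
    rng.shuffle(val)
    return DatasetSplit(train=train, validation=val)


def _instance_to_record(inst: LabeledInstance) -> dict:
    p = inst.pair
    return {
        "doc_id": p.sentence.doc_id,
        "sent_index": p.sentence.sent_index,
        "text": p.sentence.text,
        "e1_span": [p.mention1.token_start, p.mention1.token_end],
        "e1_type": p.mention1.entity_type.value,
        "e1_id": p.mention1.term_id,
        "e2_span": [p.mention2.token_start, p.mention2.token_end],
        "e2_type": p.mention2.entity_type.value,
        "e2_id": p.mention2.term_id,
        "label": inst.label,
        "provenance": inst.provenance,
    }


def save_instances_jsonl(instances: Iterable[LabeledInstance], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for inst in instances:
            fh.write(json.dumps(_instance_to_record(inst), sort_keys=True) + "\n")


def load_instances_jsonl(path: str | Path) -> list[LabeledInstance]:
    """Reload exported instances; sentences are re-tokenized from stored text."""
    out: list[LabeledInstance] = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            sents = split_and_tokenize(rec["text"], doc_id=rec["doc_id"])
            if not sents:
                continue
            sent = Sentence(
                doc_id=rec["doc_id"],
                sent_index=rec["sent_index"],
                text=sents[0].text,
                tokens=sents[0].tokens,
            )
            mentions = []
            for slot in ("e1", "e2"):
                i, j = rec[f"{slot}_span"]
                c0 = sent.tokens[i].start
                c1 = sent.tokens[j - 1].end
                mentions.append(
                    EntityMention(
                        term_id=rec[f"{slot}_id"],
                        entity_type=EntityType(rec[f"{slot}_type"]),
                        doc_id=sent.doc_id,
                        sent_index=sent.sent_index,
                        token_start=i,
                        token_end=j,
                        char_start=c0,
                        char_end=c1,
                        surface=sent.text[c0:c1],
                    )
                )
            pair = CandidatePair(sentence=sent, mention1=mentions[0], mention2=mentions[1])
            out.append(
                LabeledInstance(pair=pair, label=rec["label"], provenance=rec["provenance"])
            )
    return out
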