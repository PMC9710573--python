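"""Co-occurrence matrix and automatic label generation."""

import itertools
import random

import pytest

from litmarker.entity_extraction import candidate_pairs, extract_document
from litmarker.lexicon import EntityType, build_automaton
from litmarker.synthetic import CorpusSpec, generate
from litmarker.weak_labeling import (
    LabelingConfig,
    assemble_dataset,
    build_matrix,
    generate_negative,
    generate_positive,
)

PAIR = (EntityType.DISEASE, EntityType.MICROBIOME)


def _extract_corpus(corpus):
    auto = build_automaton(list(corpus.term_lists.values()))
    out = []
    for doc in corpus.documents:
        out.extend(extract_document(doc["doc_id"], doc["text"], auto))
    return out


def _brute_force_counts(extracted):
    """Oracle: double loop over sentences, one increment per (sentence, pair)."""
    counts = {}
    for sentence, mentions in extracted:
        seen = set()
        for p in candidate_pairs(mentions, sentence, PAIR):
            if p.key() not in seen:
                seen.add(p.key())
                counts[p.key()] = counts.get(p.key(), 0) + 1
    return counts


@pytest.fixture(scope="module")
def skewed_corpus():
    # one dominant pair far above all others, a mid pair, and a freq-1 tail
    spec = CorpusSpec(
        seed=3,
        n_docs=25,
        pair_counts=((0, 0, 60), (1, 1, 12), (2, 2, 9)),
        n_negative_triples=8,
        n_excluded_negatives=3,
        max_sentences_per_doc=400,
    )
    return generate(spec)


@pytest.fixture(scope="module")
def skewed_matrix(skewed_corpus):
    return build_matrix(_extract_corpus(skewed_corpus), PAIR)


class TestBuildMatrix:
    def test_sentence_level_counting_ignores_repeats(self, automaton, disease_terms):
        # the same pair twice in one sentence counts once
        doc = (
            "Gastroenteritis with Vibrio parahaemolyticus resembled gastroenteritis "
            "after Vibrio parahaemolyticus exposure. "
            "Gastroenteritis followed Vibrio parahaemolyticus. "
            "Gastroenteritis involved Vibrio parahaemolyticus."
        )
        extracted = extract_document("d", doc, automaton)
        m = build_matrix(extracted, PAIR)
        key = (("disease", "D:GE"), ("microbiome", "M:VP"))
        assert m.count(key) == 3

    def test_dominant_pair_is_argmax(self, skewed_matrix):
        (a, b) = skewed_matrix.argmax()
        assert {a[1], b[1]} == {"D000", "M000"}
        assert skewed_matrix.count(skewed_matrix.argmax()) == 60

    def test_matrix_equals_brute_force_recount(self, skewed_corpus, skewed_matrix):
        extracted = _extract_corpus(skewed_corpus)
        assert skewed_matrix.counts == _brute_force_counts(extracted)

    def test_random_corpora_equal_brute_force(self):
        rng = random.Random(17)
        for trial in range(3):
            pairs = tuple(
                (rng.randrange(6), rng.randrange(6), rng.randint(1, 8)) for _ in range(4)
            )
            # drop duplicate (d, m) plants
            seen, dedup = set(), []
            for d, m, c in pairs:
                if (d, m) not in seen:
                    seen.add((d, m))
                    dedup.append((d, m, c))
            spec = CorpusSpec(seed=100 + trial, n_docs=6, pair_counts=tuple(dedup))
            corpus = generate(spec)
            extracted = _extract_corpus(corpus)
            assert build_matrix(extracted, PAIR).counts == _brute_force_counts(extracted)


class TestGeneratePositive:
    def test_truncation_at_t2(self):
        corpus = generate(
            CorpusSpec(seed=4, n_docs=20, pair_counts=((0, 0, 200),), max_sentences_per_doc=400)
        )
        m = build_matrix(_extract_corpus(corpus), PAIR)
        pos = generate_positive(m, LabelingConfig())
        assert len(pos) == 50  # t2 caps a count-200 pair at 50 sentences

    def test_t1_boundary(self, skewed_matrix):
        pos = generate_positive(skewed_matrix, LabelingConfig())
        by_pair = {}
        for inst in pos:
            by_pair.setdefault(inst.pair.key(), []).append(inst)
        ids = {frozenset((a[1], b[1])) for (a, b) in by_pair}
        # count 60 and count 12 qualify; count 9 and the freq-1 tail do not
        assert frozenset({"D000", "M000"}) in ids
        assert frozenset({"D001", "M001"}) in ids
        assert frozenset({"D002", "M002"}) not in ids
        assert len(by_pair[min(by_pair, key=lambda k: len(by_pair[k]))]) == 12

    def test_count_exactly_t1_all_kept(self):
        corpus = generate(CorpusSpec(seed=5, n_docs=5, pair_counts=((0, 0, 10),)))
        m = build_matrix(_extract_corpus(corpus), PAIR)
        assert len(generate_positive(m, LabelingConfig())) == 10

    def test_no_pair_reaches_t1(self):
        corpus = generate(CorpusSpec(seed=6, n_docs=5, pair_counts=((0, 0, 3),)))
        m = build_matrix(_extract_corpus(corpus), PAIR)
        assert generate_positive(m, LabelingConfig()) == []

    def test_every_positive_pair_reaches_t1_and_capped(self, skewed_matrix):
        cfg = LabelingConfig()
        pos = generate_positive(skewed_matrix, cfg)
        by_pair = {}
        for inst in pos:
            by_pair.setdefault(inst.pair.key(), []).append(inst)
        for key, insts in by_pair.items():
            assert skewed_matrix.count(key) >= cfg.t1
            assert len(insts) <= cfg.t2


class TestGenerateNegative:
    def test_triple_sentences_are_negatives(self, skewed_matrix):
        negs = generate_negative(skewed_matrix, PAIR)
        assert len(negs) == 16  # 8 triples x 2 freq-1 pairs; excluded sentences dropped
        for inst in negs:
            assert skewed_matrix.count(inst.pair.key()) == 1

    def test_two_entity_sentences_excluded(self, skewed_matrix, skewed_corpus):
        negs = generate_negative(skewed_matrix, PAIR)
        neg_sents = {(i.sentence.doc_id, i.sentence.sent_index) for i in negs}
        excluded = {
            (doc_id, idx)
            for doc_id, idx, d, m, label, cue in skewed_corpus.truth.instances
            if label == "negative"
            and skewed_matrix.sentence_census[(doc_id, idx)].total() == 2
        }
        assert excluded and not (neg_sents & excluded)

    def test_high_frequency_pair_never_negative(self, skewed_matrix):
        negs = generate_negative(skewed_matrix, PAIR)
        ids = {frozenset((a[1], b[1])) for (a, b) in (i.pair.key() for i in negs)}
        assert frozenset({"D000", "M000"}) not in ids


class TestAssembleDataset:
    def _insts(self, skewed_matrix):
        pos = generate_positive(skewed_matrix, LabelingConfig())
        neg = generate_negative(skewed_matrix, PAIR)
        return pos, neg

    def test_ratio_and_split(self):
        corpus = generate(
            CorpusSpec(
                seed=7,
                n_docs=40,
                pair_counts=tuple((i, i, 20) for i in range(5)),
                n_negative_triples=60,
                max_sentences_per_doc=400,
            )
        )
        m = build_matrix(_extract_corpus(corpus), PAIR)
        pos = generate_positive(m, LabelingConfig())
        neg = generate_negative(m, PAIR)
        assert len(neg) > len(pos) * 4 / 6  # surplus negatives
        split = assemble_dataset(pos, neg, LabelingConfig())
        allinst = split.train + split.validation
        n_pos = sum(1 for i in allinst if i.label == "positive")
        n_neg = len(allinst) - n_pos
        assert abs(n_pos / 6 - n_neg / 4) * 4 <= 1  # 6:4 within one instance
        # stratified 8:2
        frac = len(split.train) / len(allinst)
        assert abs(frac - 0.8) < 0.02
        tr_pos = sum(1 for i in split.train if i.label == "positive")
        assert abs(tr_pos - 0.8 * n_pos) <= 1

    def test_already_at_ratio_unchanged(self, skewed_matrix):
        pos, neg = self._insts(skewed_matrix)
        pos, neg = pos[:24], neg[:16]
        split = assemble_dataset(pos, neg, LabelingConfig())
        assert len(split.train) + len(split.validation) == 40

    def test_deterministic_under_seed(self, skewed_matrix):
        pos, neg = self._insts(skewed_matrix)
        cfg = LabelingConfig(seed=9)
        s1 = assemble_dataset(pos, neg, cfg)
        s2 = assemble_dataset(pos, neg, cfg)
        assert s1.train == s2.train and s1.validation == s2.validation

    def test_disjoint_and_complete(self, skewed_matrix):
        pos, neg = self._insts(skewed_matrix)
        split = assemble_dataset(pos, neg, LabelingConfig())
        train_keys = {(id(i)) for i in split.train}
        val_keys = {(id(i)) for i in split.validation}
        assert not (train_keys & val_keys)
        assert set(map(id, split.train + split.validation)) <= set(map(id, pos + neg))

    def test_empty_side_errors(self, skewed_matrix):
        pos, neg = self._insts(skewed_matrix)
        with pytest.raises(ValueError, match="positive"):
            assemble_dataset([], neg)
        with pytest.raises(ValueError, match="negative"):
            assemble_dataset(pos, [])
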