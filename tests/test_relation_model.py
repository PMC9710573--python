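"""Masking/shaping, baseline training, prediction and the architecture contract."""

import random

import numpy as np
import pytest

from litmarker.relation_model import (
    PAD,
    BaselineRelationClassifier,
    MaskedSequence,
    ModelConfig,
    mask_and_shape,
    predict_relation,
    train,
)
from litmarker.tree_composition import EncoderTreeParams, encode_tokens, gumbel_tree_compose, encoder_tree_forward
from litmarker.synthetic import BINARY_CUES, generate_instances
from litmarker.weak_labeling import DatasetSplit


@pytest.fixture(scope="module")
def binary_instances():
    return generate_instances(BINARY_CUES, 250, seed=21)


@pytest.fixture(scope="module")
def fitted(binary_instances):
    cfg = ModelConfig(epochs=8)
    split = DatasetSplit(train=binary_instances[:400], validation=binary_instances[400:])
    clf = BaselineRelationClassifier(cfg)
    _, history = train(clf, split, cfg, seed=0)
    return clf, cfg, split, history


class TestMaskAndShape:
    def test_padded_to_exact_max_len(self, binary_instances):
        cfg = ModelConfig()
        seq = mask_and_shape(binary_instances[0], cfg)
        assert len(seq.tokens) == 100
        assert len(seq.mask) == 100
        n_real = sum(seq.mask)
        assert seq.tokens[n_real:] == (PAD,) * (100 - n_real)  # padding only at tail

    def test_exactly_one_marker_per_entity(self, binary_instances):
        seq = mask_and_shape(binary_instances[0], ModelConfig())
        markers = [t for t in seq.tokens if t in ("DISEASE1", "DISEASE2", "MICROBIOME1", "MICROBIOME2")]
        assert len(markers) == 2
        assert seq.tokens[seq.e1_index] in ("DISEASE1", "MICROBIOME1")
        assert seq.tokens[seq.e2_index] in ("DISEASE2", "MICROBIOME2")

    def test_span_collapses_to_single_marker(self, binary_instances):
        # multi-token entity spans become one marker: length shrinks accordingly
        inst = binary_instances[0]
        pair = inst.pair
        n_tokens = len(pair.sentence.tokens)
        span_lens = (
            pair.mention1.token_end - pair.mention1.token_start,
            pair.mention2.token_end - pair.mention2.token_start,
        )
        seq = mask_and_shape(inst, ModelConfig())
        assert sum(seq.mask) == n_tokens - sum(span_lens) + 2

    def test_long_sentence_truncated_markers_kept(self, binary_instances):
        inst = binary_instances[0]
        pair = inst.pair
        # graft a long tail: entities sit in the first 40 tokens of a 250-token sentence
        from litmarker.entity_extraction import CandidatePair, split_and_tokenize

        long_text = pair.sentence.text + " filler" * 250 + "."
        sent = split_and_tokenize(long_text, doc_id="long")[0]
        long_pair = CandidatePair(
            sentence=sent, mention1=pair.mention1, mention2=pair.mention2
        )
        seq = mask_and_shape(long_pair, ModelConfig())
        assert len(seq.tokens) == 100
        assert sum(seq.mask) == 100
        assert seq.tokens[seq.e1_index].endswith("1")
        assert seq.tokens[seq.e2_index].endswith("2")

    def test_markers_too_far_apart_error(self, binary_instances):
        inst = binary_instances[0]
        pair = inst.pair
        from litmarker.entity_extraction import CandidatePair, EntityMention, split_and_tokenize

        text = pair.sentence.text[: pair.sentence.tokens[-2].start] + " pad" * 150 + " tail."
        sent = split_and_tokenize(text, doc_id="far")[0]
        far = EntityMention(
            term_id="X",
            entity_type=pair.mention2.entity_type,
            doc_id="far",
            sent_index=0,
            token_start=len(sent.tokens) - 2,
            token_end=len(sent.tokens) - 1,
            char_start=sent.tokens[-2].start,
            char_end=sent.tokens[-2].end,
            surface=sent.tokens[-2].text,
        )
        far_pair = CandidatePair(sentence=sent, mention1=pair.mention1, mention2=far)
        with pytest.raises(ValueError, match="max_len"):
            mask_and_shape(far_pair, ModelConfig())


class TestTraining:
    def test_separable_cue_reaches_high_f1(self, fitted):
        _, _, _, history = fitted
        assert max(h["val_f1"] for h in history) >= 0.95

    def test_history_recorded_per_epoch(self, fitted):
        _, cfg, _, history = fitted
        assert len(history) == cfg.epochs
        assert all(0.0 <= h["val_f1"] <= 1.0 for h in history)

    def test_shuffled_labels_near_majority_baseline(self, binary_instances):
        rng = random.Random(0)
        labels = [i.label for i in binary_instances]
        rng.shuffle(labels)
        from litmarker.weak_labeling import LabeledInstance

        shuffled = [
            LabeledInstance(pair=i.pair, label=l, provenance=i.provenance)
            for i, l in zip(binary_instances, labels)
        ]
        cfg = ModelConfig(epochs=8)
        split = DatasetSplit(train=shuffled[:400], validation=shuffled[400:])
        clf = BaselineRelationClassifier(cfg)
        _, history = train(clf, split, cfg, seed=0)
        # macro F1 of a no-signal classifier hovers near chance (0.5 for 2 balanced classes)
        assert history[-1]["val_f1"] <= 0.65

    def test_single_label_errors(self, binary_instances):
        only_pos = [i for i in binary_instances if i.label == "positive"]
        cfg = ModelConfig(epochs=2)
        split = DatasetSplit(train=only_pos[:50], validation=only_pos[50:60])
        with pytest.raises(ValueError, match="single label"):
            train(BaselineRelationClassifier(cfg), split, cfg, seed=0)

    def test_f1_nondecreasing_with_training_size(self):
        # learnability trend: mean held-out F1 does not degrade as data grows
        sizes = [60, 200, 600]
        test_set = generate_instances(BINARY_CUES, 60, seed=77)
        scores = []
        for size in sizes:
            inst = generate_instances(BINARY_CUES, size, seed=31)
            cfg = ModelConfig(epochs=5)
            cut = int(0.8 * len(inst))
            clf = BaselineRelationClassifier(cfg)
            train(clf, DatasetSplit(train=inst[:cut], validation=inst[cut:]), cfg, seed=0)
            from sklearn.metrics import f1_score

            y_true = [i.label for i in test_set]
            y_pred = [
                predict_relation(clf, mask_and_shape(i, cfg), cfg).label for i in test_set
            ]
            scores.append(f1_score(y_true, y_pred, pos_label="positive"))
        assert all(b >= a - 1e-9 for a, b in zip(scores, scores[1:]))


class TestPrediction:
    def test_distribution_normalized(self, fitted, binary_instances):
        clf, cfg, _, _ = fitted
        for inst in binary_instances[:20]:
            pred = predict_relation(clf, mask_and_shape(inst, cfg), cfg)
            assert abs(sum(pred.distribution.values()) - 1.0) < 1e-6
            assert all(p >= 0 for p in pred.distribution.values())

    def test_cue_sentence_predicted_positive(self, fitted):
        clf, cfg, split, _ = fitted
        pos = [i for i in split.validation if i.label == "positive"][:10]
        for inst in pos:
            assert predict_relation(clf, mask_and_shape(inst, cfg), cfg).label == "positive"

    def test_deterministic_prediction(self, fitted, binary_instances):
        clf, cfg, _, _ = fitted
        seq = mask_and_shape(binary_instances[0], cfg)
        p1 = predict_relation(clf, seq, cfg)
        p2 = predict_relation(clf, seq, cfg)
        assert p1 == p2

    def test_shape_mismatch_errors(self, fitted):
        clf, cfg, _, _ = fitted
        bad = MaskedSequence(
            tokens=("DISEASE1", "MICROBIOME2", PAD), e1_index=0, e2_index=1, mask=(1, 1, 0)
        )
        with pytest.raises(ValueError, match="max_len"):
            clf.predict_proba(bad)


class TestArchitectureContract:
    def test_per_token_features_are_768(self):
        feats = encode_tokens(["Fusobacterium", "in", "cancer"])
        assert feats.shape == (3, 768)

    def test_contextual_features_differ_by_neighborhood(self):
        a = encode_tokens(["risk", "of", "cancer"])
        b = encode_tokens(["low", "risk", "here"])
        assert not np.allclose(a[0], b[1])  # same token, different context

    def test_batch_of_distributions_sum_to_one(self, binary_instances):
        cfg = ModelConfig(epochs=1)
        params = EncoderTreeParams.init(cfg, seed=0)
        for inst in binary_instances[:5]:
            probs = encoder_tree_forward(mask_and_shape(inst, cfg), params)
            assert probs.shape == (2,)
            assert abs(probs.sum() - 1.0) < 1e-9
            assert (probs >= 0).all()

    def test_zeroed_classifier_gives_uniform(self, binary_instances):
        cfg = ModelConfig()
        params = EncoderTreeParams.init(cfg, seed=1)
        params.fc_W[:] = 0.0
        params.fc_b[:] = 0.0
        probs = encoder_tree_forward(mask_and_shape(binary_instances[0], cfg), params)
        assert np.allclose(probs, 0.5)

    def test_tree_composer_reduces_to_single_vector(self):
        params = EncoderTreeParams.init(ModelConfig(), seed=2)
        feats = encode_tokens(["a", "b", "c", "d", "e"])
        vec = gumbel_tree_compose(feats, params)
        assert vec.shape == (768,)

    def test_dimension_mismatch_errors(self):
        params = EncoderTreeParams.init(ModelConfig(), seed=3)
        with pytest.raises(ValueError):
            gumbel_tree_compose(np.zeros((4, 10)), params)
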