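"""Masking, schedule, pretraining/fine-tuning contracts and metrics."""
import numpy as np
import pytest

import rankcell as rc
from rankcell.encoding import CLS, MASK, CellSentence
from rankcell.errors import ConfigurationError, DataError
from rankcell.train import learning_rate, mask_tokens, stratified_split

from conftest import clone_model


def _sentence(n_genes, start=10):
    return CellSentence(tokens=np.array([CLS] + list(range(start, start + n_genes))))


class TestMaskTokens:
    def test_exact_target_count_floor_rule(self):
        s = _sentence(100)
        _, pos, truth = mask_tokens(s, 0.15, 0, vocab_size=200)
        assert len(pos) == 15
        assert len(truth) == 15

    def test_minimum_one_target(self):
        s = _sentence(1)
        _, pos, _ = mask_tokens(s, 0.15, 0, vocab_size=200)
        assert len(pos) == 1

    def test_cls_never_masked_over_many_draws(self):
        s = _sentence(20)
        for seed in range(1000):
            toks, pos, _ = mask_tokens(s, 0.15, seed, vocab_size=200)
            assert 0 not in pos
            assert toks[0] == CLS

    def test_empirical_fraction_within_one_point(self):
        rng = np.random.default_rng(0)
        fractions = []
        for _ in range(300):
            n = int(rng.integers(100, 300))
            s = _sentence(n)
            _, pos, _ = mask_tokens(s, 0.15, rng, vocab_size=500)
            fractions.append(len(pos) / n)
        assert abs(np.mean(fractions) - 0.15) < 0.01

    def test_corruption_follows_80_10_10(self):
        rng = np.random.default_rng(1)
        masked = randomized = unchanged = 0
        for _ in range(200):
            s = _sentence(100)
            toks, pos, truth = mask_tokens(s, 0.15, rng, vocab_size=500)
            masked += (toks[pos] == MASK).sum()
            randomized += ((toks[pos] != MASK) & (toks[pos] != truth)).sum()
            unchanged += (toks[pos] == truth).sum()
        total = masked + randomized + unchanged
        assert abs(masked / total - 0.8) < 0.03
        assert abs(unchanged / total - 0.1) < 0.03

    def test_pure_mask_mode(self):
        s = _sentence(50)
        toks, pos, _ = mask_tokens(s, 0.2, 3, vocab_size=100, pure_mask=True)
        assert (toks[pos] == MASK).all()

    def test_deterministic_under_seed(self):
        s = _sentence(40)
        a = mask_tokens(s, 0.15, 7, vocab_size=100)
        b = mask_tokens(s, 0.15, 7, vocab_size=100)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_invalid_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            mask_tokens(_sentence(5), 0.0, 0, vocab_size=100)


class TestSchedule:
    def test_warmup_endpoints_exact(self):
        sched = rc.TrainingSchedule(max_lr=1e-3, warmup_steps=100)
        assert learning_rate(0, sched, 1000) == 0.0
        assert learning_rate(100, sched, 1000) == 1e-3

    def test_cosine_decay_monotone_to_zero(self):
        sched = rc.TrainingSchedule(max_lr=1e-3, warmup_steps=50)
        lrs = [learning_rate(s, sched, 500) for s in range(50, 501)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        assert lrs[-1] == pytest.approx(0.0, abs=1e-12)


class TestPretrain:
    def test_loss_decreases_over_epochs(self, pretrained_tiny):
        trace = pretrained_tiny["trace"]
        assert trace[-1] < trace[0]

    def test_reproducible_loss_trace(self, tiny_bundle):
        corpus = rc.TokenizedCorpus(
            sentences=tiny_bundle["corpus"].sentences[:48],
            vocab=tiny_bundle["vocab"], max_input=64)
        sched = rc.TrainingSchedule.pretrain_tiny(seed=5, epochs=2)
        traces = []
        for _ in range(2):
            model = rc.build_model(
                rc.EncoderConfig.tiny(tiny_bundle["vocab"].size, max_input=64),
                seed=5)
            _, trace = rc.pretrain(model, corpus, sched)
            traces.append(trace)
        assert np.allclose(traces[0], traces[1], atol=1e-4)

    def test_empty_corpus_rejected(self, tiny_bundle):
        corpus = rc.TokenizedCorpus(sentences=[], vocab=tiny_bundle["vocab"],
                                    max_input=64)
        with pytest.raises(DataError):
            rc.pretrain(rc.build_model(
                rc.EncoderConfig.tiny(tiny_bundle["vocab"].size, max_input=64),
                seed=0), corpus, rc.TrainingSchedule.pretrain_tiny())


class TestFinetune:
    def test_freezing_all_blocks_leaves_encoder_bit_identical(
            self, tiny_bundle, pretrained_tiny):
        model = clone_model(pretrained_tiny["model"])
        before = {k: p.data.copy() for k, p in model.params.items()
                  if k.startswith("b") or k.endswith("emb")}
        sched = rc.TrainingSchedule.finetune_tiny(
            seed=0, epochs=1, freeze_blocks=model.config.n_blocks)
        model, _ = rc.finetune(model, tiny_bundle["corpus"], sched)
        for k, v in before.items():
            assert np.array_equal(model.params[k].data, v), k

    def test_frozen_prefix_blocks_fixed_others_move(self, tiny_bundle,
                                                    pretrained_tiny):
        model = clone_model(pretrained_tiny["model"])
        b0 = model.params["b0.q_w"].data.copy()
        b1 = model.params["b1.q_w"].data.copy()
        sched = rc.TrainingSchedule.finetune_tiny(seed=0, epochs=1,
                                                  freeze_blocks=1)
        model, _ = rc.finetune(model, tiny_bundle["corpus"], sched)
        assert np.array_equal(model.params["b0.q_w"].data, b0)
        assert not np.array_equal(model.params["b1.q_w"].data, b1)

    def test_pretraining_helps_on_hard_data(self, pretrained_tiny):
        """Synthetic analogue of the with/without-prior comparison: on weakly
        separated programs, starting from the pretrained encoder reaches
        held-out accuracy at least as high as a random initialization."""
        cfg = rc.SyntheticConfig(n_cells=200, n_genes=100, n_cell_types=4,
                                 program_size=10, program_fold=2.0, seed=8)
        ds, _ = rc.generate_corpus(cfg)
        med = rc.compute_gene_medians(ds)
        vocab = rc.build_vocabulary(ds.gene_ids, med)
        corpus = rc.encode_dataset(ds, med, vocab, max_input=64,
                                   label_column="cell_type")
        sched = rc.TrainingSchedule.finetune_tiny(seed=0, epochs=2)
        pre = clone_model(pretrained_tiny["model"])
        _, m_pre = rc.finetune(pre, corpus, sched)
        fresh = rc.build_model(rc.EncoderConfig.tiny(vocab.size, max_input=64),
                               seed=0)
        _, m_fresh = rc.finetune(fresh, corpus, sched)
        assert m_pre.accuracy >= m_fresh.accuracy

    def test_unlabeled_corpus_rejected(self, tiny_bundle):
        corpus = rc.TokenizedCorpus(
            sentences=[CellSentence(tokens=np.array([CLS, 5, 9]))],
            vocab=tiny_bundle["vocab"], max_input=64)
        with pytest.raises(DataError, match="label"):
            rc.finetune(rc.build_model(
                rc.EncoderConfig.tiny(tiny_bundle["vocab"].size, max_input=64),
                seed=0), corpus, rc.TrainingSchedule.finetune_tiny())


class TestStratifiedSplit:
    def test_disjoint_and_proportional(self):
        labels = np.array(["a"] * 50 + ["b"] * 30 + ["c"] * 20, dtype=object)
        tr, te = stratified_split(labels, 0.8, seed=1)
        assert set(tr) & set(te) == set()
        assert len(tr) + len(te) == 100
        assert (labels[tr] == "a").sum() == 40
        assert (labels[te] == "c").sum() == 4

    def test_every_class_in_training_split(self):
        labels = np.array(["a"] * 40 + ["rare"], dtype=object)
        tr, _ = stratified_split(labels, 0.8, seed=0)
        assert "rare" in set(labels[tr])

    def test_reproducible_under_seed(self):
        labels = np.array(list("aabbccdd") * 10, dtype=object)
        a = stratified_split(labels, 0.8, seed=3)
        b = stratified_split(labels, 0.8, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestEvaluateClassifier:
    def test_perfect_predictions(self):
        m = rc.evaluate_classifier(["a", "b"], ["a", "b"])
        assert m.accuracy == 1.0 and m.macro_f1 == 1.0

    def test_hand_computed_example(self):
        # truth (A,A,B,B), preds (A,B,B,B): acc .75, F1(A)=2/3, F1(B)=4/5
        m = rc.evaluate_classifier(["A", "B", "B", "B"], ["A", "A", "B", "B"])
        assert m.accuracy == 0.75
        assert m.macro_f1 == pytest.approx((2 / 3 + 4 / 5) / 2, abs=1e-6)
        assert m.per_class["A"]["f1"] == pytest.approx(2 / 3, abs=1e-6)

    def test_single_class_all_correct(self):
        m = rc.evaluate_classifier(["x", "x"], ["x", "x"])
        assert m.accuracy == 1.0

    def test_disjoint_label_sets_rejected(self):
        with pytest.raises(DataError, match="disjoint"):
            rc.evaluate_classifier(["a", "a"], ["b", "b"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            rc.evaluate_classifier(["a"], ["a", "b"])


class TestZeroShot:
    def test_query_at_centroid_classified_to_that_class(self):
        ref = np.array([[1.0, 0.0], [0.9, 0.1], [0.0, 1.0], [0.1, 0.9]])
        labels = ["x", "x", "y", "y"]
        preds, _ = rc.zero_shot_classify(np.array([[0.95, 0.05]]), ref, labels)
        assert preds[0] == "x"

    def test_orthogonal_centroids(self):
        ref = np.array([[1.0, 0.0], [0.0, 1.0]])
        preds, _ = rc.zero_shot_classify(np.array([[0.0, 2.0], [3.0, 0.0]]),
                                         ref, ["a", "b"])
        assert preds.tolist() == ["b", "a"]

    def test_empty_reference_rejected(self):
        with pytest.raises(DataError):
            rc.zero_shot_classify(np.ones((1, 2)), np.ones((0, 2)), [])

    def test_trained_model_beats_chance(self, tiny_bundle, pretrained_tiny):
        corpus = tiny_bundle["corpus"]
        model = pretrained_tiny["model"]
        emb, _ = rc.embed_cells(model, corpus.sentences)
        labels = corpus.labels()
        ref, query = emb[:140], emb[140:]
        preds, metrics = rc.zero_shot_classify(query, ref, labels[:140],
                                               truth=labels[140:])
        assert metrics.accuracy > 1.0 / 4
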