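"""Tests for the classifier: architecture, training, scoring, persistence."""

import copy

import numpy as np
import pytest

from plastrans.evaluation import auc
from plastrans.model import (ModelConfig, build_model,
                             classify_score, load_model, save_model,
                             score_sequence, score_window, split_windows,
                             train_model, UNCERTAIN)
from plastrans.network import PlasTransNet, bce_with_logits, encode_batch
from plastrans.simulator import (NON_TRANSMISSIBLE, TRANSMISSIBLE, Fragment)

from conftest import random_dna


def _tiny_config(**kw):
    base = dict(triplet_kernels=8, base_kernels=8, hidden_dim=8, batch_size=32,
                max_epochs=2, max_len=200, min_len=50, seed=0)
    base.update(kw)
    return ModelConfig(**base)


def _fragments(rng, n_per_class, lo=100, hi=200):
    frags = []
    for i in range(n_per_class):
        for label in (TRANSMISSIBLE, NON_TRANSMISSIBLE):
            frags.append(Fragment(
                sequence=random_dna(rng, int(rng.integers(lo, hi + 1))),
                label=label, genome_id="g", start=0, strand="+",
                fragment_id=f"{label[:1]}{i}"))
    return frags


class TestArchitecture:
    def test_default_merged_dimension_is_1024(self):
        model = build_model(ModelConfig())
        assert model.net.merged_dim == 1024

    def test_default_branch_has_512_feature_maps(self):
        model = build_model(ModelConfig())
        assert model.net.triplet_branch.b.size == 512
        assert model.net.base_branch.b.size == 512
        assert model.net.triplet_branch.W.shape == (6, 65, 512)

    def test_outputs_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(0)
        model = build_model(_tiny_config())
        scores = model.score_batch([random_dna(rng, 150) for _ in range(8)])
        assert np.all((scores > 0) & (scores < 1))

    def test_invalid_config_errors(self):
        with pytest.raises(ValueError):
            build_model(ModelConfig(triplet_kernels=0))
        with pytest.raises(ValueError):
            build_model(ModelConfig(min_len=0))


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        """Central-difference check on a tiny network, all parameter groups."""
        rng = np.random.default_rng(1)
        net = PlasTransNet(triplet_kernels=3, base_kernels=3, kernel_len=2,
                           hidden_dim=4, n_head_blocks=1, seed=1)
        seqs = [random_dna(rng, 12) for _ in range(4)]
        batch = encode_batch(seqs, max_len=12, klen=2)
        y = np.array([1.0, 0.0, 1.0, 0.0])

        def loss_fn():
            logits = net.forward_logits(batch, train=True)
            return bce_with_logits(logits, y)

        loss, dlogits = loss_fn()
        grads = net.backward(dlogits)
        eps = 1e-4  # small enough not to cross ReLU/batch-norm kinks
        for gname, group in net.param_groups().items():
            for pname, param in group.items():
                flat = param.reshape(-1)
                for k in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                    orig = flat[k]
                    flat[k] = orig + eps
                    lp, _ = loss_fn()
                    flat[k] = orig - eps
                    lm, _ = loss_fn()
                    flat[k] = orig
                    num = (lp - lm) / (2 * eps)
                    ana = grads[gname][pname].reshape(-1)[k]
                    assert ana == pytest.approx(num, abs=2e-3), (gname, pname)


class TestTraining:
    def test_loss_decreases_on_separable_data(self, benchmark):
        train, _, _ = benchmark
        cfg = _tiny_config(max_len=400, min_len=100, max_epochs=2,
                           triplet_kernels=16, base_kernels=16, hidden_dim=16,
                           batch_size=128)
        model = train_model(build_model(cfg), train[:800] + train[-800:], cfg)
        assert model.history["train_loss"][-1] < model.history["train_loss"][0]

    def test_single_class_errors(self):
        rng = np.random.default_rng(2)
        frags = [f for f in _fragments(rng, 10) if f.label == TRANSMISSIBLE]
        cfg = _tiny_config()
        with pytest.raises(ValueError, match="single class"):
            train_model(build_model(cfg), frags, cfg)

    def test_out_of_range_fragments_listed(self):
        rng = np.random.default_rng(3)
        frags = _fragments(rng, 4)
        frags[0].sequence = "ACGT" * 100  # 400 bp > tiny max_len 200
        cfg = _tiny_config()
        with pytest.raises(ValueError, match=frags[0].fragment_id):
            train_model(build_model(cfg), frags, cfg)

    def test_training_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        frags = _fragments(rng, 30)
        cfg = _tiny_config(max_epochs=2)
        m1 = train_model(build_model(cfg), copy.deepcopy(frags), cfg)
        m2 = train_model(build_model(cfg), copy.deepcopy(frags), cfg)
        probe = [f.sequence for f in frags[:10]]
        np.testing.assert_array_equal(m1.score_batch(probe), m2.score_batch(probe))


class TestScoring:
    def test_score_window_range_and_determinism(self, trained_model):
        rng = np.random.default_rng(5)
        w = random_dna(rng, 300)
        s1 = score_window(trained_model, w)
        s2 = score_window(trained_model, w)
        assert 0.0 <= s1 <= 1.0
        assert s1 == s2

    def test_score_window_length_bounds(self, trained_model):
        with pytest.raises(ValueError):
            score_window(trained_model, "ACGT" * 10)
        with pytest.raises(ValueError):
            score_window(trained_model, "A" * 500)

    def test_strand_invariance(self, trained_model):
        """A window and its reverse complement are segment permutations of
        the same encoded input, so their scores coincide."""
        from plastrans.encoding import reverse_complement

        rng = np.random.default_rng(6)
        for _ in range(20):
            w = random_dna(rng, int(rng.integers(100, 401)))
            assert score_window(trained_model, w) == pytest.approx(
                score_window(trained_model, reverse_complement(w)), abs=1e-5)

    def test_padding_never_alters_pooled_score(self, trained_model):
        """Scores of short windows are identical whether encoded alone or
        padded inside a batch of full-length windows."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            short = random_dna(rng, int(rng.integers(100, 200)))
            alone = trained_model.score_batch([short])[0]
            padded = trained_model.score_batch([short, random_dna(rng, 400)])[0]
            assert alone == pytest.approx(padded, abs=1e-6)

    def test_scan_window_decomposition(self):
        assert [len(w) for w in split_windows("A" * 800)] == [400, 400]
        assert [len(w) for w in split_windows("A" * 950)] == [400, 400, 150]
        assert [len(w) for w in split_windows("A" * 450)] == [400]  # 50 bp dropped
        with pytest.raises(ValueError):
            split_windows("A" * 80)

    def test_sequence_score_is_mean_of_window_scores(self, trained_model):
        rng = np.random.default_rng(8)
        seq = random_dna(rng, 800)
        rec = score_sequence(trained_model, seq, "s1")
        assert len(rec.window_scores) == 2
        assert rec.score == pytest.approx(np.mean(rec.window_scores), abs=1e-12)

    def test_stub_scorer_average_arithmetic(self, trained_model):
        """With a stub scoring each window at length/1000, a 1050 bp sequence
        scores (0.4 + 0.4 + 0.25) / 3."""
        stub = copy.copy(trained_model)
        stub.score_batch = lambda seqs: np.array([len(s) / 1000 for s in seqs])
        rec = score_sequence(stub, "A" * 1050, "stub")
        assert rec.score == pytest.approx((0.4 + 0.4 + 0.25) / 3, abs=1e-12)


class TestDecisionRule:
    def test_basic_labels(self):
        assert classify_score(0.9, 0.2) == TRANSMISSIBLE
        assert classify_score(0.1, 0.2) == NON_TRANSMISSIBLE

    def test_near_half_score_uncertain_at_small_threshold(self):
        assert classify_score(0.4664, 0.05) == UNCERTAIN
        assert classify_score(0.4972, 0.05) == UNCERTAIN
        assert classify_score(0.4664, 0.0) == NON_TRANSMISSIBLE

    def test_exactly_half_is_non_transmissible(self):
        assert classify_score(0.5, 0.0) == NON_TRANSMISSIBLE

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            classify_score(0.5, 0.5)
        with pytest.raises(ValueError):
            classify_score(0.5, -0.1)
        with pytest.raises(ValueError):
            classify_score(1.5, 0.1)

    def test_labels_partition_and_uncertain_monotone(self):
        rng = np.random.default_rng(9)
        scores = rng.random(200)
        prev = -1
        for t in [0.0, 0.05, 0.1, 0.2, 0.3, 0.49]:
            labels = [classify_score(s, t) for s in scores]
            assert all(l in (TRANSMISSIBLE, NON_TRANSMISSIBLE, UNCERTAIN)
                       for l in labels)
            n_unc = labels.count(UNCERTAIN)
            assert n_unc >= prev
            prev = n_unc


class TestPersistence:
    def test_round_trip_scores_identical(self, trained_model, tmp_path):
        rng = np.random.default_rng(10)
        probe = [random_dna(rng, 300) for _ in range(10)]
        path = tmp_path / "model.npz"
        save_model(trained_model, str(path))
        loaded = load_model(str(path))
        np.testing.assert_array_equal(
            trained_model.score_batch(probe), loaded.score_batch(probe))

    def test_round_trip_preserves_heldout_auc(self, trained_model, benchmark,
                                              heldout_auc, tmp_path):
        _, test, _ = benchmark
        path = tmp_path / "model.npz"
        save_model(trained_model, str(path))
        loaded = load_model(str(path))
        scores = loaded.score_batch([f.sequence for f in test["A"]])
        y = [1 if f.label == TRANSMISSIBLE else 0 for f in test["A"]]
        assert auc(scores.tolist(), y) == heldout_auc

    def test_encoded_batch_round_trip(self, tmp_path):
        from plastrans.network import encode_batch, load_batch, save_batch

        rng = np.random.default_rng(11)
        batch = encode_batch([random_dna(rng, 150), random_dna(rng, 300)], 400)
        path = tmp_path / "batch.npz"
        save_batch(batch, str(path))
        loaded = load_batch(str(path))
        for field in ("trip_idx", "trip_mask", "base_idx", "base_mask", "lengths"):
            np.testing.assert_array_equal(getattr(batch, field),
                                          getattr(loaded, field))

    def test_corrupted_artifact_errors(self, tmp_path):
        path = tmp_path / "junk.npz"
        path.write_bytes(b"not a model")
        with pytest.raises(ValueError, match="cannot read"):
            load_model(str(path))
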