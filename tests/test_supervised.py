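"""Supervised networks, training contracts and evaluation metrics."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from promoforge._autograd import Tensor
from promoforge.features import FeatureMatrix, Encoding
from promoforge.supervised import (ConfusionCounts, NetConfig, ResBlock1d,
                                   auroc, baseline_ml, binary_metrics,
                                   build_network, cross_validate,
                                   encode_dataset, extract_targets,
                                   hyperparameter_search, load_model,
                                   pearson_cc, predict, residual_block,
                                   save_model, self_attention,
                                   train_supervised)
from promoforge.synthetic import (SyntheticSpec, consensus_pwm,
                                  simulate_activity_dataset,
                                  simulate_real_fake)

RNG = np.random.default_rng(99)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class TestResidualBlock:
    def test_zeroed_branch_with_identity_skip_is_identity(self):
        block = ResBlock1d(np.random.default_rng(0), 4, 4)
        for layer in (block.conv1, block.conv2):
            layer.weight.data[:] = 0
            layer.bias.data[:] = 0
        x = RNG.standard_normal((2, 4, 10))
        assert np.allclose(residual_block(x, block), x)

    def test_output_shape_matches_input(self):
        block = ResBlock1d(np.random.default_rng(0), 4, 4)
        x = RNG.standard_normal((3, 4, 12))
        assert residual_block(x, block).shape == x.shape

    def test_channel_mismatch_uses_projection_skip(self):
        block = ResBlock1d(np.random.default_rng(0), 4, 8)
        x = RNG.standard_normal((2, 4, 10))
        assert residual_block(x, block).shape == (2, 8, 10)

    def test_gradient_flows_through_skip_when_branch_zeroed(self):
        block = ResBlock1d(np.random.default_rng(0), 3, 3)
        for layer in (block.conv1, block.conv2):
            layer.weight.data[:] = 0
            layer.bias.data[:] = 0
        x = Tensor(RNG.standard_normal((1, 3, 5)), requires_grad=True)
        (residual_block(x, block) ** 2).sum().backward()
        assert np.allclose(x.grad, 2 * x.data)


class TestSelfAttention:
    def test_single_position_returns_v(self):
        q = RNG.standard_normal((1, 4))
        k = RNG.standard_normal((1, 4))
        v = RNG.standard_normal((1, 6))
        assert np.allclose(self_attention(q, k, v, 4), v)

    def test_equal_logits_average_v(self):
        q = np.zeros((3, 4))
        k = RNG.standard_normal((5, 4))
        v = RNG.standard_normal((5, 6))
        out = self_attention(q, k, v, 4)
        assert np.allclose(out, np.tile(v.mean(axis=0), (3, 1)))

    def test_attention_rows_sum_to_one(self):
        from promoforge._autograd import softmax
        q = RNG.standard_normal((7, 4))
        k = RNG.standard_normal((7, 4))
        logits = q @ k.T / 2.0
        w = softmax(Tensor(logits), axis=-1).data
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-6)

    def test_non_positive_key_dim_rejected(self):
        with pytest.raises(ValueError):
            self_attention(np.ones((2, 2)), np.ones((2, 2)), np.ones((2, 2)), 0)


# ---------------------------------------------------------------------------
# network construction and training
# ---------------------------------------------------------------------------

class TestBuildAndTrain:
    def test_binary_outputs_strictly_in_unit_interval(self):
        cfg = NetConfig(n_resblocks=1, channels=4, epochs=1, seed=0)
        model = build_network(cfg, (4, 50))
        x = FeatureMatrix(RNG.integers(0, 2, (8, 200)).astype(float),
                          Encoding.ONEHOT, 50)
        scores = predict(model, x)
        assert scores.shape == (8,)
        assert ((scores > 0) & (scores < 1)).all()

    def test_default_config_builds_twenty_resblocks(self):
        model = build_network(NetConfig(), (4, 50))
        assert model.n_resblocks_built == 20

    def test_same_seed_gives_identical_initial_parameters(self):
        cfg = NetConfig(n_resblocks=1, channels=4, seed=7)
        a = build_network(cfg, (4, 50)).network.params()
        b = build_network(cfg, (4, 50)).network.params()
        assert all(np.array_equal(p.data, q.data) for p, q in zip(a, b))

    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError, match="arch"):
            NetConfig(arch="transformer")

    def test_training_is_deterministic_under_seed(self, realfake_dataset):
        ds = realfake_dataset.subset(range(60))
        X = encode_dataset(ds, "onehot")
        y = extract_targets(ds, "binary", "realness")
        cfg = NetConfig(n_resblocks=1, channels=4, epochs=3,
                        batch_size=16, seed=3)
        histories = []
        for _ in range(2):
            m = build_network(cfg, (4, 50))
            train_supervised(m, X, y, cfg)
            histories.append(m.history)
        assert histories[0] == histories[1]

    def test_zero_epochs_returns_model_unchanged(self, realfake_dataset):
        ds = realfake_dataset.subset(range(20))
        X = encode_dataset(ds, "onehot")
        y = extract_targets(ds, "binary", "realness")
        cfg = NetConfig(n_resblocks=1, channels=4, epochs=0, seed=0)
        m = build_network(cfg, (4, 50))
        before = [p.data.copy() for p in m.network.params()]
        train_supervised(m, X, y, cfg)
        assert m.history == []
        assert all(np.array_equal(b, p.data)
                   for b, p in zip(before, m.network.params()))

    def test_single_class_labels_warn_but_train(self):
        X = FeatureMatrix(RNG.integers(0, 2, (10, 40)).astype(float),
                          Encoding.ONEHOT, 10)
        cfg = NetConfig(n_resblocks=1, channels=4, epochs=1, seed=0)
        m = build_network(cfg, (4, 10))
        with pytest.warns(UserWarning, match="single class"):
            train_supervised(m, X, np.ones(10), cfg)

    def test_nan_targets_rejected(self):
        X = FeatureMatrix(np.ones((4, 40)), Encoding.ONEHOT, 10)
        cfg = NetConfig(task="regression", n_resblocks=1, channels=4,
                        epochs=1, seed=0)
        m = build_network(cfg, (4, 10))
        with pytest.raises(ValueError, match="NaN"):
            train_supervised(m, X, np.array([1.0, np.nan, 2.0, 3.0]), cfg)

    def test_predict_is_pure_and_permutation_equivariant(self, realfake_dataset):
        ds = realfake_dataset.subset(range(30))
        X = encode_dataset(ds, "onehot")
        cfg = NetConfig(n_resblocks=1, channels=4, epochs=1, seed=0)
        m = build_network(cfg, (4, 50))
        s1 = predict(m, X)
        s2 = predict(m, X)
        assert np.array_equal(s1, s2)
        perm = RNG.permutation(X.n_samples)
        s3 = predict(m, FeatureMatrix(X.values[perm], X.encoding, 50))
        assert np.allclose(s3, s1[perm])

    def test_predict_layout_mismatch_raises(self):
        cfg = NetConfig(n_resblocks=1, channels=4, epochs=1, seed=0)
        m = build_network(cfg, (4, 50))
        with pytest.raises(ValueError, match="layout"):
            predict(m, FeatureMatrix(np.ones((2, 80)), Encoding.ONEHOT, 20))

    def test_separable_data_reaches_high_training_accuracy(self):
        spec = SyntheticSpec(n=200,
                             minus35_pwm=consensus_pwm("TTGACA", 1.0),
                             minus10_pwm=consensus_pwm("TATAAT", 1.0),
                             noise_sigma=0.0, seed=21)
        ds = simulate_real_fake(spec)
        X = encode_dataset(ds, "onehot")
        y = extract_targets(ds, "binary", "realness")
        cfg = NetConfig(n_resblocks=2, channels=8, epochs=30,
                        learning_rate=3e-3, batch_size=32,
                        dropout_rate=0.0, seed=0)
        m = build_network(cfg, (4, 50))
        train_supervised(m, X, y, cfg)
        acc = np.mean((predict(m, X) > 0.5) == y)
        assert acc >= 0.95

    def test_checkpoint_round_trip(self, tmp_path, realfake_dataset):
        ds = realfake_dataset.subset(range(30))
        X = encode_dataset(ds, "onehot")
        y = extract_targets(ds, "binary", "realness")
        cfg = NetConfig(n_resblocks=1, channels=4, epochs=2, seed=0)
        m = build_network(cfg, (4, 50))
        train_supervised(m, X, y, cfg)
        path = tmp_path / "model.npz"
        save_model(m, path)
        m2 = load_model(path)
        assert np.allclose(predict(m2, X), predict(m, X))
        assert m2.history == m.history


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def brute_force_metrics(tp, tn, fp, fn):
    """Straight transcription of the metric definitions."""
    import math
    out = {}
    out["Sn"] = tp / (tp + fn) if tp + fn else None
    out["Sp"] = tn / (tn + fp) if tn + fp else None
    out["Acc"] = (tp + tn) / (tp + tn + fp + fn)
    d = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    out["MCC"] = (tp * tn - fp * fn) / d if d else None
    return out


class TestMetrics:
    def test_worked_confusion_table(self):
        m = binary_metrics(ConfusionCounts(TP=3, TN=4, FP=1, FN=2))
        assert m["Sn"] == pytest.approx(0.6)
        assert m["Sp"] == pytest.approx(0.8)
        assert m["Acc"] == pytest.approx(0.7)
        assert m["MCC"] == pytest.approx(
            (3 * 4 - 1 * 2) / np.sqrt(4 * 5 * 5 * 6))

    def test_symmetric_table_has_zero_mcc(self):
        m = binary_metrics(ConfusionCounts(5, 5, 5, 5))
        assert m["Acc"] == 0.5 and m["MCC"] == 0

    def test_perfect_classifier(self):
        m = binary_metrics(ConfusionCounts(3, 7, 0, 0))
        assert m["Sn"] == m["Sp"] == m["Acc"] == m["MCC"] == 1

    def test_all_small_tables_match_brute_force(self):
        for tp, tn, fp, fn in itertools.product(range(4), repeat=4):
            if tp + tn + fp + fn == 0:
                continue
            mine = binary_metrics(ConfusionCounts(tp, tn, fp, fn))
            ref = brute_force_metrics(tp, tn, fp, fn)
            for key in ("Sn", "Sp", "Acc", "MCC"):
                if ref[key] is None:
                    assert mine[key] is None
                else:
                    assert mine[key] == pytest.approx(ref[key])

    def test_undefined_metrics_are_none_not_zero(self):
        m = binary_metrics(ConfusionCounts(TP=0, TN=3, FP=0, FN=0))
        assert m["Sn"] is None and m["MCC"] is None

    def test_auroc_matches_sklearn_and_is_rank_invariant(self):
        from sklearn.metrics import roc_auc_score
        y = RNG.integers(0, 2, 60)
        y[0], y[1] = 0, 1
        s = RNG.standard_normal(60)
        assert auroc(y, s) == pytest.approx(roc_auc_score(y, s))
        # monotone transforms preserve ranks, hence AUROC
        assert auroc(y, np.exp(2 * s)) == pytest.approx(auroc(y, s))

    def test_pearson_edge_cases(self):
        v = RNG.standard_normal(20)
        assert pearson_cc(v, v) == pytest.approx(1.0)
        assert pearson_cc(v, -v) == pytest.approx(-1.0)
        with pytest.raises(ValueError, match="constant"):
            pearson_cc(np.ones(10), v[:10])


# ---------------------------------------------------------------------------
# cross-validation and search
# ---------------------------------------------------------------------------

class TestCrossValidation:
    def test_folds_partition_dataset(self, realfake_dataset):
        from sklearn.model_selection import StratifiedKFold
        y = extract_targets(realfake_dataset, "binary", "realness")
        splitter = StratifiedKFold(5, shuffle=True, random_state=0)
        seen = []
        for _, te in splitter.split(np.zeros(len(y)), y):
            seen.extend(te)
        assert sorted(seen) == list(range(len(y)))

    def test_label_shuffled_data_scores_at_chance(self, realfake_dataset):
        rng = np.random.default_rng(0)
        cfg = NetConfig(n_resblocks=1, channels=4, epochs=5,
                        batch_size=32, seed=0, dropout_rate=0.0)
        accs = []
        from dataclasses import replace as dc_replace
        from promoforge.seqdata import RealnessLabel, SequenceDataset
        for rep in range(3):
            order = rng.permutation(len(realfake_dataset))
            labels = [realfake_dataset[i].realness_label for i in order]
            shuffled = SequenceDataset(
                [dc_replace(r, realness_label=l)
                 for r, l in zip(realfake_dataset, labels)], fixed_length=50)
            rep_out = cross_validate(cfg, shuffled, 4, seed=rep,
                                     target="realness")
            accs.append(rep_out.means["Acc"])
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_k_larger_than_dataset_rejected(self, realfake_dataset):
        with pytest.raises(ValueError, match="exceeds"):
            cross_validate(NetConfig(), realfake_dataset.subset(range(4)), 10)

    def test_noise_free_regression_recovers_signal(self):
        spec = SyntheticSpec(n=500, noise_sigma=0.0, seed=8)
        ds = simulate_activity_dataset(spec)
        cfg = NetConfig(arch="simple_cnn", task="regression", channels=16,
                        epochs=60, learning_rate=3e-3, batch_size=16,
                        dropout_rate=0.3, weight_decay=0.1, seed=0)
        rep = cross_validate(cfg, ds, 5, seed=1, log_transform=False)
        assert rep.means["PCC"] >= 0.8


class TestHyperparameterSearch:
    def test_single_point_grid_returns_that_point(self, realfake_dataset):
        base = NetConfig(n_resblocks=1, channels=4, epochs=2, seed=0)
        ds = realfake_dataset.subset(range(60))
        best, report = hyperparameter_search([0.01], [16], base, ds, 3, seed=0)
        assert best.learning_rate == 0.01 and best.batch_size == 16
        assert len(report) == 1

    def test_report_covers_full_grid_and_best_is_argmax(self, realfake_dataset):
        base = NetConfig(n_resblocks=1, channels=4, epochs=2, seed=0)
        ds = realfake_dataset.subset(range(60))
        best, report = hyperparameter_search([0.001, 0.01], [16, 32],
                                             base, ds, 3, seed=0)
        assert len(report) == 4
        best_row = max(report, key=lambda r: r["score"])
        assert all(best_row["score"] >= r["score"] for r in report)

    def test_out_of_range_grid_rejected(self, realfake_dataset):
        base = NetConfig(n_resblocks=1, channels=4, epochs=1, seed=0)
        with pytest.raises(ValueError, match="outside"):
            hyperparameter_search([2.0], [16], base, realfake_dataset, 2)
        with pytest.raises(ValueError, match="empty"):
            hyperparameter_search([], [16], base, realfake_dataset, 2)


class TestBaselines:
    def test_elastic_net_recovers_noiseless_linear_map(self):
        rng = np.random.default_rng(4)
        X = FeatureMatrix(rng.standard_normal((150, 30)), Encoding.PSEDNC)
        beta = rng.standard_normal(30)
        y = X.values @ beta
        assert baseline_ml(X, y, "elastic_net", k=5, seed=0) >= 0.95

    def test_pure_noise_targets_score_near_zero(self):
        rng = np.random.default_rng(5)
        X = FeatureMatrix(rng.standard_normal((120, 20)), Encoding.PSEDNC)
        pccs = [baseline_ml(X, rng.standard_normal(120), "elastic_net",
                            k=4, seed=s) for s in range(3)]
        assert abs(np.mean(pccs)) < 0.2

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(6)
        X = FeatureMatrix(rng.standard_normal((80, 10)), Encoding.PSEDNC)
        y = rng.standard_normal(80)
        a = baseline_ml(X, y, "gradient_boosted_trees", k=3, seed=1)
        b = baseline_ml(X, y, "gradient_boosted_trees", k=3, seed=1)
        assert a == b
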