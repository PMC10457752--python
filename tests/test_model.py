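"""Architecture audit, gradient correctness, fold logic and training
determinism of the period-window classifier."""

import numpy as np
import pytest

import pulsesite as ps
from pulsesite import model as M

# the published architecture table for input 1495, 5 classes:
# (layer type, channels, length, params)
TABLE = [("AveragePooling1D", 1, 299, 0),
         ("Conv1D", 4, 296, 20),
         ("MaxPooling1D", 4, 74, 0),
         ("Conv1D", 10, 55, 810),
         ("MaxPooling1D", 10, 5, 0),
         ("Flatten", None, 50, 0),
         ("Dense", None, 64, 3264),
         ("Dropout", None, 64, 0),
         ("Dense", None, 5, 325)]


class TestArchitecture:
    def test_audit_reproduces_published_table(self):
        m = M.build_model(1495, 5)
        assert len(m.audit) == 9
        got = [(r.layer_type, r.n_channels, r.length_dim, r.n_params)
               for r in m.audit]
        assert got == TABLE

    def test_parameter_totals(self):
        counts = M.count_parameters(M.build_model(1495, 5))
        assert counts["per_layer"] == [20, 810, 3264, 325]
        assert counts["total_trainable"] == 4419
        assert counts["total_nontrainable"] == 0

    def test_counts_match_hand_formula(self):
        # independent arithmetic: conv k*c_in*c_out + c_out, dense d_in*d_out + d_out
        m = M.build_model(1495, 5)
        expected = [4 * 1 * 4 + 4, 20 * 4 * 10 + 10, 50 * 64 + 64,
                    64 * 5 + 5]
        assert [l.n_params() for l in m.trainable_layers()] == expected

    def test_two_class_variant(self):
        counts = M.count_parameters(M.build_model(1495, 2))
        assert counts["per_layer"][-1] == 64 * 2 + 2 == 130
        assert counts["total_trainable"] == 4224

    def test_incompatible_input_length_names_offending_stage(self):
        with pytest.raises(ValueError, match="AveragePooling1D"):
            M.build_model(1496, 5)
        with pytest.raises(ValueError, match="MaxPooling1D"):
            M.build_model(1500, 5)

    def test_initial_pooling_is_part_of_the_model(self):
        m = M.build_model(1495, 5, seed=3)
        X = np.random.default_rng(0).standard_normal((4, 1495)).astype(
            np.float32)
        pooled = X.reshape(4, 299, 5).mean(axis=2)
        np.testing.assert_array_equal(
            m.forward(X), m.forward(pooled, skip_initial_pool=True))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        # 615 is the smallest-but-one input compatible with the pooling chain
        m = M.build_model(615, 3, seed=5)
        for layer in m.layers:
            if isinstance(layer, M.Dropout):
                layer.rate = 0.0
        rng = np.random.default_rng(8)
        X = rng.standard_normal((6, 615))
        y = rng.integers(0, 3, 6)

        def loss():
            x = np.asarray(X, dtype=np.float64)[:, :, None]
            for layer in m.layers:
                x = layer.forward(x, train=True)
            p = M._softmax(x)
            return -np.mean(np.log(p[np.arange(6), y] + 1e-12)), p

        base_loss, probs = loss()
        dlogits = probs.copy()
        dlogits[np.arange(6), y] -= 1.0
        m._backward(dlogits / 6)
        grads = [g for l in m.trainable_layers() for g in l.grads()]
        params = [p for l in m.trainable_layers() for p in l.params()]

        eps = 1e-4
        checked = 0
        for p, g in zip(params, grads):
            flat_idx = rng.choice(p.size, size=min(8, p.size), replace=False)
            for i in flat_idx:
                orig = p.flat[i]
                p.flat[i] = orig + eps
                lp, _ = loss()
                p.flat[i] = orig - eps
                lm, _ = loss()
                p.flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                assert numeric == pytest.approx(g.flat[i],
                                                abs=1e-4, rel=5e-2)
                checked += 1
        assert checked >= 30


class TestFolds:
    def test_fold_sizes_and_ratio(self):
        y = np.repeat(list("ABCDE"), 20)
        folds = M.split_folds(y, k=5, seed=0)
        for tr, te in folds:
            assert len(te) == 20 and len(tr) == 80  # 4:1

    def test_stratification_is_exact_for_balanced_input(self):
        y = np.repeat(list("ABCDE"), 20)
        for tr, te in M.split_folds(y, k=5, seed=1):
            _, counts = np.unique(y[te], return_counts=True)
            assert np.all(counts == 4)

    def test_folds_disjoint_and_exhaustive(self):
        y = np.repeat(list("ABCDE"), 21)
        folds = M.split_folds(y, k=5, seed=2)
        all_test = np.concatenate([te for _, te in folds])
        assert len(all_test) == len(y)
        assert len(np.unique(all_test)) == len(y)

    def test_same_seed_reproduces_partition(self):
        y = np.repeat(list("ABCDE"), 20)
        a = M.split_folds(y, k=5, seed=7)
        b = M.split_folds(y, k=5, seed=7)
        for (tra, tea), (trb, teb) in zip(a, b):
            np.testing.assert_array_equal(tea, teb)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="fewer than"):
            M.split_folds(np.array(list("AAABB")), k=5)

    def test_recording_level_split_keeps_recordings_whole(self):
        y = np.repeat(list("AB"), 50)
        groups = np.repeat([f"{c}{i}" for c in "AB" for i in range(5)], 10)
        folds = M.split_folds(y, k=5, seed=0, level="recording",
                              groups=groups)
        for tr, te in folds:
            assert set(groups[tr]) & set(groups[te]) == set()


def _toy_windows(n_per_class=30, length=615, seed=0):
    """Three synthetic classes with distinct low-frequency signatures."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, length)
    X, y = [], []
    for i, c in enumerate("ABC"):
        base = np.sin(2 * np.pi * (i + 1) * t)
        X.append(base + 0.3 * rng.standard_normal((n_per_class, length)))
        y += [c] * n_per_class
    return np.concatenate(X).astype(np.float32), np.array(y)


class TestTraining:
    def test_learns_separable_toy_classes(self):
        X, y = _toy_windows()
        cfg = M.TrainingConfig(epochs=12, seed=3)
        folds = M.train_cv(X, y, cfg, k=5)
        acc = np.concatenate([f.y_true == f.y_pred for f in folds]).mean()
        assert acc > 0.8

    def test_every_window_predicted_exactly_once(self):
        X, y = _toy_windows(n_per_class=10)
        folds = M.train_cv(X, y, M.TrainingConfig(epochs=2, seed=0), k=5)
        seen = np.concatenate([f.test_indices for f in folds])
        assert sorted(seen) == list(range(len(y)))

    def test_same_seed_gives_identical_predictions(self):
        X, y = _toy_windows(n_per_class=10)
        cfg = M.TrainingConfig(epochs=3, seed=9)
        a = M.train_cv(X, y, cfg, k=5)
        b = M.train_cv(X, y, cfg, k=5)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.y_pred, fb.y_pred)
            np.testing.assert_array_equal(fa.scores, fb.scores)

    def test_divergent_training_reported(self):
        X, y = _toy_windows(n_per_class=10)
        cfg = M.TrainingConfig(epochs=3, seed=0, learning_rate=1e12)
        with np.errstate(all="ignore"), pytest.raises(M.TrainingDivergence):
            M.train_cv(X, y, cfg, k=5)

    def test_weights_roundtrip_through_archive(self, tmp_path):
        X, _ = _toy_windows(n_per_class=4)
        m = M.build_model(615, 3, seed=1)
        M.save_weights(m, tmp_path / "w.json")
        back = M.load_weights(tmp_path / "w.json")
        np.testing.assert_allclose(m.forward(X[:5]), back.forward(X[:5]),
                                   rtol=1e-6, atol=1e-7)
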