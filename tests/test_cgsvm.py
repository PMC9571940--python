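"""CG-SVM model: loss-term oracles, gradient checks, center updates,
feature extraction contracts and end-to-end training behaviour."""

import numpy as np
import pytest

from eitgesture import cgsvm_model as cg
from eitgesture.cgsvm_model import (
    CGSVMConfig,
    aux_loss_and_feature_grad,
    center_distance_penalty,
    center_loss,
    center_penalty_grad,
    extract_features,
    init_params,
    predict,
    softmax_loss,
    total_loss,
    train,
    update_centers,
)

TINY = CGSVMConfig(
    n_classes=3, input_len=10, conv_blocks=((3, 2), (2, 3)), gru_hidden=4,
    aux_hidden=5, dropout_rate=0.0, lambda1=0.1, lambda2=0.05, K=1.0, seed=0,
)


def _oracle_softmax(x, y, w, b):
    total = 0.0
    for xi, yi in zip(x, y):
        logits = [float(xi @ w[:, j] + b[j]) for j in range(w.shape[1])]
        denom = sum(np.exp(l) for l in logits)
        total += -np.log(np.exp(logits[yi]) / denom)
    return total


def _oracle_center(x, y, c):
    return 0.5 * sum(
        sum((xi[k] - c[yi][k]) ** 2 for k in range(len(xi)))
        for xi, yi in zip(x, y)
    )


def _oracle_penalty(y, c, k):
    total = 0.0
    for yi in y:
        for j in range(len(c)):
            if j != yi:
                gap = sum((c[yi][d] - c[j][d]) ** 2 for d in range(c.shape[1]))
                total += max(0.0, k - gap)
    return total


class TestLossTerms:
    def test_uniform_softmax_gives_log_n(self):
        w, b = np.zeros((7, 5)), np.zeros(5)
        assert softmax_loss(np.ones((1, 7)), [3], w, b) == pytest.approx(
            np.log(5.0), abs=1e-12
        )

    def test_confident_correct_logit_drives_loss_to_zero(self):
        w = np.zeros((2, 3))
        w[0, 1] = 50.0
        assert softmax_loss(np.array([[1.0, 0.0]]), [1], w, np.zeros(3)) < 1e-12

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            softmax_loss(np.ones((1, 2)), [5], np.zeros((2, 3)), np.zeros(3))

    def test_center_loss_zero_at_centers_and_half_norm(self):
        c = np.array([[0.0, 0.0], [1.0, 1.0]])
        assert center_loss(c[[0, 1]], [0, 1], c) == 0.0
        assert center_loss(np.array([[1.0, 0.0]]), [0], c) == pytest.approx(0.5)

    def test_center_loss_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            center_loss(np.ones((1, 3)), [0], np.ones((2, 2)))

    def test_penalty_zero_when_gaps_exceed_margin(self):
        c = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        assert center_distance_penalty([0, 1, 2], c, 1.0) == 0.0

    def test_penalty_on_coincident_two_class_centers(self):
        assert center_distance_penalty([0, 1], np.zeros((2, 4)), 1.0) == pytest.approx(2.0)

    def test_penalty_margin_must_be_positive(self):
        with pytest.raises(ValueError):
            center_distance_penalty([0], np.zeros((2, 2)), 0.0)

    @pytest.mark.parametrize("trial", range(10))
    def test_losses_match_brute_force_oracles(self, trial):
        rng = np.random.default_rng(trial)
        m, d, n = rng.integers(1, 9), rng.integers(2, 6), rng.integers(2, 6)
        x = rng.standard_normal((m, d))
        y = rng.integers(0, n, size=m)
        w, b = rng.standard_normal((d, n)), rng.standard_normal(n)
        c = rng.standard_normal((n, d))
        k = float(rng.uniform(0.5, 4.0))
        assert softmax_loss(x, y, w, b) == pytest.approx(
            _oracle_softmax(x, y, w, b), abs=1e-10
        )
        assert center_loss(x, y, c) == pytest.approx(
            _oracle_center(x, y, c), abs=1e-10
        )
        assert center_distance_penalty(y, c, k) == pytest.approx(
            _oracle_penalty(y, c, k), abs=1e-10
        )

    def test_nearest_mode_penalizes_only_closest_center(self):
        c = np.array([[0.0, 0.0], [0.5, 0.0], [3.0, 0.0]])
        k = 10.0
        want = max(0.0, k - 0.25)  # nearest other center to class 0 is c1
        got = center_distance_penalty([0], c, k, mode="nearest")
        assert got == pytest.approx(want)

    def test_total_loss_weighted_sum(self):
        assert total_loss(1.0, 2.0, 3.0, 0.5, 0.1) == pytest.approx(2.3)
        assert total_loss(4.2, 9.9, 1.1, 0.0, 0.0) == 4.2
        with pytest.raises(ValueError):
            total_loss(1, 1, 1, -0.1, 0)


class TestCenterUpdates:
    def test_no_motion_when_features_sit_on_centers(self):
        c = np.arange(6, dtype=float).reshape(3, 2)
        out = update_centers(c[[0, 2]], [0, 2], c, alpha=0.7)
        np.testing.assert_allclose(out, c)

    def test_single_sample_alpha_one_moves_to_midpoint(self):
        c = np.zeros((2, 2))
        out = update_centers(np.array([[2.0, 0.0]]), [0], c, alpha=1.0)
        np.testing.assert_allclose(out[0], [1.0, 0.0])
        np.testing.assert_allclose(out[1], [0.0, 0.0])  # absent class untouched

    def test_matches_per_class_loop_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((12, 5))
        y = rng.integers(0, 4, size=12)
        c = rng.standard_normal((4, 5))
        alpha = 0.3
        want = c.copy()
        for j in range(4):
            members = x[y == j]
            if len(members):
                delta = sum(want[j] - xi for xi in members) / (1 + len(members))
                want[j] = want[j] - alpha * delta
        np.testing.assert_allclose(update_centers(x, y, c, alpha), want, atol=1e-12)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            update_centers(np.ones((1, 2)), [0], np.zeros((2, 2)), 0.0)

    def test_penalty_gradient_pushes_close_centers_apart(self):
        c = np.array([[0.0, 0.0], [0.1, 0.0]])
        g = center_penalty_grad([0, 1], c, k=1.0)
        stepped = c - 0.1 * g
        assert np.linalg.norm(stepped[0] - stepped[1]) > np.linalg.norm(c[0] - c[1])


class TestGradients:
    def test_feature_gradient_matches_finite_differences(self):
        """d(total loss)/d(features) through the auxiliary head plus the
        center term agrees with central differences to 1e-4 relative."""
        rng = np.random.default_rng(1)
        params = init_params(TINY, rng)
        # randomize biases so no ReLU pre-activation sits exactly at 0
        for k in ("d1b", "d2b"):
            params[k] = rng.standard_normal(params[k].shape) * 0.1
        f = rng.standard_normal((6, TINY.feature_dim))
        y = np.array([0, 1, 2, 0, 1, 2])
        centers = rng.standard_normal((3, TINY.feature_dim))
        comps, df, _ = aux_loss_and_feature_grad(f, y, params, centers, TINY)
        assert comps.total == pytest.approx(
            comps.ls + TINY.lambda1 * comps.lc + TINY.lambda2 * comps.ld
        )
        eps = 1e-6
        idx = rng.choice(f.size, size=20, replace=False)
        for fi in idx:
            mi = np.unravel_index(fi, f.shape)
            fp, fmn = f.copy(), f.copy()
            fp[mi] += eps
            fmn[mi] -= eps
            lp, _, _ = aux_loss_and_feature_grad(fp, y, params, centers, TINY)
            lm, _, _ = aux_loss_and_feature_grad(fmn, y, params, centers, TINY)
            fd = (lp.total - lm.total) / (2 * eps)
            assert df[mi] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_extractor_gradients_match_finite_differences(self):
        """Backprop through conv blocks, GRU and dense head agrees with
        central differences on every parameter family."""
        rng = np.random.default_rng(2)
        params = init_params(TINY, rng)
        for k in params:  # avoid exact ReLU kinks from zero biases
            if k.endswith("b") or k.endswith(("bz", "br", "bn")):
                params[k] = rng.standard_normal(params[k].shape) * 0.05
        x = rng.standard_normal((4, TINY.input_len))
        y = np.array([0, 1, 2, 1])
        centers = rng.standard_normal((3, TINY.feature_dim))

        def loss():
            f, _ = cg._forward_features(x, params, TINY)
            comps, _, _ = aux_loss_and_feature_grad(f, y, params, centers, TINY)
            return comps.total

        f, cache = cg._forward_features(x, params, TINY)
        _, df, head_grads = aux_loss_and_feature_grad(f, y, params, centers, TINY)
        grads = cg._backprop_extractor(x, df, params, cache, TINY)
        grads.update(head_grads)
        eps = 1e-6
        for key, g in grads.items():
            for fi in np.random.default_rng(5).choice(
                g.size, size=min(4, g.size), replace=False
            ):
                mi = np.unravel_index(fi, g.shape)
                p0 = params[key][mi]
                params[key][mi] = p0 + eps
                lp = loss()
                params[key][mi] = p0 - eps
                lm = loss()
                params[key][mi] = p0
                fd = (lp - lm) / (2 * eps)
                assert g[mi] == pytest.approx(fd, rel=1e-4, abs=1e-7), key


class TestFeatureExtraction:
    def test_output_dimension_contract(self):
        rng = np.random.default_rng(0)
        cfg = CGSVMConfig()
        params = init_params(cfg, rng)
        f = extract_features(rng.standard_normal(40), params, cfg)
        assert f.shape == (cfg.conv_out_len * 64 + cfg.gru_hidden,)
        assert cfg.conv_out_len == 31  # 40 -> 36 -> 33 -> 31

    def test_inference_deterministic(self):
        rng = np.random.default_rng(0)
        cfg = CGSVMConfig()
        params = init_params(cfg, rng)
        x = rng.standard_normal((3, 40))
        np.testing.assert_array_equal(
            extract_features(x, params, cfg), extract_features(x, params, cfg)
        )

    def test_zero_input_zero_biases_gives_zero_features(self):
        cfg = CGSVMConfig()
        params = init_params(cfg, np.random.default_rng(1))
        f = extract_features(np.zeros(40), params, cfg)
        np.testing.assert_allclose(f, 0.0)

    def test_wrong_length_rejected(self):
        cfg = CGSVMConfig()
        params = init_params(cfg, np.random.default_rng(1))
        with pytest.raises(ValueError):
            extract_features(np.zeros(39), params, cfg)


class TestTraining:
    def test_separable_set_learned(self, toy_split, toy_model):
        pred = predict(toy_model, toy_split.train.X())
        assert (pred == toy_split.train.y()).mean() >= 0.99

    def test_same_seed_identical_loss_trajectory(self, toy_split, toy_model):
        again = train(toy_split, CGSVMConfig(n_classes=4, epochs=50, seed=1))
        np.testing.assert_array_equal(
            toy_model.history["loss"], again.history["loss"]
        )

    def test_margin_frozen_after_warmup(self, toy_model):
        assert toy_model.k_used is not None and toy_model.k_used > 0
        assert toy_model.config.K == toy_model.k_used

    def test_within_class_compactness_improves(self, toy_model):
        h = toy_model.history["mean_center_dist"]
        assert h.iloc[-1] < h.iloc[0]

    def test_prediction_batch_invariance_and_permutation(self, toy_split, toy_model):
        x = toy_split.test.X()
        batch = predict(toy_model, x)
        single = np.array([predict(toy_model, xi) for xi in x])
        np.testing.assert_array_equal(batch, single)
        perm = np.random.default_rng(0).permutation(len(x))
        np.testing.assert_array_equal(predict(toy_model, x[perm]), batch[perm])

    def test_center_margin_term_keeps_centers_apart(self, toy_split, toy_model):
        """Training with the center distance penalty ends with a minimum
        pairwise squared center gap at least as large as without it."""
        plain = train(
            toy_split,
            CGSVMConfig(n_classes=4, epochs=50, seed=1, lambda2=0.0),
        )
        gap_with = toy_model.history["min_center_gap"].iloc[-1]
        gap_without = plain.history["min_center_gap"].iloc[-1]
        assert gap_with >= gap_without

    def test_wrong_input_length_rejected(self, toy_model):
        with pytest.raises(ValueError):
            predict(toy_model, np.zeros((2, 39)))

    def test_empty_training_set_rejected(self, toy_split):
        from eitgesture.synthetic_gestures import Dataset, DatasetSplit

        empty = DatasetSplit(train=Dataset((), "toy"), test=toy_split.test)
        with pytest.raises(ValueError):
            train(empty, CGSVMConfig(n_classes=4, epochs=1))
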