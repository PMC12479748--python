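"""Network equations, SMOTE geometry, SpecAugment and the ensemble rule."""

import numpy as np
import pytest

from ecgfusion import nn
from ecgfusion.models import (BiRNN, EnsembleWeights, ResNetBlock1d,
                              Subsystem2Model, birnn_forward, ensemble_predict,
                              fit_ensemble_weights, resnet_block_forward,
                              smote_oversample, spec_augment)


def finite_difference_check(params, loss_fn, n_per_param=5, eps=1e-6):
    """Max relative error between analytic and central-difference grads."""
    loss = loss_fn()
    loss.backward()
    worst = 0.0
    for p in params:
        g = p.grad.copy()
        for i in range(min(n_per_param, p.data.size)):
            idx = np.unravel_index(i, p.data.shape)
            orig = p.data[idx]
            p.data[idx] = orig + eps
            lp = float(loss_fn().data)
            p.data[idx] = orig - eps
            lm = float(loss_fn().data)
            p.data[idx] = orig
            fd = (lp - lm) / (2 * eps)
            worst = max(worst, abs(fd - g[idx]) / max(1.0, abs(fd)))
    return worst


class TestResNetBlock:
    def test_zero_weights_identity(self, rng):
        blk = ResNetBlock1d(rng, 4)
        for layer in (blk.conv1, blk.conv2):
            layer.w.data[:] = 0.0
            layer.b.data[:] = 0.0
        x = rng.normal(size=(2, 4, 6))
        np.testing.assert_array_equal(resnet_block_forward(x, blk), x)

    def test_output_shape_matches_input(self, rng):
        blk = ResNetBlock1d(rng, 8)
        x = rng.normal(size=(3, 8, 10))
        assert resnet_block_forward(x, blk).shape == x.shape

    def test_shape_mismatch_names_dimensions(self, rng):
        blk = ResNetBlock1d(rng, 8)
        with pytest.raises(ValueError, match="8"):
            resnet_block_forward(rng.normal(size=(3, 4, 10)), blk)

    def test_gradient_matches_finite_differences(self):
        # seed picked so no ReLU input sits at a kink, where central
        # differences are invalid; the precondition is asserted
        rng = np.random.default_rng(1)
        blk = ResNetBlock1d(rng, 3)
        blk.set_training(False)
        x = rng.normal(size=(2, 3, 5))

        pre1 = blk.bn1(nn.Tensor(x))
        pre2 = blk.bn2(blk.conv1(nn.relu(pre1)))
        assert min(np.abs(pre1.data).min(), np.abs(pre2.data).min()) > 1e-4

        def loss():
            out = blk(nn.Tensor(x))
            return nn.tsum(nn.mul(out, out))

        assert finite_difference_check(blk.params(), loss) < 1e-5


class TestBiRNN:
    def test_zero_parameters_emit_bias(self, rng):
        net = BiRNN(rng, 3, 4, 2)
        for p in net.params():
            p.data[:] = 0.0
        net.b_y.data[:] = [0.3, -0.7]
        ys, _, _ = birnn_forward(rng.normal(size=(5, 3)), net)
        np.testing.assert_array_equal(ys, np.tile([0.3, -0.7], (5, 1)))

    def test_time_reversal_swaps_directions(self, rng):
        net = BiRNN(rng, 3, 4, 2)
        net.w_b.data = net.w_f.data.copy()
        net.v_b.data = net.v_f.data.copy()
        net.b_b.data = net.b_f.data.copy()
        seq = rng.normal(size=(6, 3))
        _, fwd, bwd = birnn_forward(seq, net)
        _, fwd_rev, _ = birnn_forward(seq[::-1], net)
        np.testing.assert_allclose(fwd_rev, bwd[::-1], atol=1e-12)

    def test_single_step_symmetry_with_tied_params(self, rng):
        net = BiRNN(rng, 3, 4, 2)
        net.w_b.data = net.w_f.data.copy()
        net.v_b.data = net.v_f.data.copy()
        net.b_b.data = net.b_f.data.copy()
        _, fwd, bwd = birnn_forward(rng.normal(size=(1, 3)), net)
        np.testing.assert_allclose(fwd, bwd, atol=1e-12)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(2)
        net = BiRNN(rng, 2, 3, 2)
        seq = rng.normal(size=(4, 2))

        def loss():
            xs = [nn.Tensor(seq[t][None, :]) for t in range(4)]
            ys = net(xs)
            total = ys[0]
            for y in ys[1:]:
                total = total + y
            return nn.tsum(nn.mul(total, total))

        assert finite_difference_check(net.params(), loss, n_per_param=4) < 1e-5

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(ValueError):
            birnn_forward(np.empty((0, 3)), BiRNN(rng, 3, 4, 2))


class TestSmote:
    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(8, 3))
        y = np.array([0] * 4 + [1] * 4)
        Xo, yo = smote_oversample(X, y, seed=0)
        np.testing.assert_array_equal(Xo, X)
        np.testing.assert_array_equal(yo, y)

    def test_counts_and_original_preservation(self, rng):
        X = rng.normal(size=(14, 2))
        y = np.array([0] * 10 + [1] * 4)
        Xo, yo = smote_oversample(X, y, k=3, seed=1)
        assert (yo == 0).sum() == 10 and (yo == 1).sum() == 10
        np.testing.assert_array_equal(Xo[:14], X)

    def test_synthetic_points_on_minority_segments(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.array([0] * 22 + [1] * 8)
        Xo, yo = smote_oversample(X, y, k=5, seed=2)
        minority = X[y == 1]
        for s in Xo[30:]:
            d_min = np.inf
            for a in range(8):
                for b in range(8):
                    if a == b:
                        continue
                    u, v = minority[a], minority[b]
                    t = np.clip(np.dot(s - u, v - u) / np.dot(v - u, v - u), 0, 1)
                    d_min = min(d_min, np.linalg.norm(s - (u + t * (v - u))))
            assert d_min < 1e-9

    def test_tiny_minority_rejected_or_k_reduced(self, rng):
        X = rng.normal(size=(6, 2))
        with pytest.raises(ValueError):
            smote_oversample(X, np.array([0] * 5 + [1]), seed=0)
        with pytest.warns(UserWarning, match="k reduced"):
            Xo, yo = smote_oversample(rng.normal(size=(8, 2)),
                                      np.array([0] * 5 + [1] * 3), k=5, seed=0)
        assert (yo == 1).sum() == 5


class TestSpecAugment:
    def test_zero_masks_identity(self, rng):
        img = rng.uniform(size=(50, 60))
        np.testing.assert_array_equal(
            spec_augment(img, n_time_masks=0, n_freq_masks=0, seed=0), img)

    def test_single_time_mask_width(self, rng):
        img = rng.uniform(size=(50, 60))
        out = spec_augment(img, n_time_masks=1, n_freq_masks=0,
                           mask_width=10, seed=3)
        changed = np.where((out != img).any(axis=0))[0]
        assert changed.size == 10
        assert np.array_equal(changed, np.arange(changed[0], changed[0] + 10))
        np.testing.assert_allclose(out[:, changed], img.mean())

    def test_seed_reproducibility(self, rng):
        img = rng.uniform(size=(40, 40))
        a = spec_augment(img, seed=5)
        b = spec_augment(img, seed=5)
        assert np.array_equal(a, b)

    def test_mask_wider_than_image_rejected(self, rng):
        with pytest.raises(ValueError):
            spec_augment(rng.uniform(size=(10, 10)), mask_width=10)


class TestEnsemble:
    def test_identical_inputs_fixed_point(self):
        p = np.array([[0.7, 0.3]])
        _, out = ensemble_predict(p, p, EnsembleWeights(0.3, 0.7))
        np.testing.assert_allclose(out, p)

    def test_degenerate_weight_selects_one_subsystem(self):
        p1 = np.array([[0.9, 0.1]])
        p2 = np.array([[0.2, 0.8]])
        labels, out = ensemble_predict(p1, p2, EnsembleWeights(1.0, 0.0))
        np.testing.assert_allclose(out, p1)
        assert labels[0] == 0

    def test_hand_computed_example(self):
        labels, p = ensemble_predict([[0.9, 0.1]], [[0.2, 0.8]],
                                     EnsembleWeights(0.5, 0.5))
        np.testing.assert_allclose(p, [[0.55, 0.45]])
        assert labels[0] == 0

    def test_tie_breaks_toward_positive_class(self):
        labels, _ = ensemble_predict([[0.5, 0.5]], [[0.5, 0.5]])
        assert labels[0] == 0

    def test_probabilities_stay_normalized(self, rng):
        p1 = rng.dirichlet([1, 1], size=20)
        p2 = rng.dirichlet([1, 1], size=20)
        _, p = ensemble_predict(p1, p2, EnsembleWeights(0.25, 0.75))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_invalid_weights_and_shapes(self):
        with pytest.raises(ValueError):
            EnsembleWeights(0.6, 0.6)
        with pytest.raises(ValueError):
            EnsembleWeights(-0.1, 1.1)
        with pytest.raises(ValueError):
            ensemble_predict(np.ones((2, 2)), np.ones((2, 3)))

    def test_grid_search_recovers_better_subsystem(self, rng):
        y = np.array([0, 0, 1, 1])
        p_good = np.eye(2)[y][:, ::-1][:, ::-1]  # perfect
        p_bad = np.tile([0.5, 0.5], (4, 1))
        w = fit_ensemble_weights(p_good, p_bad, y)
        labels, _ = ensemble_predict(p_good, p_bad, w)
        assert (labels == y).all()


class TestSoftmax:
    def test_rows_sum_to_one(self, rng):
        logits = nn.Tensor(rng.normal(scale=10, size=(30, 5)))
        probs = nn.softmax(logits, axis=1).data
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
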