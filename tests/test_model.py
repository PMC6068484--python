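"""The branched network: forward pass, gradients, training."""
import numpy as np
import pytest

import edfnn
from edfnn import EDFNN, LayerParams, TrainConfig
from edfnn.errors import TrainingDivergenceError
from edfnn.embedding import DelayConfig, EmbeddedDataset


def make_dataset(X, Y, n_channels=1):
    n_lags = X.shape[1] // n_channels
    return EmbeddedDataset(
        Xd=X, Yd=Y, t_index=np.arange(len(X)),
        lags=np.arange(n_lags), n_channels=n_channels,
        cycle_ids=np.arange(len(X)) // 10,
    )


class TestPrimitives:
    def test_relu(self):
        np.testing.assert_array_equal(
            edfnn.relu(np.array([-1.0, 0.0, 2.5])), [0.0, 0.0, 2.5])

    def test_layer_forward_zero_weights_pass_bias(self):
        p = LayerParams(np.zeros((3, 4)), np.array([-1.0, 0.0, 2.0]))
        np.testing.assert_array_equal(
            edfnn.layer_forward(np.ones(4), p), [0.0, 0.0, 2.0])

    def test_layer_forward_identity_on_nonnegative(self):
        p = LayerParams(np.eye(3), np.zeros(3))
        a = np.array([0.5, 0.0, 2.0])
        np.testing.assert_array_equal(edfnn.layer_forward(a, p), a)

    def test_layer_forward_hand_computed(self):
        p = LayerParams(np.array([[1.0, -1.0]]), np.array([0.5]))
        np.testing.assert_array_equal(
            edfnn.layer_forward(np.array([2.0, 1.0]), p), [1.5])

    def test_layer_forward_shape_mismatch(self):
        p = LayerParams(np.zeros((2, 3)), np.zeros(2))
        with pytest.raises(ValueError):
            edfnn.layer_forward(np.ones(4), p)

    def test_concat_branches(self):
        a, b = np.arange(6.0), np.arange(6.0) + 10
        assert edfnn.concat_branches([a, b]).shape == (12,)
        np.testing.assert_array_equal(edfnn.concat_branches([a]), a)


class TestMseCost:
    def test_zero_on_equal(self):
        assert edfnn.mse_cost(np.ones((4, 1)), np.ones((4, 1))) == 0.0

    def test_half_factor(self):
        # one row, scalar residual 0.2 -> 0.5 * 0.04
        assert edfnn.mse_cost([[0.5]], [[0.3]]) == pytest.approx(0.02)

    def test_quadratic_homogeneity(self, rng):
        p = rng.normal(size=(8, 2))
        t = rng.normal(size=(8, 2))
        c1 = edfnn.mse_cost(p, t)
        c2 = edfnn.mse_cost(t + 2 * (p - t), t)
        assert c2 == pytest.approx(4 * c1)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            edfnn.mse_cost(np.ones((3, 1)), np.ones((4, 1)))


class TestForward:
    def test_all_zero_parameters_give_zero_output(self, rng):
        m = EDFNN([4, 3], f=2, seed=0)
        m.params[:] = 0.0
        out = m.forward(rng.normal(size=(5, 7)))
        np.testing.assert_array_equal(out, np.zeros((5, 2)))

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(5, 7))
        out1 = EDFNN([4, 3], f=1, seed=3).forward(X)
        out2 = EDFNN([4, 3], f=1, seed=3).forward(X)
        np.testing.assert_array_equal(out1, out2)

    def test_layout_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            EDFNN([4, 3], f=1).forward(rng.normal(size=(2, 6)))

    def test_hand_computed_toy_network(self):
        """3-feature single branch with hand-set weights, checked on paper."""
        m = EDFNN([3], f=1, hidden=2, seed=0)
        m.params[:] = 0.0
        layers = m._layers()
        layers[0].theta[...] = [[1.0, 0.0, -1.0], [0.5, 0.5, 0.5]]
        layers[0].bias[...] = [0.0, -0.25]
        layers[1].theta[...] = [[1.0, 2.0], [-1.0, 1.0]]
        layers[2].theta[...] = [[3.0, 1.0]]
        layers[2].bias[...] = [0.1]
        # x = [1, 2, 0.5]: z1 = [0.5, 1.5] -> a1 = [0.5, 1.5]
        # z2 = [0.5+3.0, -0.5+1.5] = [3.5, 1.0] -> a2 = [3.5, 1.0]
        # out = 3*3.5 + 1*1.0 + 0.1 = 11.6
        out = m.forward(np.array([[1.0, 2.0, 0.5]]))
        assert out[0, 0] == pytest.approx(11.6)

    def test_branched_equals_block_diagonal_single_network(self, rng):
        """Oracle: the two-branch net is output-identical to one network whose
        first/second layers carry block-diagonal weights."""
        m = EDFNN([5, 4], f=2, seed=11)
        layers = m._layers()
        X = rng.normal(size=(20, 9))

        def block_diag(a, b):
            out = np.zeros((a.shape[0] + b.shape[0], a.shape[1] + b.shape[1]))
            out[:a.shape[0], :a.shape[1]] = a
            out[a.shape[0]:, a.shape[1]:] = b
            return out

        l1 = LayerParams(block_diag(layers[0].theta, layers[2].theta),
                         np.concatenate([layers[0].bias, layers[2].bias]))
        l2 = LayerParams(block_diag(layers[1].theta, layers[3].theta),
                         np.concatenate([layers[1].bias, layers[3].bias]))
        a1 = edfnn.layer_forward(X, l1)
        a2 = edfnn.layer_forward(a1, l2)
        oracle = edfnn.layer_forward(a2, layers[4], activation=None)
        np.testing.assert_allclose(m.forward(X), oracle, rtol=1e-12)


class TestGradients:
    def test_gradient_check_against_central_differences(self, rng):
        """Analytic gradients match central finite differences to <= 1e-5
        relative error on random small models."""
        for seed in range(3):
            m = EDFNN([4, 3], f=2, hidden=3, seed=seed)
            r = np.random.default_rng(seed)
            X = r.normal(size=(6, 7))
            Y = r.uniform(0, 1, size=(6, 2))
            grad, _ = m.gradients(X, Y)
            h = 1e-6
            num = np.empty_like(grad)
            for i in range(len(m.params)):
                orig = m.params[i]
                m.params[i] = orig + h
                cp = edfnn.mse_cost(m._forward(X), Y)
                m.params[i] = orig - h
                cm = edfnn.mse_cost(m._forward(X), Y)
                m.params[i] = orig
                num[i] = (cp - cm) / (2 * h)
            rel = np.linalg.norm(grad - num) / max(np.linalg.norm(grad), 1e-12)
            assert rel <= 1e-5


class TestTraining:
    def test_realizable_linear_target_reaches_tiny_cost(self, rng):
        """Features linearly encode the target (least-squares oracle residual
        ~0), so training must drive the cost below 1e-3."""
        X = rng.normal(size=(600, 8))
        w = rng.uniform(-0.2, 0.2, 8)
        y = (X @ w + 0.5).reshape(-1, 1)
        # independent oracle: the target is exactly realizable
        resid = np.linalg.lstsq(np.column_stack([X, np.ones(len(X))]), y, rcond=None)[1]
        assert float(resid.squeeze()) < 1e-18
        ds = make_dataset(X, y, n_channels=2)
        m = EDFNN.for_dataset(ds, channels_per_sensor=1, seed=0)
        curve = edfnn.train(m, ds, TrainConfig(epochs=300, seed=0))
        assert curve.train[-1] < 1e-3

    def test_same_seed_bitwise_identical_curves(self, small_embedded):
        cfg = TrainConfig(epochs=5, seed=42)
        runs = []
        for _ in range(2):
            m = EDFNN.for_dataset(small_embedded, seed=42)
            runs.append(edfnn.train(m, small_embedded, cfg).train)
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_smoothed_learning_curve_non_increasing(self, small_embedded):
        m = EDFNN.for_dataset(small_embedded, seed=1)
        curve = edfnn.train(m, small_embedded,
                            TrainConfig(epochs=60, seed=1)).train
        smooth = np.convolve(curve, np.ones(10) / 10, mode="valid")
        assert np.all(np.diff(smooth) <= 1e-4)

    def test_divergence_raises_with_epoch(self, small_embedded):
        m = EDFNN.for_dataset(small_embedded, seed=0)
        with pytest.raises(TrainingDivergenceError):
            edfnn.train(m, small_embedded,
                        TrainConfig(learning_rate=1e6, epochs=5,
                                    optimizer="gradient-descent", seed=0))

    def test_gradient_descent_optimizer_also_learns(self, small_embedded):
        m = EDFNN.for_dataset(small_embedded, seed=0)
        curve = edfnn.train(m, small_embedded,
                            TrainConfig(learning_rate=0.05, epochs=30,
                                        optimizer="gradient-descent", seed=0)).train
        assert curve[-1] < curve[0]


class TestForecast:
    def test_clamped_to_unit_interval(self):
        m = EDFNN([2], f=1, hidden=2, seed=0)
        m.params[:] = 0.0
        m._layers()[-1].bias[...] = [1.3]  # raw output 1.3
        out = m.forecast(np.zeros((1, 2)))
        assert out[0, 0] == np.nextafter(1.0, 0.0)
        m._layers()[-1].bias[...] = [-0.7]
        assert m.forecast(np.zeros((1, 2)))[0, 0] == 0.0

    def test_trained_model_tracks_ramp(self, small_embedded):
        """On a clean synthetic subject the one-step forecast lands within
        0.05 of the generator's true next-sample percent."""
        tr, va = edfnn.split_train_validation(small_embedded, seed=0)
        m = EDFNN.for_dataset(tr, seed=0)
        edfnn.train(m, tr, TrainConfig(epochs=120, seed=0))
        pred = m.forecast(va.Xd)
        err = np.abs(pred - va.Yd)
        assert np.median(err) < 0.05

    def test_roundtrip_serialization(self, small_embedded, tmp_path, rng):
        m = EDFNN.for_dataset(small_embedded, seed=5)
        m.delay_config = DelayConfig()
        edfnn.train(m, small_embedded, TrainConfig(epochs=3, seed=5))
        p = tmp_path / "model.npz"
        m.save(p)
        m2 = EDFNN.load(p)
        X = small_embedded.Xd[:10]
        np.testing.assert_array_equal(m.forward(X), m2.forward(X))
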