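import numpy as np
import pytest

from bcdnet.classifier import (BCDCNNClassifier, ClassifierState, TrainConfig,
                               caviar_update, ces_gradient, ces_loss, predict,
                               softmax, train)


class TestSoftmax:
    def test_uniform_logits(self):
        np.testing.assert_allclose(softmax(np.zeros(2)), [0.5, 0.5])

    def test_large_logits_stable(self):
        t = softmax(np.array([1000.0, 0.0]))
        assert np.all(np.isfinite(t))
        assert t[0] == pytest.approx(1.0)

    def test_sums_to_one(self, rng):
        for _ in range(20):
            t = softmax(rng.normal(0, 10, 7))
            assert t.sum() == pytest.approx(1.0, abs=1e-12)


class TestLoss:
    def test_one_hot_prediction_zero_loss(self):
        assert ces_loss(np.array([0.0, 1.0]), 1) == 0.0

    def test_worked_example(self):
        assert ces_loss(np.array([0.7, 0.3]), 1) == pytest.approx(-0.4 * np.log(0.3))

    def test_correct_but_not_confident_zero_loss(self):
        # t_eps equals t_max, so the ambiguity weight vanishes
        assert ces_loss(np.array([0.6, 0.4]), 0) == 0.0

    def test_ordering_in_ambiguity_weight(self):
        # harder samples (larger t_max - t_eps) weigh strictly more
        t_eps = 0.1
        losses = [ces_loss(np.array([t_eps, tm, 1 - t_eps - tm]), 0)
                  for tm in (0.5, 0.6, 0.7)]
        assert losses[0] < losses[1] < losses[2]


class TestGradient:
    def test_perfect_prediction_zero_gradient(self):
        np.testing.assert_array_equal(ces_gradient(np.array([1.0, 0.0]), 0), 0.0)

    def test_plugin_example(self):
        g = ces_gradient(np.array([0.7, 0.3]), 1)
        np.testing.assert_allclose(g, [0.28, -0.28])
        np.testing.assert_allclose(g, 0.4 * (np.array([0.7, 0.3]) - np.array([0, 1.0])))

    @pytest.mark.parametrize("n_classes", [2, 3, 5])
    def test_matches_finite_differences(self, n_classes):
        rng = np.random.default_rng(n_classes)
        for _ in range(100):
            a = rng.normal(0, 2, n_classes)
            eps = int(rng.integers(n_classes))
            t = softmax(a)
            weight = t.max() - t[eps]  # frozen
            grad = ces_gradient(t, eps)
            num = np.zeros(n_classes)
            for u in range(n_classes):
                for sgn in (1, -1):
                    ap = a.copy()
                    ap[u] += sgn * 1e-6
                    tp = softmax(ap)
                    num[u] += sgn * (-weight * np.log(max(tp[eps], 1e-12))) / 2e-6
            np.testing.assert_allclose(grad, num, atol=1e-5)

    def test_zero_exactly_when_true_class_is_max(self, rng):
        for _ in range(20):
            t = softmax(rng.normal(0, 2, 4))
            eps = int(np.argmax(t))
            assert ces_loss(t, eps) == 0.0
            np.testing.assert_array_equal(ces_gradient(t, eps), 0.0)


def _state(errors, lag1=None, prev_grad=None, lr=0.1, phi0=0.0):
    return ClassifierState(
        conv_params=None, dense_params=None,
        output_weights=np.array([[1.0, 2.0], [3.0, 4.0]]),
        lag1_weights=lag1, prev_gradient=prev_grad,
        errors=list(errors), learning_rate=lr, phi0=phi0,
    )


class TestCaviarUpdate:
    def test_no_history_plain_gradient_step(self):
        st = _state([0.5])
        grad = np.ones((2, 2))
        g0 = st.output_weights.copy()
        g_new = caviar_update(st, grad)
        np.testing.assert_allclose(g_new, g0 - 0.1 * grad)
        np.testing.assert_array_equal(st.lag1_weights, g0)

    def test_equal_errors_blend_equally(self):
        lag1 = np.zeros((2, 2))
        prev_grad = np.zeros((2, 2))
        st = _state([0.3, 0.3, 0.3], lag1=lag1, prev_grad=prev_grad)
        g0 = st.output_weights.copy()
        grad = np.full((2, 2), 2.0)
        g_new = caviar_update(st, grad)
        np.testing.assert_allclose(g_new, 0.5 * g0 + 0.5 * lag1 - 0.1 * (0.5 * grad))

    def test_identical_lags_reduce_to_plain_step(self):
        g0 = np.array([[1.0, -1.0]])
        grad = np.array([[0.5, 0.25]])
        st = ClassifierState(None, None, g0.copy(), lag1_weights=g0.copy(),
                             prev_gradient=grad.copy(),
                             errors=[0.4, 0.2, 0.1], learning_rate=0.2)
        g_new = caviar_update(st, grad)
        np.testing.assert_allclose(g_new, g0 - 0.2 * grad)

    def test_zero_lagged_error_uses_max_ratio(self):
        st = _state([0.0, 0.0, 0.5], lag1=np.zeros((2, 2)), prev_grad=np.zeros((2, 2)))
        g_new = caviar_update(st, np.zeros((2, 2)))  # phi1 = clamp(0.5/0)=phi_max
        assert np.all(np.isfinite(g_new))


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal([-2, -2], 0.5, (40, 2)),
                   rng.normal([2, 2], 0.5, (40, 2))])
    y = np.array([0] * 40 + [1] * 40)
    return X, y


class TestTraining:
    def test_separable_toy_reaches_perfect_accuracy(self, toy_data):
        X, y = toy_data
        # the ambiguity-weighted gradient vanishes near the boundary, so the
        # step size must be generous for samples to cross it
        cfg = TrainConfig(epochs=50, use_conv=False, learning_rate=30.0, seed=0)
        state = train(list(X), y, cfg)
        labels, _ = predict(state, list(X))
        assert np.mean(labels == y) == 1.0

    def test_loss_descends_across_seeds(self, toy_data):
        X, y = toy_data
        for seed in range(5):
            cfg = TrainConfig(epochs=50, use_conv=False, learning_rate=30.0, seed=seed)
            state = train(list(X), y, cfg)
            assert state.loss_history[-1] <= state.loss_history[0]

    def test_caviar_ablation_is_nondestructive(self, toy_data):
        X, y = toy_data
        for caviar in (True, False):
            cfg = TrainConfig(epochs=50, use_conv=False, learning_rate=30.0,
                              seed=1, use_caviar=caviar)
            state = train(list(X), y, cfg)
            labels, _ = predict(state, list(X))
            assert np.mean(labels == y) == 1.0

    def test_conv_branch_learns_blob_polarity(self):
        rng = np.random.default_rng(3)
        samples, ys = [], []
        for i in range(40):
            im = rng.normal(0, 0.1, (2, 16, 16))
            im[0, 4:12, 4:12] += 1.0 if i % 2 else -1.0
            samples.append((np.zeros(3), im))
            ys.append(i % 2)
        cfg = TrainConfig(epochs=40, use_conv=True, use_dense=False,
                          conv_channels=(4, 8), learning_rate=0.5, seed=0)
        state = train(samples, ys, cfg)
        assert state.loss_history[-1] < state.loss_history[0] / 10

    def test_requires_a_branch(self):
        with pytest.raises(ValueError, match="use_conv"):
            train([np.zeros(2)], [0], TrainConfig(use_conv=False, use_dense=False))


class TestPredict:
    def test_tie_breaks_toward_lower_class(self, toy_data):
        X, y = toy_data
        state = train(list(X), y, TrainConfig(epochs=1, use_conv=False, seed=0))
        state.output_weights[:] = 0.0  # force identical logits
        labels, t = predict(state, list(X[:5]))
        assert np.all(labels == 0)
        np.testing.assert_allclose(t.sum(axis=1), 1.0)


def test_sklearn_estimator_interface(toy_data):
    X, y = toy_data
    clf = BCDCNNClassifier(epochs=30, learning_rate=30.0, seed=0)
    clf.fit(X, y)
    assert set(clf.classes_) == {0, 1}
    proba = clf.predict_proba(X)
    assert proba.shape == (80, 2)
    assert clf.score(X, y) > 0.9
    assert clf.get_params()["epochs"] == 30
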