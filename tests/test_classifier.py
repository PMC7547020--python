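import numpy as np
import pytest

from radopt.classifier import (
    ACTIVATION_NAMES,
    ClassifierConfig,
    apply_dropout,
    class_probabilities,
    cross_entropy_loss,
    encode_labels,
    forward,
    loss_and_gradients,
    make_optimizer,
    predict_classes,
    predict_scores,
    train_classifier,
)


def _toy_problem(n=40, dim=6, seed=0, sep=3.0):
    """Linearly separable two-class embedding problem."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, dim))
    labels = ["ACP" if i % 2 == 0 else "NOTACP" for i in range(n)]
    shift = np.zeros(dim)
    shift[0] = sep
    x[[l == "ACP" for l in labels]] += shift
    return x, labels


class TestForward:
    def test_softmax_rows_are_probabilities(self, rng):
        x = rng.standard_normal((5, 4))
        w = rng.standard_normal((4, 2))
        out = forward(x, w, np.zeros(2), "softmax")
        np.testing.assert_allclose(out.sum(axis=1), 1.0)
        assert np.all(out >= 0)

    def test_log_softmax_is_log_of_softmax(self, rng):
        x = rng.standard_normal((5, 4))
        w = rng.standard_normal((4, 2))
        np.testing.assert_allclose(
            forward(x, w, np.zeros(2), "log_softmax"),
            np.log(forward(x, w, np.zeros(2), "softmax")),
        )

    def test_identity_returns_logits(self, rng):
        x = rng.standard_normal((5, 4))
        w = rng.standard_normal((4, 2))
        b = rng.standard_normal(2)
        np.testing.assert_allclose(forward(x, w, b, "identity"), x @ w + b)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dim"):
            forward(np.zeros((2, 3)), np.zeros((4, 2)), np.zeros(2))

    @pytest.mark.parametrize("activation", ACTIVATION_NAMES)
    def test_all_activations_finite(self, activation, rng):
        x = rng.standard_normal((8, 3)) * 10
        w = rng.standard_normal((3, 2))
        out = forward(x, w, np.zeros(2), activation)
        assert np.all(np.isfinite(out))


class TestLoss:
    def test_perfect_prediction_near_zero(self):
        y = encode_labels(["ACP", "NOTACP"])
        yhat = np.array([[1e-12, 1 - 1e-12], [1 - 1e-12, 1e-12]])
        assert cross_entropy_loss(y, yhat) < 1e-9

    def test_uniform_prediction_is_log2(self):
        y = encode_labels(["ACP", "NOTACP", "ACP"])
        yhat = np.full((3, 2), 0.5)
        assert cross_entropy_loss(y, yhat) == pytest.approx(np.log(2))

    def test_penalties_add_expected_amounts(self):
        y = encode_labels(["ACP", "NOTACP"])
        yhat = np.full((2, 2), 0.5)
        w = np.array([[1.0, -2.0]])
        base = cross_entropy_loss(y, yhat)
        assert cross_entropy_loss(y, yhat, w, "l1", l1_coeff=0.1) == pytest.approx(
            base + 0.1 * 3.0
        )
        assert cross_entropy_loss(y, yhat, w, "l2", l2_coeff=0.1) == pytest.approx(
            base + 0.1 * 5.0
        )
        assert cross_entropy_loss(
            y, yhat, w, "l1l2", l1_coeff=0.1, l2_coeff=0.1
        ) == pytest.approx(base + 0.1 * 3.0 + 0.1 * 5.0)

    def test_rejects_non_probability_rows(self):
        y = encode_labels(["ACP"])
        with pytest.raises(ValueError, match="probability"):
            cross_entropy_loss(y, np.array([[0.7, 0.7]]))


class TestDropout:
    def test_eval_phase_is_identity(self, rng):
        x = rng.standard_normal((4, 8))
        np.testing.assert_array_equal(apply_dropout(x, 0.5, rng, phase="eval"), x)

    def test_keep_prob_one_is_identity(self, rng):
        x = rng.standard_normal((4, 8))
        np.testing.assert_array_equal(apply_dropout(x, 1.0, rng, phase="train"), x)

    def test_survivors_scaled_by_inverse_keep_prob(self, rng):
        x = np.ones((200, 50))
        out = apply_dropout(x, 0.25, rng, phase="train")
        kept = out[out != 0]
        np.testing.assert_allclose(kept, 4.0)
        assert abs(out.mean() - 1.0) < 0.05  # unbiased in expectation

    def test_invalid_keep_prob(self, rng):
        with pytest.raises(ValueError):
            apply_dropout(np.ones(3), 0.0, rng)


class TestGradients:
    @pytest.mark.parametrize("activation", ACTIVATION_NAMES)
    @pytest.mark.parametrize("reg_mode", ["none", "l2"])
    def test_central_difference_check(self, activation, reg_mode):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((12, 5))
        y = encode_labels(["ACP" if i % 2 else "NOTACP" for i in range(12)])
        w = rng.standard_normal((5, 2)) * 0.3
        b = rng.standard_normal(2) * 0.1
        _, gw, gb = loss_and_gradients(x, y, w, b, activation, reg_mode)
        h = 1e-6

        def loss_at(wp, bp):
            p = class_probabilities(x, wp, bp, activation)
            return cross_entropy_loss(y, p, wp, reg_mode)

        for idx in np.ndindex(w.shape):
            wp, wm = w.copy(), w.copy()
            wp[idx] += h
            wm[idx] -= h
            num = (loss_at(wp, b) - loss_at(wm, b)) / (2 * h)
            assert abs(num - gw[idx]) <= 1e-5
        for j in range(2):
            bp, bm = b.copy(), b.copy()
            bp[j] += h
            bm[j] -= h
            num = (loss_at(w, bp) - loss_at(w, bm)) / (2 * h)
            assert abs(num - gb[j]) <= 1e-5


class TestOptimizers:
    def _run(self, spec, lr=0.1, steps=200):
        """Minimize a simple quadratic f(p) = sum(p^2) from p=ones."""
        opt = make_optimizer(spec, lr)
        p = np.ones(4)
        for _ in range(steps):
            p = opt.update(0, p, 2 * p)
        return p

    @pytest.mark.parametrize(
        "name",
        ["Gradient Descent", "Momentum", "Adam", "Adagrad", "RMSProp", "FTRL"],
    )
    def test_quadratic_convergence(self, name):
        p = self._run({"name": name})
        assert np.all(np.abs(p) < 0.1)

    def test_adadelta_moves_downhill(self):
        # Adadelta's effective step is tiny early on; just check descent.
        p = self._run({"name": "Adadelta"}, lr=1.0, steps=500)
        assert np.all(np.abs(p) < 1.0)

    def test_sgd_matches_closed_form(self):
        opt = make_optimizer({"name": "Gradient Descent"}, 0.5)
        p = opt.update(0, np.array([2.0]), np.array([1.0]))
        np.testing.assert_allclose(p, [1.5])

    def test_proximal_l1_soft_thresholds_small_weights(self):
        opt = make_optimizer(
            {"name": "Proximal Adagrad", "proximal_reg": "l1"}, 0.1
        )
        p = np.array([1e-6, 1.0])
        new = opt.update(0, p, np.zeros(2))
        assert new[0] == 0.0  # thresholded to exactly zero
        assert new[1] > 0.9

    def test_proximal_l2_shrinks_multiplicatively(self):
        opt = make_optimizer(
            {"name": "Proximal Adadelta", "proximal_reg": "l2"}, 1.0
        )
        p = np.array([1.0])
        new = opt.update(0, p, np.zeros(1))
        np.testing.assert_allclose(new, 1.0 / 1.001)

    def test_unknown_name(self):
        with pytest.raises(ValueError, match="Nadam"):
            make_optimizer({"name": "Nadam"}, 0.1)


class TestTraining:
    def test_separable_problem_reaches_high_accuracy(self):
        x, labels = _toy_problem(sep=5.0)  # well past the class overlap regime
        clf = train_classifier(
            x, labels, ClassifierConfig(epochs=300, learning_rate=0.1)
        )
        preds = predict_classes(clf, x)
        assert np.mean([p == l for p, l in zip(preds, labels)]) >= 0.95

    def test_loss_trace_decreases_whole_batch(self):
        x, labels = _toy_problem()
        clf = train_classifier(x, labels, ClassifierConfig(epochs=100))
        assert clf.loss_trace[-1] < clf.loss_trace[0]

    def test_deterministic_given_seed(self):
        x, labels = _toy_problem()
        cfg = ClassifierConfig(epochs=30, batch_size=8, keep_prob=0.75, seed=5)
        a = train_classifier(x, labels, cfg)
        b = train_classifier(x, labels, cfg)
        np.testing.assert_array_equal(a.w, b.w)
        np.testing.assert_array_equal(a.b, b.b)

    def test_batch_none_equals_batch_ge_n(self):
        x, labels = _toy_problem(n=20)
        a = train_classifier(x, labels, ClassifierConfig(epochs=20, batch_size=None))
        b = train_classifier(x, labels, ClassifierConfig(epochs=20, batch_size=500))
        np.testing.assert_allclose(a.w, b.w)

    def test_standardization_folds_back_exactly(self):
        """Scores from folded-back raw-space parameters equal scores computed
        in standardized space."""
        x, labels = _toy_problem()
        x = x * 7.0 + 3.0  # badly scaled embeddings
        clf = train_classifier(x, labels, ClassifierConfig(epochs=50))
        mu, sigma = x.mean(axis=0), x.std(axis=0)
        xs = (x - mu) / sigma
        clf_std = train_classifier(
            xs, labels, ClassifierConfig(epochs=50, standardize=False)
        )
        np.testing.assert_allclose(
            predict_scores(clf, x), predict_scores(clf_std, xs), atol=1e-10
        )

    def test_single_class_rejected(self):
        x = np.random.default_rng(0).standard_normal((5, 3))
        with pytest.raises(ValueError, match="each class"):
            train_classifier(x, ["ACP"] * 5, ClassifierConfig())

    @pytest.mark.parametrize("activation", ACTIVATION_NAMES)
    def test_every_activation_trains(self, activation):
        x, labels = _toy_problem(n=30)
        cfg = ClassifierConfig(activation=activation, epochs=50, learning_rate=0.05)
        clf = train_classifier(x, labels, cfg)
        scores = predict_scores(clf, x)
        assert np.all(np.isfinite(scores))

    def test_l1_regularization_sparsifies(self):
        x, labels = _toy_problem(dim=10)
        dense = train_classifier(x, labels, ClassifierConfig(epochs=200))
        sparse = train_classifier(
            x,
            labels,
            ClassifierConfig(epochs=200, reg_mode="l1", l1_coeff=0.05),
        )
        assert np.abs(sparse.w).sum() < np.abs(dense.w).sum()
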