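import numpy as np
import pytest

from rehab_imu.classify import (
    ClassifierBank,
    LogisticModel,
    fit_bank,
    fit_logistic,
    fit_projection,
    load_bundle,
    predict_binary,
    predict_multiclass,
    predict_proba,
    project,
    reconstruct,
    save_bundle,
)


def newton_raphson_logistic(X, y, lam, iters=200):
    """Independent IRLS oracle: penalized ML for logistic regression with
    an unpenalized intercept."""
    X1 = np.hstack([X, np.ones((len(X), 1))])
    d = X1.shape[1]
    P = np.eye(d)
    P[-1, -1] = 0.0
    w = np.zeros(d)
    for _ in range(iters):
        p = 1.0 / (1.0 + np.exp(-(X1 @ w)))
        g = X1.T @ (y - p) - lam * (P @ w)
        H = -(X1.T * (p * (1 - p))) @ X1 - lam * P
        w = w - np.linalg.solve(H, g)
        if np.max(np.abs(g)) < 1e-12:
            break
    return w[:-1], w[-1]


class TestProjection:
    def test_rank_two_data_keeps_two_components(self):
        rng = np.random.default_rng(0)
        n = 40
        X = np.zeros((n, 10))
        X[:, 2] = rng.normal(size=n)
        X[:, 7] = rng.normal(size=n)
        X += 3.0  # constant offset everywhere
        model = fit_projection(X)
        assert model.k == 2
        scores = project(model, X)
        np.testing.assert_allclose(reconstruct(model, scores), X, atol=1e-8)

    def test_selection_rule_is_smallest_k_reaching_threshold(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 8)) * np.array([10, 6, 3, 2, 1, .5, .2, .1])
        model = fit_projection(X)
        cum = np.cumsum(model.explained_variance_ratio)
        assert cum[model.k - 1] >= 0.99 - 1e-12
        if model.k > 1:
            assert cum[model.k - 2] < 0.99

    def test_matches_correlation_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 6)) @ rng.normal(size=(6, 6)) + rng.normal(size=6)
        n = len(X)
        Z = (X - X.mean(0)) / X.std(0)
        evals, evecs = np.linalg.eigh(Z.T @ Z / n)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        model = fit_projection(X)
        np.testing.assert_allclose(
            model.explained_variance_ratio, evals / evals.sum(), atol=1e-9
        )
        np.testing.assert_allclose(
            model.explained_variance, evals[: model.k] * n / (n - 1), atol=1e-9
        )
        for i in range(model.k):
            dot = abs(np.dot(model.components[i], evecs[:, i]))
            assert dot == pytest.approx(1.0, abs=1e-9)

    def test_loadings_are_orthonormal(self):
        rng = np.random.default_rng(3)
        model = fit_projection(rng.normal(size=(30, 12)))
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(model.k), atol=1e-8)

    def test_projecting_training_mean_gives_zero(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 5)) + 7
        model = fit_projection(X)
        np.testing.assert_allclose(project(model, X.mean(0)), 0.0, atol=1e-9)

    def test_projected_training_variance_reproduces_spectrum(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 6)) * np.array([5, 3, 2, 1, .5, .1])
        model = fit_projection(X)
        scores = project(model, X)
        np.testing.assert_allclose(
            scores.var(axis=0, ddof=1), model.explained_variance, atol=1e-9
        )

    def test_projection_is_affine(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 4))
        model = fit_projection(X)
        x, y, alpha = rng.normal(size=4), rng.normal(size=4), 0.3
        lhs = project(model, alpha * x + (1 - alpha) * y)
        rhs = alpha * project(model, x) + (1 - alpha) * project(model, y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_dimension_mismatch_and_tiny_input_rejected(self):
        model = fit_projection(np.random.default_rng(7).normal(size=(10, 3)))
        with pytest.raises(ValueError, match="feature count"):
            project(model, np.zeros(5))
        with pytest.raises(ValueError):
            fit_projection(np.zeros((1, 3)))


class TestLogistic:
    def test_separable_data_classified_perfectly(self):
        X = np.array([[-3.0], [-2.0], [-1.5], [1.5], [2.0], [3.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = fit_logistic(X, y, lam=1e-4)
        for xi, yi in zip(X, y):
            label, _ = predict_binary(model, xi)
            assert label == yi

    def test_label_flip_negates_weights(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 3))
        y = (X @ np.array([1.0, -2.0, 0.5]) > 0).astype(int)
        m1 = fit_logistic(X, y, lam=0.5)
        m2 = fit_logistic(X, 1 - y, lam=0.5)
        np.testing.assert_allclose(m2.weights, -m1.weights, atol=1e-6)
        assert m2.intercept == pytest.approx(-m1.intercept, abs=1e-6)

    def test_matches_newton_raphson_oracle(self):
        X = np.array([
            [0.2, 1.1], [-0.5, 0.3], [1.4, -0.2],
            [-1.1, -0.8], [0.9, 0.5], [-0.3, -1.5],
        ])
        y = np.array([1, 0, 1, 0, 1, 0])
        lam = 0.5
        model = fit_logistic(X, y, lam=lam)
        w_ref, b_ref = newton_raphson_logistic(X, y.astype(float), lam)
        np.testing.assert_allclose(model.weights, w_ref, atol=1e-6)
        assert model.intercept == pytest.approx(b_ref, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            fit_logistic(np.zeros((4, 2)), np.ones(4))

    def test_decision_boundary_gives_half_probability(self):
        model = LogisticModel(
            weights=np.array([2.0, -1.0]), intercept=0.5,
            lam=0.0, positive_class="pos", negative_class="neg",
        )
        x = np.array([0.25, 1.0])  # w.x + b = 0
        label, p = predict_binary(model, x)
        assert p == pytest.approx(0.5)
        assert label == "pos"  # >= 0.5 goes to the positive class

    def test_mirror_probabilities_sum_to_one(self):
        model = LogisticModel(
            weights=np.array([1.0]), intercept=0.0,
            lam=0.0, positive_class=1, negative_class=0,
        )
        _, p1 = predict_binary(model, np.array([0.7]))
        _, p2 = predict_binary(model, np.array([-0.7]))
        assert p1 + p2 == pytest.approx(1.0)

    def test_probability_matches_sigmoid_formula(self):
        rng = np.random.default_rng(9)
        w, b = rng.normal(size=3), 0.3
        model = LogisticModel(weights=w, intercept=b, lam=0.0,
                              positive_class=1, negative_class=0)
        X = rng.normal(size=(10, 3))
        got = predict_proba(model, X)
        want = 1.0 / (1.0 + np.exp(-(X @ w + b)))
        np.testing.assert_allclose(got, want, atol=1e-12)


class TestBank:
    @staticmethod
    def _clusters(seed=10, n=30, spread=0.3):
        rng = np.random.default_rng(seed)
        centers = {"a": (0, 0), "b": (5, 0), "c": (0, 5)}
        X, labels = [], []
        for lbl, c in centers.items():
            X.append(rng.normal(size=(n, 2)) * spread + c)
            labels += [lbl] * n
        return np.vstack(X), np.array(labels)

    def test_two_label_bank_has_opposed_decisions(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(size=(20, 2)) - 2,
                       rng.normal(size=(20, 2)) + 2])
        y = np.array(["neg"] * 20 + ["pos"] * 20)
        bank = fit_bank(X, y, lam=0.5)
        d_pos = predict_proba(bank.models["pos"], X) - 0.5
        d_neg = predict_proba(bank.models["neg"], X) - 0.5
        assert np.all(np.sign(d_pos) == -np.sign(d_neg))

    def test_separated_clusters_train_perfectly(self):
        X, labels = self._clusters()
        bank = fit_bank(X, labels)
        preds = [predict_multiclass(bank, x) for x in X]
        assert np.mean(np.array(preds) == labels) == 1.0

    def test_prevalence_counts_sum_to_training_size(self):
        X, labels = self._clusters(n=17)
        bank = fit_bank(X, labels)
        assert sum(bank.training_prevalence.values()) == len(labels)

    def test_rare_class_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_bank(X, np.array(["a", "a", "a", "a", "b"]))

    def test_argmax_wins_when_strictly_highest(self):
        X, labels = self._clusters(seed=12)
        bank = fit_bank(X, labels)
        probs = {c: predict_proba(m, np.atleast_2d(X[0]))[0]
                 for c, m in bank.models.items()}
        assert predict_multiclass(bank, X[0]) == max(probs, key=probs.get)

    def test_exact_tie_broken_by_training_prevalence_then_name(self):
        flat = LogisticModel(weights=np.zeros(2), intercept=0.0, lam=0.0,
                             positive_class=None, negative_class=None)
        bank = ClassifierBank(
            models={"A": flat, "B": flat},
            training_prevalence={"A": 30, "B": 10},
        )
        assert predict_multiclass(bank, np.zeros(2)) == "A"
        bank_tied = ClassifierBank(
            models={"B": flat, "A": flat},
            training_prevalence={"A": 10, "B": 10},
        )
        assert predict_multiclass(bank_tied, np.zeros(2)) == "A"

    def test_agreement_with_brute_force_argmax_on_random_banks(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            classes = ["u", "v", "w"]
            bank = ClassifierBank(
                models={
                    c: LogisticModel(weights=rng.normal(size=4),
                                     intercept=float(rng.normal()),
                                     lam=0.0, positive_class=c,
                                     negative_class=f"not:{c}")
                    for c in classes
                },
                training_prevalence={c: int(rng.integers(5, 50))
                                     for c in classes},
            )
            x = rng.normal(size=4)
            best, best_p = None, -1.0
            for c in classes:
                p = float(predict_proba(bank.models[c], np.atleast_2d(x))[0])
                if p > best_p:
                    best, best_p = c, p
            assert predict_multiclass(bank, x) == best

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            predict_multiclass(ClassifierBank({}, {}), np.zeros(2))


class TestBundleRoundTrip:
    def test_save_and_load_reproduce_predictions(self, tmp_path):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(40, 6))
        labels = np.where(X[:, 0] > 0, "pos", "neg")
        proj = fit_projection(X)
        bank = fit_bank(project(proj, X), labels)
        path = tmp_path / "bundle.json"
        save_bundle(path, proj, bank)
        proj2, bank2 = load_bundle(path)
        Z = project(proj2, X)
        before = [predict_multiclass(bank, z) for z in project(proj, X)]
        after = [predict_multiclass(bank2, z) for z in Z]
        assert before == after
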