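"""Scatter-matrix LDA and PNN: hand oracles, closed forms, limits."""

import numpy as np
import pytest

from semgbench.classifiers import (
    accuracy,
    lda_fit,
    lda_predict,
    pnn_fit,
    pnn_predict,
    predicted_labels,
    scatter_matrices,
)


TOY_X = np.array([[0.0], [2.0], [4.0], [6.0]])
TOY_Y = np.array(["c0", "c0", "c1", "c1"])


class TestLDA:
    def test_toy_scatter_matrices_by_hand(self):
        """classes {0,2} and {4,6}: Sw = 4, Sb = 16 (means 1 and 5, mu=3)."""
        Sw, Sb, means, mu = scatter_matrices(TOY_X, TOY_Y, ["c0", "c1"])
        assert Sw[0, 0] == pytest.approx(4.0)
        assert Sb[0, 0] == pytest.approx(16.0)
        np.testing.assert_allclose(means.ravel(), [1.0, 5.0])
        assert mu[0] == pytest.approx(3.0)

    def test_toy_projected_means_up_to_scale(self):
        model = lda_fit(TOY_X, TOY_Y)
        m = model.class_means_projected.ravel()
        # 1-D projection is the identity up to a positive scale: the
        # projected means stay in ratio 1:5
        assert m[1] / m[0] == pytest.approx(5.0, rel=1e-9)

    def test_toy_predictions_and_tie_rule(self):
        model = lda_fit(TOY_X, TOY_Y)
        labels = predicted_labels(lda_predict(model, [[2.9], [1.0], [5.0], [3.0]]))
        # 2.9 is nearer mean 1 than mean 5; exact midpoint 3.0 breaks to
        # the first class in label order
        assert labels.tolist() == ["c0", "c0", "c1", "c0"]

    def test_identical_classes_have_zero_between_scatter(self):
        X = np.vstack([TOY_X[:2], TOY_X[:2]])
        y = np.array(["c0", "c0", "c1", "c1"])
        model = lda_fit(X, y)
        assert np.allclose(model.Sb, 0.0)
        assert np.all(model.eigenvalues < 1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            lda_fit(TOY_X, ["c0"] * 4)
        with pytest.raises(ValueError, match="fewer than two"):
            lda_fit(TOY_X, ["c0", "c0", "c0", "c1"])
        with pytest.raises(ValueError, match="finite"):
            lda_fit(np.array([[0.0], [np.nan], [1.0], [2.0]]), TOY_Y)

    def test_bayes_consistency_on_separated_gaussians(self, gaussian_task):
        X_train, y_train, X_test, y_test = gaussian_task
        model = lda_fit(X_train, y_train)
        assert accuracy(lda_predict(model, X_test), y_test) >= 0.99

    def test_two_class_direction_matches_fisher_closed_form(self):
        rng = np.random.default_rng(3)
        d = 16
        A = rng.normal(size=(d, d))
        cov = A @ A.T / d + np.eye(d)
        mu1, mu2 = rng.normal(size=d), rng.normal(size=d)
        X = np.vstack(
            [rng.multivariate_normal(mu1, cov, 300), rng.multivariate_normal(mu2, cov, 300)]
        )
        y = np.array(["a"] * 300 + ["b"] * 300)
        model = lda_fit(X, y)
        m1, m2 = X[:300].mean(axis=0), X[300:].mean(axis=0)
        fisher = np.linalg.solve(
            model.Sw + model.regularization * np.eye(d), m1 - m2
        )
        w = model.W[:, 0]
        cos = abs(fisher @ w) / (np.linalg.norm(fisher) * np.linalg.norm(w))
        assert cos > 0.999

    def test_agrees_with_reference_implementation(self, gaussian_task):
        """Independent cross-check against scikit-learn's eigen-solver LDA."""
        sklearn_da = pytest.importorskip("sklearn.discriminant_analysis")
        X_train, y_train, X_test, y_test = gaussian_task
        ref = sklearn_da.LinearDiscriminantAnalysis(solver="eigen").fit(
            X_train, y_train
        )
        ours = lda_fit(X_train, y_train)
        ref_labels = ref.predict(X_test)
        our_labels = predicted_labels(lda_predict(ours, X_test))
        assert np.mean(ref_labels == our_labels) >= 0.995

    def test_training_row_permutation_invariance(self, gaussian_task):
        X_train, y_train, X_test, _ = gaussian_task
        perm = np.random.default_rng(9).permutation(len(X_train))
        a = predicted_labels(lda_predict(lda_fit(X_train, y_train), X_test[:50]))
        b = predicted_labels(
            lda_predict(lda_fit(X_train[perm], y_train[perm]), X_test[:50])
        )
        assert np.array_equal(a, b)


class TestPNN:
    def test_radial_layer_stores_training_set(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        y = np.array(["a", "b"] * 5)
        model = pnn_fit(X, y, sigma=0.5)
        assert model.exemplars.shape[0] == 10  # Q radial neurons
        np.testing.assert_array_equal(model.exemplars, X)

    def test_indicator_matrix_one_hot(self):
        model = pnn_fit(np.zeros((3, 2)), ["c1", "c1", "c2"], sigma=1.0)
        assert model.T.shape == (3, 2)
        np.testing.assert_array_equal(model.T.sum(axis=1), [1, 1, 1])

    def test_polarization_factor_convention(self):
        model = pnn_fit(np.zeros((2, 1)), ["a", "b"], sigma=0.8326)
        assert model.b == pytest.approx(1.0)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            pnn_fit(np.zeros((2, 1)), ["a", "b"], sigma=0.0)

    def test_training_exemplar_recovers_own_label(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 4))
        y = np.array(["a", "b", "c", "d"] * 5)
        model = pnn_fit(X, y, sigma=0.01)
        assert np.array_equal(predicted_labels(pnn_predict(model, X)), y)

    def test_two_cluster_example(self):
        model = pnn_fit(
            np.array([[0.0, 0.0], [10.0, 10.0]]), ["c1", "c2"], sigma=1.0
        )
        assert predicted_labels(pnn_predict(model, [[1.0, 1.0]]))[0] == "c1"

    def test_small_sigma_limit_is_nearest_neighbour(self):
        """sigma -> 0+: PNN decisions equal 1-NN on 100 random queries."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 5))
        y = rng.choice(["a", "b", "c"], size=60)
        queries = rng.normal(size=(100, 5))
        model = pnn_fit(X, y, sigma=1e-6)
        pnn_labels = predicted_labels(pnn_predict(model, queries))
        nn_labels = y[
            np.argmin(
                np.linalg.norm(queries[:, None] - X[None], axis=-1), axis=1
            )
        ]
        assert np.array_equal(pnn_labels, nn_labels)

    def test_large_sigma_limit_is_majority_class(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        y = np.array(["maj"] * 20 + ["min"] * 10)
        model = pnn_fit(X, y, sigma=1e6)
        labels = predicted_labels(pnn_predict(model, rng.normal(size=(20, 3))))
        assert all(l == "maj" for l in labels)

    def test_training_row_permutation_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 4))
        y = rng.choice(["a", "b"], size=40)
        q = rng.normal(size=(30, 4))
        perm = rng.permutation(40)
        a = predicted_labels(pnn_predict(pnn_fit(X, y, sigma=0.3), q))
        b = predicted_labels(pnn_predict(pnn_fit(X[perm], y[perm], sigma=0.3), q))
        assert np.array_equal(a, b)

    def test_spread_controls_overfitting(self):
        """Training accuracy is non-increasing in sigma and the
        train-test gap shrinks as sigma grows (the over/under-fitting
        dial of the polarization factor)."""
        rng = np.random.default_rng(6)
        n = 150
        centers = {"a": np.zeros(4), "b": np.full(4, 1.2)}
        X_tr = np.vstack([rng.normal(centers[c], 1.0, (n, 4)) for c in "ab"])
        y_tr = np.array(["a"] * n + ["b"] * n)
        X_te = np.vstack([rng.normal(centers[c], 1.0, (n, 4)) for c in "ab"])
        y_te = y_tr.copy()
        train_accs, gaps = [], []
        for sigma in (0.05, 0.5, 5.0):
            model = pnn_fit(X_tr, y_tr, sigma=sigma)
            tr = accuracy(pnn_predict(model, X_tr), y_tr)
            te = accuracy(pnn_predict(model, X_te), y_te)
            train_accs.append(tr)
            gaps.append(tr - te)
        assert train_accs == sorted(train_accs, reverse=True)
        assert gaps == sorted(gaps, reverse=True)


def test_dimension_mismatch_rejected(gaussian_task):
    X_train, y_train, _, _ = gaussian_task
    lda = lda_fit(X_train, y_train)
    pnn = pnn_fit(X_train, y_train)
    with pytest.raises(ValueError, match="dimension"):
        lda_predict(lda, np.zeros((3, 5)))
    with pytest.raises(ValueError, match="dimension"):
        pnn_predict(pnn, np.zeros((3, 5)))
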