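"""Fisher LDA: canonical directions, posteriors, prediction, boundaries."""

import numpy as np
import pytest
import scipy.linalg

from mrsclassify import FisherLDAClassifier, compute_boundaries, fit_fisher_lda
from mrsclassify.errors import DimensionMismatch, SingularProblem
from tests.conftest import make_blob_dm, random_dm


def two_class_closed_form(X, y):
    """Oracle: w proportional to pinv(Sw) (mu2 - mu1) for two classes."""
    mu = [X[y == c].mean(axis=0) for c in (0, 1)]
    Sw = sum(
        (X[y == c] - mu[c]).T @ (X[y == c] - mu[c]) for c in (0, 1)
    )
    w = np.linalg.pinv(Sw) @ (mu[1] - mu[0])
    return w / np.linalg.norm(w)


def angle(u, v):
    """Angle between 1-D directions, sign-insensitive, accurate near 0."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    if u @ v < 0:
        v = -v
    residual = u - (u @ v) * v
    return np.arcsin(np.clip(np.linalg.norm(residual), 0.0, 1.0))


class TestFit:
    def test_two_class_matches_closed_form(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [4.0, 0.0], [5.0, 1.0]])
        y = np.array([0, 0, 1, 1])
        with pytest.warns(UserWarning):  # 2 features for 4 cases
            clf = FisherLDAClassifier().fit(X, y)
        w_oracle = two_class_closed_form(X, y)
        assert angle(clf.weights_[:, 0], w_oracle) <= 1e-8

    def test_identical_means_singular(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        y = np.array([0, 0, 1, 1])
        with pytest.raises(SingularProblem):
            FisherLDAClassifier().fit(X, y)

    def test_three_classes_two_canonical_variables(self):
        dm = make_blob_dm(n_classes=3)
        clf = fit_fisher_lda(dm)
        assert clf.weights_.shape[1] == 2
        assert clf.means_.shape == (3, 2)

    def test_four_classes_three_variables(self):
        dm = make_blob_dm(n_classes=4, n_per_class=8)
        clf = fit_fisher_lda(dm)
        assert clf.weights_.shape[1] == 3

    def test_generalized_eig_oracle(self):
        # oracle: scipy's symmetric-definite generalized eigensolver
        for seed in range(5):
            dm = random_dm(n=40, p=5, seed=seed)
            clf = fit_fisher_lda(dm)
            X, y = dm.X, dm.y
            mu_all = X.mean(axis=0)
            Sw = np.zeros((5, 5))
            Sb = np.zeros((5, 5))
            for c in np.unique(y):
                Xc = X[y == c]
                mu = Xc.mean(axis=0)
                Sw += (Xc - mu).T @ (Xc - mu)
                d = (mu - mu_all)[:, None]
                Sb += len(Xc) * d @ d.T
            evals, evecs = scipy.linalg.eigh(Sb, Sw)
            order = np.argsort(evals)[::-1]
            for j in range(clf.weights_.shape[1]):
                assert angle(clf.weights_[:, j], evecs[:, order[j]]) <= 1e-8

    def test_priors_frequencies_and_uniform(self):
        dm = make_blob_dm(n_per_class=10, n_classes=2)
        dm.y[:5] = 1  # unbalance: 5 vs 15
        freq = fit_fisher_lda(dm)
        np.testing.assert_allclose(freq.priors_, [0.25, 0.75])
        unif = FisherLDAClassifier(priors="uniform").fit(dm.X, dm.y)
        np.testing.assert_allclose(unif.priors_, [0.5, 0.5])

    def test_singular_sw_warns_and_fits(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 20))  # far more features than cases
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.warns(UserWarning, match="pseudo-inverse"):
            clf = FisherLDAClassifier().fit(X, y)
        assert clf.weights_.shape == (20, 1)
        assert np.isfinite(clf.weights_).all() and clf.sigma_ > 0
        np.testing.assert_allclose(
            clf.predict_proba(X).sum(axis=1), 1.0, atol=1e-12
        )


class TestProjection:
    def test_zero_row_projects_to_origin(self):
        dm = make_blob_dm()
        clf = fit_fisher_lda(dm)
        np.testing.assert_array_equal(
            clf.transform(np.zeros((1, dm.n_features))), 0.0
        )

    def test_linearity(self):
        dm = make_blob_dm(seed=3)
        clf = fit_fisher_lda(dm)
        x = dm.X[:1]
        np.testing.assert_allclose(
            clf.transform(2 * x), 2 * clf.transform(x), rtol=1e-12
        )

    def test_dimension_mismatch(self):
        clf = fit_fisher_lda(make_blob_dm())
        with pytest.raises(DimensionMismatch):
            clf.transform(np.zeros((2, 99)))


class TestPosteriors:
    def test_rows_sum_to_one(self):
        dm = make_blob_dm(n_classes=4, n_per_class=8, seed=1)
        clf = fit_fisher_lda(dm)
        post = clf.predict_proba(dm.X)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_midpoint_equal_posteriors(self):
        dm = make_blob_dm(n_classes=2, seed=2)
        clf = FisherLDAClassifier(priors="uniform").fit(dm.X, dm.y)
        mid = (clf.means_[0] + clf.means_[1]) / 2
        post = clf.posterior_from_projection(mid)
        np.testing.assert_allclose(post[0], [0.5, 0.5], atol=1e-12)

    def test_far_tail_saturates(self):
        dm = make_blob_dm(n_classes=2, separation=25.0, seed=3)
        clf = fit_fisher_lda(dm)
        post = clf.posterior_from_projection(clf.means_[0])
        assert post[0, 0] >= 1 - 1e-20

    def test_predict_is_argmax_posterior(self):
        dm = make_blob_dm(n_classes=3, seed=4)
        clf = fit_fisher_lda(dm)
        post = clf.predict_proba(dm.X)
        np.testing.assert_array_equal(
            clf.predict(dm.X), clf.classes_[np.argmax(post, axis=1)]
        )

    def test_training_points_recovered(self):
        dm = make_blob_dm(n_classes=3, separation=10.0, seed=5)
        clf = fit_fisher_lda(dm)
        assert np.mean(clf.predict(dm.X) == dm.y) == 1.0

    def test_tie_breaks_to_lower_index(self):
        dm = make_blob_dm(n_classes=2, seed=6)
        clf = FisherLDAClassifier(priors="uniform").fit(dm.X, dm.y)
        # exactly between the two projected means: posterior tie
        mid = (clf.means_[0] + clf.means_[1]) / 2
        post = clf.posterior_from_projection(mid)
        assert post[0, 0] == pytest.approx(post[0, 1], abs=1e-12)
        assert int(np.argmax(post[0])) == 0


class TestBoundaries:
    def test_two_class_symmetric_threshold(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(-5, 1, (20, 1)), rng.normal(5, 1, (20, 1))])
        y = np.array([0] * 20 + [1] * 20)
        clf = FisherLDAClassifier(priors="uniform").fit(X, y)
        b = compute_boundaries(clf)
        mid = (clf.means_[0, 0] + clf.means_[1, 0]) / 2
        assert b.intersection_point[0] == pytest.approx(mid, abs=1e-9)

    def test_equilateral_intersection_at_centroid(self):
        # class means at the vertices of an equilateral triangle with
        # equal priors: the three equal-posterior lines meet at the
        # centroid, where all posteriors are exactly 1/3
        means = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        clf = FisherLDAClassifier()
        clf.classes_ = np.arange(3)
        clf.means_ = means
        clf.sigma_ = 0.4
        clf.priors_ = np.full(3, 1 / 3)
        clf.weights_ = np.eye(2)
        clf.n_features_in_ = 2
        b = compute_boundaries(clf)
        centroid = means.mean(axis=0)
        np.testing.assert_allclose(b.intersection_point, centroid, atol=1e-9)
        post = clf.posterior_from_projection(b.intersection_point)
        np.testing.assert_allclose(post[0], 1 / 3, atol=1e-9)

    def test_boundary_points_are_posterior_ties(self):
        dm = make_blob_dm(n_classes=3, seed=7)
        clf = fit_fisher_lda(dm)
        b = compute_boundaries(clf, Z_train=clf.transform(dm.X))
        for (i, j), pt in zip(b.pairs, b.boundary_points):
            post = clf.posterior_from_projection(pt)[0]
            assert abs(post[i] - post[j]) <= 1e-9

    def test_four_classes_no_boundaries(self):
        dm = make_blob_dm(n_classes=4, n_per_class=8)
        clf = fit_fisher_lda(dm)
        assert compute_boundaries(clf) is None

    def test_collinear_means_parallel_lines(self):
        clf = FisherLDAClassifier()
        clf.classes_ = np.arange(3)
        clf.means_ = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        clf.sigma_ = 0.5
        clf.priors_ = np.full(3, 1 / 3)
        clf.weights_ = np.eye(2)
        clf.n_features_in_ = 2
        with pytest.warns(UserWarning, match="collinear"):
            b = compute_boundaries(clf)
        assert b.intersection_point is None
        assert len(b.boundary_points) == 3
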