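"""Fisher linear discriminant analysis with spherical-Gaussian posteriors.

For C classes (2 <= C <= 4) the canonical variates are the top C-1
eigenvectors of ``pinv(Sw) @ Sb``, where Sw is the pooled within-class
scatter and Sb the between-class scatter of the class means. Cases are
projected as ``Z = X @ W`` (no centring) into the (C-1)-dimensional
canonical space.

Fisher's criterion itself carries no probability model, so class
membership probabilities are obtained by placing a spherical Gaussian
on each projected class mean, with one standard deviation common to
all classes — the pooled root-mean-square distance of projected
training cases from their class mean, over all cases and canonical
dimensions. Bayes' theorem over these C Gaussians (class priors default
to training frequencies) yields the posterior of each case for each
class; prediction is the maximum-posterior class, ties broken toward
the lowest class index.

In one or two canonical dimensions (C = 2 or 3) the equal-posterior
loci between class pairs are points/straight lines (equal spherical
covariances), and are computed in closed form for display and export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .errors import DimensionMismatch, SingularProblem
from .model import DesignMatrix


@dataclass
class Boundaries:
    """Class-boundary geometry in the canonical projection space.

    ``intersection_point`` is the common point of the pairwise
    equal-posterior lines (C=3) or None; ``boundary_points`` holds one
    outer endpoint per class pair, so each boundary can be drawn as a
    segment from the intersection outward. ``pairs`` names the class
    index pair of each boundary point.
    """

    intersection_point: np.ndarray | None
    boundary_points: list[np.ndarray]
    pairs: list[tuple[int, int]]


class FisherLDAClassifier(ClassifierMixin, BaseEstimator):
    """Fisher LDA for 2-4 classes with Gaussian-posterior probabilities.

    Parameters
    ----------
    priors : {'frequencies', 'uniform'} or array of shape (C,)
        Class priors used in the Bayes posterior. ``'frequencies'``
        (default) uses training class frequencies; ``'uniform'`` is
        useful when super-classes have very unequal sizes.
    min_class_size : int
        Minimum training cases per class (default 2; resampling
        internals relax it to 1).

    Attributes
    ----------
    classes_ : array of class labels
    weights_ : (n_features, C-1) canonical-variate matrix, columns in
        descending discriminant-eigenvalue order
    eigenvalues_ : (C-1,) discriminant eigenvalues
    means_ : (C, C-1) projected class means
    sigma_ : float, common spherical standard deviation
    priors_ : (C,) class priors
    """

    def __init__(self, priors="frequencies", min_class_size: int = 2):
        self.priors = priors
        self.min_class_size = min_class_size

    # -- fitting ------------------------------------------------------

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        C = len(self.classes_)
        if not 2 <= C <= 4:
            raise ValueError(f"Fisher LDA supports 2-4 classes, got {C}")
        counts = np.bincount(y_idx, minlength=C)
        if counts.min() < self.min_class_size:
            small = self.classes_[counts < self.min_class_size]
            raise ValueError(
                f"classes {small!r} have fewer than {self.min_class_size} cases"
            )
        n, p = X.shape
        if p >= n - C:
            warnings.warn(
                f"{p} features for {n} cases in {C} classes: the within-class "
                "scatter is singular; using its pseudo-inverse",
                stacklevel=2,
            )

        grand_mean = X.mean(axis=0)
        Sw = np.zeros((p, p))
        Sb = np.zeros((p, p))
        class_means = np.empty((C, p))
        for c in range(C):
            Xc = X[y_idx == c]
            mu = Xc.mean(axis=0)
            class_means[c] = mu
            d = Xc - mu
            Sw += d.T @ d
            dm = (mu - grand_mean)[:, None]
            Sb += counts[c] * (dm @ dm.T)
        if np.allclose(Sb, 0.0):
            raise SingularProblem("all class means coincide; nothing to separate")

        d = C - 1
        M = np.linalg.pinv(Sw) @ Sb
        evals, evecs = scipy.linalg.eig(M)
        evals = evals.real
        evecs = evecs.real
        order = np.argsort(evals)[::-1][:d]
        W = evecs[:, order]
        # sign convention: largest-|loading| positive per canonical variate
        for j in range(W.shape[1]):
            i = np.argmax(np.abs(W[:, j]))
            if W[i, j] < 0:
                W[:, j] = -W[:, j]
        self.weights_ = W
        self.eigenvalues_ = evals[order]

        Z = X @ W
        self.means_ = class_means @ W
        sq = 0.0
        for c in range(C):
            sq += float(((Z[y_idx == c] - self.means_[c]) ** 2).sum())
        sigma = np.sqrt(sq / (n * d))
        # degenerate (perfectly projected) data: keep the Gaussians proper
        self.sigma_ = sigma if sigma > 0 else np.finfo(float).eps ** 0.5

        if isinstance(self.priors, str):
            if self.priors == "frequencies":
                self.priors_ = counts / n
            elif self.priors == "uniform":
                self.priors_ = np.full(C, 1.0 / C)
            else:
                raise ValueError(f"unknown priors {self.priors!r}")
        else:
            pr = np.asarray(self.priors, dtype=float)
            if pr.shape != (C,) or pr.min() < 0 or not np.isclose(pr.sum(), 1.0):
                raise ValueError("priors must be C non-negative values summing to 1")
            self.priors_ = pr
        return self

    # -- projection & posteriors --------------------------------------

    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.weights_.shape[0]:
            raise DimensionMismatch(
                f"model has {self.weights_.shape[0]} features, input has {X.shape[1]}"
            )
        return X

    def transform(self, X) -> np.ndarray:
        """Project cases into canonical-variate space: ``X @ W``."""
        return self._check_X(X) @ self.weights_

    def posterior_from_projection(self, Z) -> np.ndarray:
        """Spherical-Gaussian Bayes posteriors from canonical coordinates."""
        check_is_fitted(self)
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        d2 = ((Z[:, None, :] - self.means_[None, :, :]) ** 2).sum(axis=2)
        logp = np.log(self.priors_)[None, :] - d2 / (2.0 * self.sigma_**2)
        return np.exp(logp - logsumexp(logp, axis=1, keepdims=True))

    def predict_proba(self, X) -> np.ndarray:
        """Class-membership probabilities of each case (rows sum to 1)."""
        return self.posterior_from_projection(self.transform(X))

    def predict(self, X):
        """Maximum-posterior class; ties go to the lowest class index."""
        post = self.predict_proba(X)
        return self.classes_[np.argmax(post, axis=1)]


def fit_fisher_lda(dm: DesignMatrix, priors="frequencies") -> FisherLDAClassifier:
    """Fit a Fisher LDA classifier on a design matrix."""
    return FisherLDAClassifier(priors=priors).fit(dm.X, dm.y)


def project(model: FisherLDAClassifier, X) -> np.ndarray:
    """Canonical-variate coordinates of cases (``X @ W``)."""
    return model.transform(X)


def posterior_probabilities(model: FisherLDAClassifier, Z) -> np.ndarray:
    """Posteriors from canonical coordinates ``Z``."""
    return model.posterior_from_projection(Z)


def predict(model: FisherLDAClassifier, X):
    return model.predict(X)


def _pair_line(model: FisherLDAClassifier, a: int, b: int):
    """Equal-posterior locus of classes a, b: points z with n.z = c."""
    mu_a, mu_b = model.means_[a], model.means_[b]
    normal = mu_a - mu_b
    const = float(
        (mu_a @ mu_a - mu_b @ mu_b) / 2.0
        + model.sigma_**2 * np.log(model.priors_[b] / model.priors_[a])
    )
    return normal, const


def compute_boundaries(
    model: FisherLDAClassifier, bbox_scale: float = 1.2, Z_train=None
) -> Boundaries | None:
    """Closed-form class boundaries in canonical space (C = 2 or 3).

    C=2 (one dimension): the single threshold where both posteriors are
    equal — the midpoint of the projected means shifted by
    ``sigma^2 * ln(prior_b/prior_a) / (mu_b - mu_a)``.

    C=3 (two dimensions): the three pairwise equal-posterior lines meet
    in one point (solved from two of the pairwise equalities); each
    boundary is represented by an outer endpoint on its locus, on the
    side away from the third class, clipped at ``bbox_scale`` times the
    extent of ``Z_train`` (training projections; defaults to the class
    means) so the segment from the intersection outward spans the data.

    C=4 projects into three dimensions: no boundaries are computed and
    None is returned.
    """
    check_is_fitted(model)
    C = len(model.classes_)
    if C not in (2, 3):
        return None
    if C == 2:
        n_ab, c_ab = _pair_line(model, 0, 1)
        z = c_ab / n_ab[0]
        return Boundaries(
            intersection_point=np.array([z]),
            boundary_points=[np.array([z])],
            pairs=[(0, 1)],
        )

    # C == 3, d == 2
    pairs = [(0, 1), (0, 2), (1, 2)]
    lines = {pq: _pair_line(model, *pq) for pq in pairs}
    A = np.vstack([lines[(0, 1)][0], lines[(0, 2)][0]])
    b = np.array([lines[(0, 1)][1], lines[(0, 2)][1]])
    if abs(np.linalg.det(A)) < 1e-12 * max(np.abs(A).max() ** 2, 1.0):
        warnings.warn(
            "collinear class means: boundary lines are parallel, no "
            "intersection point",
            stacklevel=2,
        )
        inter = None
    else:
        inter = np.linalg.solve(A, b)

    ref = np.asarray(Z_train, dtype=float) if Z_train is not None else model.means_
    center = ref.mean(axis=0)
    half_extent = bbox_scale * max(
        float(np.abs(ref - center).max()), float(model.sigma_)
    )

    boundary_points: list[np.ndarray] = []
    for (a_i, b_i) in pairs:
        normal, const = lines[(a_i, b_i)]
        direction = np.array([-normal[1], normal[0]])
        direction = direction / np.linalg.norm(direction)
        if inter is None:
            # parallel lines: report the foot of the centre on each locus
            base = center + (const - normal @ center) / (normal @ normal) * normal
            boundary_points.append(base + half_extent * direction)
            continue
        third = [k for k in range(3) if k not in (a_i, b_i)][0]
        away = inter - model.means_[third]
        if np.dot(direction, away) < 0:
            direction = -direction
        boundary_points.append(inter + 2.0 * half_extent * direction)
    return Boundaries(
        intersection_point=inter, boundary_points=boundary_points, pairs=pairs
    )
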