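"""PCA feature extraction with variance-coverage retention.

Principal components are the eigenvectors of the covariance matrix of
the mean-centred design matrix, ranked by eigenvalue. The number of
retained components is the smallest count whose cumulative variance
fraction reaches ``variance_target`` (default 0.95). Besides the usual
score transform, a back-transform filter is provided: projecting onto
the retained components and returning to the original feature space
discards the low-variance directions, acting as an attribute-noise
filter on the spectra.

Covariance (not correlation) of the centred data is used: spectral
channels share units, so standardisation is optional (``standardize``).
Component signs are fixed so each component's largest-magnitude loading
is positive, keeping serialised models reproducible.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .errors import DegenerateData, DimensionMismatch
from .model import DesignMatrix


class PCAFilter(TransformerMixin, BaseEstimator):
    """Principal-component extraction and back-transform filtering.

    Parameters
    ----------
    variance_target : float in (0, 1]
        Retain the minimal number of components whose eigenvalue
        fractions sum to at least this value. Default 0.95.
    standardize : bool
        Divide channels by their sample sd before the decomposition.

    Attributes
    ----------
    mean_ : (n_features,) array
    components_ : (n_features, n_features) orthonormal column matrix
    eigenvalues_ : (n_features,) array, descending
    n_retained_ : int
    """

    def __init__(self, variance_target: float = 0.95, standardize: bool = False):
        self.variance_target = variance_target
        self.standardize = standardize

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_samples=2)
        if not 0.0 < self.variance_target <= 1.0:
            raise ValueError("variance_target must be in (0, 1]")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        if np.allclose(Xc, 0.0):
            raise DegenerateData("all rows identical; no principal directions")
        if self.standardize:
            self.scale_ = X.std(axis=0, ddof=1)
            self.scale_[self.scale_ == 0.0] = 1.0
            Xc = Xc / self.scale_
        else:
            self.scale_ = None
        cov = (Xc.T @ Xc) / (X.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]  # Ranker: descending eigenvalue
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        # sign convention: largest-|loading| positive per component
        for j in range(evecs.shape[1]):
            i = np.argmax(np.abs(evecs[:, j]))
            if evecs[i, j] < 0:
                evecs[:, j] = -evecs[:, j]
        frac = np.cumsum(evals) / evals.sum()
        self.n_retained_ = int(np.searchsorted(frac, self.variance_target - 1e-12) + 1)
        self.n_retained_ = min(self.n_retained_, len(evals))
        self.eigenvalues_ = evals
        self.components_ = evecs
        return self

    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.components_.shape[0]:
            raise DimensionMismatch(
                f"expected {self.components_.shape[0]} features, got "
                f"{X.shape[1] if X.ndim == 2 else 'non-2D input'}"
            )
        return X

    def transform(self, X, n_components: int | None = None) -> np.ndarray:
        """Scores on the retained (or first ``n_components``) components."""
        X = self._check_X(X)
        k = self.n_retained_ if n_components is None else n_components
        Xc = X - self.mean_
        if self.scale_ is not None:
            Xc = Xc / self.scale_
        return Xc @ self.components_[:, :k]

    def inverse_transform(self, scores) -> np.ndarray:
        """Map component scores back into the original feature space."""
        check_is_fitted(self)
        scores = np.asarray(scores, dtype=float)
        k = scores.shape[1]
        Xc = scores @ self.components_[:, :k].T
        if self.scale_ is not None:
            Xc = Xc * self.scale_
        return Xc + self.mean_

    def filter(self, X, n_components: int | None = None) -> np.ndarray:
        """Noise-filter: project onto retained components and back."""
        k = self.n_retained_ if n_components is None else n_components
        return self.inverse_transform(self.transform(X, n_components=k))


def fit_pca(dm: DesignMatrix, variance_target: float = 0.95) -> PCAFilter:
    """Fit the PCA extractor on a design matrix."""
    return PCAFilter(variance_target=variance_target).fit(dm.X)
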