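"""Correlation-based feature subset (CFS) selection with greedy stepwise search.

CFS scores a candidate subset S of k features by

    merit(S) = k * rcf / sqrt(k + k*(k-1) * rff)

where ``rcf`` is the mean feature-class correlation over S and ``rff``
the mean absolute pairwise feature-feature correlation. Subsets whose
features track the class while being mutually non-redundant score
highest: duplicating a feature raises the denominator without raising
the numerator.

Class labels are nominal while spectral intensities are continuous, so
the feature-class correlation of a column x is estimated as the
prior-weighted mean over classes c of |Pearson(x, 1{y=c})| — a
deterministic estimator symmetric under label permutation. Constant
columns get correlation 0 (with a warning), so flat channels are simply
never selected.

The search is hill climbing: forward starts from the empty set and adds
the merit-maximising feature; backward starts from the full set and
drops the feature whose removal most improves merit. Either direction
stops as soon as no move strictly increases merit. Ties break on the
lowest feature index, making the search fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .errors import EmptySubset
from .model import DesignMatrix


@dataclass
class FeatureSelectionResult:
    """Outcome of a feature selection / extraction run.

    ``selected`` lists feature labels in the order the search accepted
    them (forward) or kept them (backward/pca); ``merit_trace`` records
    the merit after each accepted move.
    """

    method: str
    selected: list = field(default_factory=list)
    selected_indices: list[int] = field(default_factory=list)
    merit_trace: list[float] = field(default_factory=list)


def cfs_merit(subset, rcf: np.ndarray, rff: np.ndarray) -> float:
    """CFS merit of a feature subset.

    Parameters
    ----------
    subset : sequence of int
        Feature indices; must be non-empty.
    rcf : (n_features,) array
        Feature-class correlations.
    rff : (n_features, n_features) array
        Pairwise feature-feature correlations (absolute values are
        taken here, the diagonal is ignored).
    """
    idx = np.sort(np.fromiter(subset, dtype=int))  # order-canonical
    k = idx.size
    if k == 0:
        raise EmptySubset("CFS merit of the empty subset is undefined")
    mean_rcf = float(np.mean(np.abs(rcf[idx])))
    if k == 1:
        return mean_rcf
    sub = np.abs(rff[np.ix_(idx, idx)])
    mean_rff = float((sub.sum() - np.trace(sub)) / (k * (k - 1)))
    return k * mean_rcf / np.sqrt(k + k * (k - 1) * mean_rff)


def feature_class_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Prior-weighted |Pearson| correlation of a feature with the class.

    For each class c the feature column is correlated with the 0/1
    indicator of c; the absolute correlations are averaged with the
    class priors as weights. Constant features return 0 with a warning
    rather than raising, so they fall out of the search naturally.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    labels, counts = np.unique(y, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least two distinct class labels")
    sx = x.std()
    if sx == 0.0:
        warnings.warn("constant feature: class correlation set to 0", stacklevel=2)
        return 0.0
    priors = counts / counts.sum()
    total = 0.0
    xc = x - x.mean()
    for lab, w in zip(labels, priors):
        ind = (y == lab).astype(float)
        si = ind.std()
        if si == 0.0:  # cannot happen with >=2 labels, defensive
            continue
        r = float(np.dot(xc, ind - ind.mean()) / (len(x) * sx * si))
        total += w * abs(r)
    return total


def _correlation_tables(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Precompute rcf vector and rff matrix for a design matrix."""
    n, p = X.shape
    rcf = np.empty(p)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(p):
            rcf[j] = feature_class_correlation(X[:, j], y)
    sd = X.std(axis=0)
    const = sd == 0.0
    Xs = X - X.mean(axis=0)
    safe_sd = np.where(const, 1.0, sd)
    Z = Xs / safe_sd
    rff = (Z.T @ Z) / n
    rff[const, :] = 0.0
    rff[:, const] = 0.0
    np.fill_diagonal(rff, 1.0)
    return rcf, rff


class CFSSelector(SelectorMixin, BaseEstimator):
    """Greedy stepwise feature selection scored by CFS merit.

    Parameters
    ----------
    direction : {'forward', 'backward'}
        Forward starts empty and adds features; backward starts full
        and removes them. Both stop at the first move that fails to
        strictly increase merit.

    Attributes
    ----------
    support_ : bool array of shape (n_features,)
        Mask of selected features.
    selected_idx_ : list of int
        Selected feature indices in acceptance order (forward) or
        ascending order (backward).
    merit_trace_ : list of float
        Merit after each accepted move.
    merit_ : float
        Final subset merit.
    """

    def __init__(self, direction: str = "forward"):
        self.direction = direction

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_features=2)
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"unknown direction {self.direction!r}")
        rcf, rff = _correlation_tables(X, y)
        p = X.shape[1]
        if self.direction == "forward":
            selected, trace = self._forward(rcf, rff, p)
        else:
            selected, trace = self._backward(rcf, rff, p)
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[selected] = True
        self.selected_idx_ = selected
        self.merit_trace_ = trace
        self.merit_ = trace[-1]
        return self

    @staticmethod
    def _forward(rcf, rff, p):
        selected: list[int] = []
        trace: list[float] = []
        current = -np.inf
        remaining = list(range(p))
        while remaining:
            best_j, best_m = None, current
            for j in remaining:
                m = cfs_merit(selected + [j], rcf, rff)
                if m > best_m:  # strict improvement; ties keep lowest index
                    best_j, best_m = j, m
            if best_j is None:
                break
            selected.append(best_j)
            remaining.remove(best_j)
            trace.append(best_m)
            current = best_m
        return selected, trace

    @staticmethod
    def _backward(rcf, rff, p):
        selected = list(range(p))
        current = cfs_merit(selected, rcf, rff)
        trace = [current]
        while len(selected) > 1:
            best_j, best_m = None, current
            for j in selected:
                m = cfs_merit([i for i in selected if i != j], rcf, rff)
                if m > best_m:
                    best_j, best_m = j, m
            if best_j is None:
                break
            selected.remove(best_j)
            trace.append(best_m)
            current = best_m
        return selected, trace

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_

    def _more_tags(self):  # pragma: no cover - sklearn plumbing
        return {"requires_y": True}


def greedy_stepwise_fs(
    dm: DesignMatrix, direction: str = "forward"
) -> FeatureSelectionResult:
    """Run greedy stepwise CFS selection on a design matrix."""
    sel = CFSSelector(direction=direction).fit(dm.X, dm.y)
    return FeatureSelectionResult(
        method=f"sequential-{direction}",
        selected=[dm.feature_labels[i] for i in sel.selected_idx_],
        selected_indices=list(sel.selected_idx_),
        merit_trace=list(sel.merit_trace_),
    )
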