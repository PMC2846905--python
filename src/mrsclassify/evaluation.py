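"""Classifier evaluation: confusion matrix, K-fold CV, leave-one-out,
bootstrap and dichotomised ROC/AUC.

All resampling schemes re-fit only the Fisher LDA classifier on the
already-fixed feature columns of the design matrix; the feature
selection stage is never re-run inside a resample, so shuffling columns
outside the selected set cannot change any result.

Accuracies are reported in percent with sample (n-1) standard
deviations. Every stochastic scheme takes an explicit seed and is
reproducible bit-for-bit from (method, seed, N/K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import OneClassOnly, TooFewCases, UnknownLabel
from .lda import FisherLDAClassifier
from .model import DesignMatrix


@dataclass
class ConfusionMatrix:
    """Counts with rows = predicted class, columns = actual class."""

    counts: np.ndarray
    class_names: list[str]

    @property
    def accuracy(self) -> float:
        """Overall accuracy in percent: trace over total."""
        total = self.counts.sum()
        return 100.0 * np.trace(self.counts) / total if total else 0.0

    def per_class_recall(self) -> np.ndarray:
        """Fraction of each actual class predicted correctly (percent)."""
        col = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rec = np.where(col > 0, 100.0 * np.diag(self.counts) / col, np.nan)
        return rec


@dataclass
class ResamplingResult:
    """Summary of one resampling evaluation run."""

    method: str
    per_replicate_accuracy: np.ndarray
    overall_mean: float
    overall_sd: float
    per_class_mean: np.ndarray
    per_class_sd: np.ndarray
    class_names: list[str]
    n_replicates: int
    seed: int | None = None
    n_redrawn: int = 0


@dataclass
class RocResult:
    """Per-class one-vs-rest ROC curves and AUCs."""

    per_class: list[tuple[str, np.ndarray, np.ndarray, float]] = field(
        default_factory=list
    )

    @property
    def aucs(self) -> dict[str, float]:
        return {name: auc for name, _, _, auc in self.per_class}


def confusion_matrix(actual, predicted, class_names: list[str]) -> ConfusionMatrix:
    """Count predictions: ``counts[p, a]`` = cases of actual class a
    predicted as p.
    """
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    C = len(class_names)
    index = {name: i for i, name in enumerate(class_names)}

    def to_idx(v):
        if isinstance(v, (int, np.integer)):
            if not 0 <= v < C:
                raise UnknownLabel(f"class index {v} outside 0..{C - 1}")
            return int(v)
        if v not in index:
            raise UnknownLabel(f"label {v!r} not among {class_names}")
        return index[v]

    counts = np.zeros((C, C), dtype=int)
    for a, p in zip(actual, predicted):
        counts[to_idx(p), to_idx(a)] += 1
    return ConfusionMatrix(counts=counts, class_names=list(class_names))


def _fit_eval(dm: DesignMatrix, train_idx, test_idx, priors) -> np.ndarray:
    """Refit LDA on a training split; return predictions on the test split."""
    clf = FisherLDAClassifier(priors=priors, min_class_size=1)
    clf.fit(dm.X[train_idx], dm.y[train_idx])
    return clf.predict(dm.X[test_idx])


def _summarise(
    method: str,
    acc: list[float],
    per_class: list[np.ndarray],
    dm: DesignMatrix,
    seed: int | None,
    n_redrawn: int = 0,
) -> ResamplingResult:
    acc = np.asarray(acc)
    pc = np.vstack(per_class)  # replicates x classes, NaN where class absent
    sd = float(acc.std(ddof=1)) if len(acc) > 1 else 0.0
    with np.errstate(invalid="ignore"):
        pc_mean = np.nanmean(pc, axis=0)
        pc_sd = np.array(
            [
                col[~np.isnan(col)].std(ddof=1)
                if (~np.isnan(col)).sum() > 1
                else 0.0
                for col in pc.T
            ]
        )
    return ResamplingResult(
        method=method,
        per_replicate_accuracy=acc,
        overall_mean=float(acc.mean()),
        overall_sd=sd,
        per_class_mean=pc_mean,
        per_class_sd=pc_sd,
        class_names=list(dm.class_names),
        n_replicates=len(acc),
        seed=seed,
        n_redrawn=n_redrawn,
    )


def _replicate_scores(dm, test_idx, pred) -> tuple[float, np.ndarray]:
    actual = dm.y[test_idx]
    acc = 100.0 * float(np.mean(pred == actual))
    pc = np.full(dm.n_classes, np.nan)
    for c in range(dm.n_classes):
        mask = actual == c
        if mask.any():
            pc[c] = 100.0 * float(np.mean(pred[mask] == c))
    return acc, pc


def _stratified_folds(y: np.ndarray, K: int, rng: np.random.Generator):
    """Shuffled round-robin assignment of each class's cases to K folds."""
    folds: list[list[int]] = [[] for _ in range(K)]
    start = 0
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        idx = idx[rng.permutation(len(idx))]
        for j, i in enumerate(idx):
            folds[(start + j) % K].append(int(i))
        start += len(idx)
    return [np.asarray(sorted(f), dtype=int) for f in folds]


def kfold_cv(
    dm: DesignMatrix, K: int, seed: int = 0, priors="frequencies"
) -> ResamplingResult:
    """Stratified K-fold cross-validation of the LDA stage.

    Each fold serves once as the test split while the classifier is
    refitted on the rest, on the design matrix's fixed feature columns.
    With ``K == n`` the partition degenerates to the identity (case i
    alone in fold i, no randomness), which makes it coincide exactly
    with :func:`loo`. Folds whose training split misses a class
    entirely are rejected and the partition re-drawn.
    """
    n = dm.n_cases
    if not 2 <= K <= n:
        raise TooFewCases(f"K must be in [2, {n}], got {K}")
    if K == n:
        folds = [np.array([i]) for i in range(n)]
    else:
        rng = np.random.default_rng(seed)
        for _attempt in range(100):
            folds = _stratified_folds(dm.y, K, rng)
            ok = all(
                len(np.unique(np.delete(dm.y, f))) == dm.n_classes for f in folds
            )
            if ok:
                break
        else:
            raise TooFewCases(
                "could not stratify folds with every class in each training split"
            )
    accs, pcs = [], []
    all_idx = np.arange(n)
    for f in folds:
        train_idx = np.setdiff1d(all_idx, f)
        if len(np.unique(dm.y[train_idx])) < dm.n_classes:
            raise TooFewCases("a training split lost a class entirely")
        pred = _fit_eval(dm, train_idx, f, priors)
        a, pc = _replicate_scores(dm, f, pred)
        accs.append(a)
        pcs.append(pc)
    return _summarise(f"{K}-fold", accs, pcs, dm, seed if K < n else None)


def loo(dm: DesignMatrix, priors="frequencies") -> ResamplingResult:
    """Leave-one-out: K-fold with K equal to the number of cases."""
    if dm.n_cases < dm.n_classes + 2:
        raise TooFewCases("leave-one-out needs at least C+2 cases")
    res = kfold_cv(dm, K=dm.n_cases, priors=priors)
    res.method = "loo"
    return res


def bootstrap_eval(
    dm: DesignMatrix,
    N: int = 1000,
    seed: int = 0,
    priors="frequencies",
    eval_on: str = "oob",
) -> ResamplingResult:
    """Bootstrap error estimation of the LDA stage.

    Each of the N replicates draws n cases with replacement, refits the
    classifier on the resample (fixed feature columns) and scores it on
    the out-of-bag cases (``eval_on='full'`` scores on the complete
    original set instead). Replicates whose resample misses a class, or
    whose out-of-bag set is empty, are redrawn; the count of redraws is
    recorded.
    """
    n = dm.n_cases
    if n < dm.n_classes + 2:
        raise TooFewCases("bootstrap needs at least C+2 cases")
    if eval_on not in ("oob", "full"):
        raise ValueError("eval_on must be 'oob' or 'full'")
    rng = np.random.default_rng(seed)
    accs, pcs = [], []
    oob_fracs = []
    n_redrawn = 0
    all_idx = np.arange(n)
    for _ in range(N):
        while True:
            sample = rng.integers(0, n, size=n)
            oob = np.setdiff1d(all_idx, sample)
            if len(np.unique(dm.y[sample])) < dm.n_classes or len(oob) == 0:
                n_redrawn += 1
                continue
            break
        test_idx = oob if eval_on == "oob" else all_idx
        pred = _fit_eval(dm, sample, test_idx, priors)
        a, pc = _replicate_scores(dm, test_idx, pred)
        accs.append(a)
        pcs.append(pc)
        oob_fracs.append(len(oob) / n)
    res = _summarise("bootstrap", accs, pcs, dm, seed, n_redrawn)
    res.oob_fraction_mean = float(np.mean(oob_fracs))  # type: ignore[attr-defined]
    return res


def roc_curve(scores, positives) -> tuple[np.ndarray, np.ndarray, float]:
    """Binary ROC by sweeping the threshold over the unique scores.

    Tied scores form a single threshold step (a diagonal segment), the
    convention under which the trapezoidal AUC equals the Mann-Whitney
    concordant-pair fraction. Returns (fpr, tpr, auc) with both curves
    running monotonically from (0, 0) to (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives).astype(bool)
    P = int(positives.sum())
    Nn = len(positives) - P
    if P == 0 or Nn == 0:
        raise OneClassOnly("ROC needs both positive and negative cases")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    pos = positives[order]
    # group tied scores into one step
    boundaries = np.flatnonzero(np.diff(s)) + 1
    tp = np.concatenate([[0], np.add.accumulate(pos)[np.append(boundaries - 1, len(s) - 1)]])
    fp = np.concatenate([[0], np.add.accumulate(~pos)[np.append(boundaries - 1, len(s) - 1)]])
    tpr = tp / P
    fpr = fp / Nn
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def multiclass_roc(model: FisherLDAClassifier, dm: DesignMatrix) -> RocResult:
    """One-vs-rest (dichotomised) ROC per class, scored by the
    posterior probability of that class."""
    post = model.predict_proba(dm.X)
    result = RocResult()
    for c, name in enumerate(dm.class_names):
        fpr, tpr, auc = roc_curve(post[:, c], dm.y == c)
        result.per_class.append((name, fpr, tpr, auc))
    return result
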