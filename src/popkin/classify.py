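"""Greedy forward feature selection by leave-one-out cross-validated AUC.

Logistic regression classifiers are grown one feature at a time: step 1
keeps the single feature with the highest pooled LOOCV AUC, and each later
step adds the feature that maximises the pooled AUC of the enlarged subset.
Inside every training fold the minority class is up-sampled with replacement
to parity, features are standardised with training-fold statistics, and
hyperparameters (inverse regularisation C, penalty, intercept) are chosen by
inner stratified k-fold AUC.  The held-out predictions from all folds are
pooled into one ROC per subset; AUC uncertainty uses the Hanley-McNeil
closed-form standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

__all__ = [
    "ClassifierSpec",
    "AucEstimate",
    "SelectionStep",
    "SelectionTrace",
    "roc_auc",
    "hanley_mcneil_ci",
    "loocv_scores",
    "greedy_select",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameter search space and evaluation settings.

    The default grid spans C in [0.01, 100] (9 log-spaced points) with L1,
    L2 and no penalty, and intercept on/off.  ``small_grid()`` gives a
    reduced L2-only grid for large simulation studies.
    """

    inverse_regularization_grid: tuple[float, ...] = tuple(
        float(c) for c in np.logspace(-2, 2, 9)
    )
    penalty_options: tuple[str, ...] = ("l2", "l1", "none")
    fit_intercept_options: tuple[bool, ...] = (True, False)
    inner_cv_folds: int = 3
    max_features: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0.01 - 1e-12 <= c <= 100 + 1e-12
               for c in self.inverse_regularization_grid):
            raise ValueError("C grid must lie within [0.01, 100]")
        if self.inner_cv_folds < 2:
            raise ValueError("inner_cv_folds must be >= 2")
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")
        bad = set(self.penalty_options) - {"l1", "l2", "none"}
        if bad:
            raise ValueError(f"unknown penalties: {sorted(bad)}")

    def combos(self) -> list[tuple[Optional[float], str, bool]]:
        out = []
        for pen in self.penalty_options:
            for fi in self.fit_intercept_options:
                if pen == "none":
                    out.append((None, pen, fi))
                else:
                    for c in self.inverse_regularization_grid:
                        out.append((c, pen, fi))
        return out

    @staticmethod
    def small_grid(seed: int = 0, max_features: int = 3) -> "ClassifierSpec":
        return ClassifierSpec(
            inverse_regularization_grid=(0.1, 1.0, 10.0),
            penalty_options=("l2",),
            fit_intercept_options=(True,),
            seed=seed,
            max_features=max_features,
        )


@dataclass(frozen=True)
class AucEstimate:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    level: float = 0.95


@dataclass(frozen=True)
class SelectionStep:
    feature: str
    auc: float
    estimate: AucEstimate


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]
    pooled_scores: np.ndarray

    @property
    def selected(self) -> list[str]:
        return [s.feature for s in self.steps]


def roc_auc(scores: Sequence[float], labels: Sequence[int]):
    """ROC points (by descending-score thresholds, ties grouped) and
    trapezoidal AUC; identical to the concordant-pair estimator."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def hanley_mcneil_ci(
    auc: float, n_pos: int, n_neg: int, level: float = 0.95
) -> AucEstimate:
    """Hanley-McNeil standard error and Wald CI for an AUC.

    SE^2 = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos*n_neg)
    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A); the CI is clipped to [0, 1].
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class counts must be >= 1")
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must lie in [0, 1]")
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a))
    var /= n_pos * n_neg
    se = math.sqrt(max(var, 0.0))
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    return AucEstimate(
        auc=a, se=se,
        ci_low=max(0.0, a - z * se), ci_high=min(1.0, a + z * se),
        n_pos=n_pos, n_neg=n_neg, level=level,
    )


def _fit_logistic(C: Optional[float], penalty: str, fit_intercept: bool,
                  X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    if penalty == "none":  # unregularised maximum likelihood
        clf = LogisticRegression(C=np.inf, fit_intercept=fit_intercept,
                                 solver="lbfgs", max_iter=500)
    else:
        clf = LogisticRegression(C=C, l1_ratio=1.0 if penalty == "l1" else 0.0,
                                 fit_intercept=fit_intercept,
                                 solver="liblinear", max_iter=500, tol=1e-6)
    clf.fit(X, y)
    return clf


def _upsample(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Up-sample the minority class with replacement to parity."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    need = int(counts.max() - counts.min())
    idx = np.flatnonzero(y == minority)
    extra = rng.choice(idx, size=need, replace=True)
    order = np.concatenate([np.arange(len(y)), extra])
    return X[order], y[order]


def _inner_auc(combo, X, y, folds, seed) -> float:
    """Mean AUC of one hyperparameter combo over inner stratified folds."""
    C, pen, fi = combo
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr_idx, va_idx in skf.split(X, y):
        if len(np.unique(y[va_idx])) < 2 or len(np.unique(y[tr_idx])) < 2:
            raise ValueError("inner fold lacks a class; reduce inner_cv_folds")
        clf = _fit_logistic(C, pen, fi, X[tr_idx], y[tr_idx])
        s = clf.predict_proba(X[va_idx])[:, 1]
        _, a = roc_auc(s, y[va_idx])
        aucs.append(a)
    return float(np.mean(aucs))


def loocv_scores(
    feature_matrix: np.ndarray,
    labels: Sequence[int],
    feature_subset: Sequence[int],
    spec: ClassifierSpec,
) -> np.ndarray:
    """Pooled held-out probabilities from leave-one-out cross-validation.

    Per fold: the held-out sample is removed, the minority class of the
    training fold is up-sampled to parity (fold-specific seed), features are
    standardised with training statistics, hyperparameters are selected by
    inner stratified k-fold AUC on the training fold, and the refitted model
    scores the held-out sample.  Deterministic given ``spec.seed``.
    """
    X_all = np.asarray(feature_matrix, dtype=float)[:, list(feature_subset)]
    y = np.asarray(labels).astype(int)
    n = len(y)
    if n < 4:
        raise ValueError("need n >= 4")
    if min(np.bincount(y)) < 2:
        raise ValueError("both classes need >= 2 samples")
    combos = spec.combos()
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X_all[mask], y[mask]
        fold_seed = (int(spec.seed) * 100003 + i) % (2 ** 31)
        rng = np.random.default_rng(fold_seed)
        Xtr, ytr = _upsample(Xtr, ytr, rng)
        scaler = StandardScaler().fit(Xtr)
        Xtr_s = scaler.transform(Xtr)
        if len(combos) > 1:
            inner = [_inner_auc(c, Xtr_s, ytr, spec.inner_cv_folds, fold_seed % 10_000)
                     for c in combos]
            best = combos[int(np.argmax(inner))]
        else:
            best = combos[0]
        clf = _fit_logistic(best[0], best[1], best[2], Xtr_s, ytr)
        scores[i] = clf.predict_proba(scaler.transform(X_all[i:i + 1]))[0, 1]
    return scores


def greedy_select(
    feature_matrix: np.ndarray,
    labels: Sequence[int],
    spec: ClassifierSpec,
    feature_names: Sequence[str] | None = None,
) -> SelectionTrace:
    """Greedy forward selection maximising pooled LOOCV AUC.

    Ties are broken by canonical (input) feature order.  The trace carries
    one step per added feature, each with its pooled AUC and Hanley-McNeil
    estimate, plus the final model's pooled held-out scores.
    """
    X = np.asarray(feature_matrix, dtype=float)
    y = np.asarray(labels).astype(int)
    p = X.shape[1]
    if p < 1:
        raise ValueError("need >= 1 candidate feature")
    names = list(feature_names) if feature_names is not None else [
        f"f{j}" for j in range(p)
    ]
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    selected: list[int] = []
    steps: list[SelectionStep] = []
    last_scores = np.empty(0)
    for _ in range(min(spec.max_features, p)):
        best_j, best_auc, best_scores = -1, -math.inf, None
        for j in range(p):
            if j in selected:
                continue
            s = loocv_scores(X, y, selected + [j], spec)
            _, a = roc_auc(s, y)
            if a > best_auc:  # strict: ties keep the earlier (canonical) feature
                best_j, best_auc, best_scores = j, a, s
        selected.append(best_j)
        last_scores = best_scores
        steps.append(SelectionStep(
            feature=names[best_j], auc=best_auc,
            estimate=hanley_mcneil_ci(best_auc, n_pos, n_neg),
        ))
    return SelectionTrace(steps=steps, pooled_scores=last_scores)
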