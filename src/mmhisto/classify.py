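"""Cost-balanced RBF-SVM classification and cross-validated evaluation.

The classifier is a support vector machine with a radial basis kernel
``K(xi, xj) = exp(-gamma * ||xi - xj||^2)``.  Class imbalance is handled by
two cost factors with ratio ``C+/C- = (#negative examples)/(#positive
examples)``, which makes the potential total cost of false positives and
false negatives equal.  ``gamma = 1`` is the default; the usual grid
``{10, 1, 0.1, 0.01, 0.001}`` is exposed in the config.

Features are z-scored with training-split statistics before the kernel:
the morphological features mix units (pixel areas, distances, ratios,
entropies) and an RBF on raw columns would be dominated by the largest
scale.  Evaluation is repeated stratified K-fold cross-validation with the
*entire* two-stage feature selection re-run inside every training fold, so
held-out data never influences selection (a tested contract).  Held-out
scores of the K folds are pooled into one ROC per repeat; the report gives
mean/std over repeats of the AUC and of specificity at fixed sensitivities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

GAMMA_GRID = (10.0, 1.0, 0.1, 0.01, 0.001)
SENS_LEVELS = (90, 95, 99)


@dataclass
class ClassifierConfig:
    gamma: float = 1.0
    gamma_grid: tuple = GAMMA_GRID
    base_cost: float = 1.0
    cv_folds: int = 10
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class EvalReport:
    auc_mean: float
    auc_std: float
    spec_at_sens: dict  # {90: (mean, std), ...} in percent
    per_fold_scores: pd.DataFrame  # columns: repeat, fold, index, y, score
    selected_features_per_fold: list


def cost_ratio(y: np.ndarray) -> float:
    """C+/C- = #negatives / #positives."""
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return n_neg / n_pos


@dataclass
class TrainedSvm:
    """Fitted scorer: standardization stats + SVC, restricted to a feature subset."""

    columns: tuple
    mean: np.ndarray
    std: np.ndarray
    svc: SVC

    def score(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float)[:, list(self.columns)] - self.mean) / self.std
        return self.svc.decision_function(Z)

    __call__ = score


def train_svm(
    X: np.ndarray, y: np.ndarray, features, cfg: ClassifierConfig | None = None
) -> TrainedSvm:
    """Fit the cost-balanced RBF-SVM on a feature subset.

    Standardization statistics come from the given (training) data only.
    """
    cfg = cfg or ClassifierConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    cols = tuple(sorted(features))
    Xs = X[:, list(cols)]
    if len(Xs) >= 2 and np.allclose(Xs, Xs[0]):
        raise ValueError("degenerate training data: all rows identical")
    mu = Xs.mean(axis=0)
    sd = Xs.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Z = (Xs - mu) / sd
    ratio = cost_ratio(y)
    svc = SVC(
        kernel="rbf",
        gamma=cfg.gamma,
        C=cfg.base_cost,
        class_weight={0: 1.0, 1: ratio},
    )
    svc.fit(Z, y)
    return TrainedSvm(columns=cols, mean=mu, std=sd, svc=svc)


def auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney (rank) AUC with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def spec_at_sensitivity(scores, y, sens_levels=SENS_LEVELS) -> dict:
    """Specificity (%) at the highest threshold reaching each sensitivity level.

    Predictions are positive when ``score >= threshold``; for each level the
    highest threshold with sensitivity >= level is used (conservative: the
    reported specificity is attainable at that exact operating point).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    pos, neg = scores[y == 1], scores[y == 0]
    out = {}
    thresholds = np.sort(np.unique(scores))[::-1]
    for level in sens_levels:
        spec = 0.0
        for t in thresholds:  # descending: first hit is the highest threshold
            if (pos >= t).mean() * 100 >= level:
                spec = float((neg < t).mean() * 100)
                break
        out[int(level)] = spec
    return out


def _subset_cv_auc_cached(X, y, cols: tuple, splits, cfg: ClassifierConfig, cache: dict) -> float:
    if cols in cache:
        return cache[cols]
    scores = np.empty(len(y), dtype=float)
    for tr, te in splits:
        model = train_svm(X[tr], y[tr], cols, cfg)
        scores[te] = model.score(X[te])
    val = auc(scores, y)
    cache[cols] = val
    return val


def make_auc_scorer(X: np.ndarray, y: np.ndarray, cfg: ClassifierConfig | None = None,
                    folds: int = 5, seed: int = 0):
    """Cross-validated-AUC scorer over feature subsets, with memoization.

    Used as the selection criterion: AUC is estimated by stratified K-fold
    cross-validation on the given (training) data with a fixed seed, so the
    criterion is deterministic for a given dataset.
    """
    cfg = cfg or ClassifierConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    folds = min(folds, int((y == 1).sum()), int((y == 0).sum()))
    folds = max(folds, 2)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = [(tr, te) for tr, te in skf.split(X, y)]
    cache: dict = {}

    def scorer(cols) -> float:
        return _subset_cv_auc_cached(X, y, tuple(sorted(cols)), splits, cfg, cache)

    return scorer


def _stratified_splits(y: np.ndarray, folds: int, seed: int):
    folds = min(folds, int((y == 1).sum()), int((y == 0).sum()))
    folds = max(folds, 2)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ClassifierConfig | None = None,
    selection_cfg=None,
    splits_per_repeat: list | None = None,
) -> EvalReport:
    """Repeated stratified K-fold evaluation with nested feature selection.

    Per fold, mRMR + SFFS selection and SVM training see the training split
    only; the held-out fold is scored once.  ``splits_per_repeat`` overrides
    the random partitions (used to test the leakage contract).
    """
    from .selection import SelectionConfig, select_features  # local to avoid cycle

    cfg = cfg or ClassifierConfig()
    selection_cfg = selection_cfg or SelectionConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 samples per class")

    if splits_per_repeat is None:
        splits_per_repeat = [
            _stratified_splits(y, cfg.cv_folds, cfg.seed + rep) for rep in range(cfg.n_repeats)
        ]

    rows = []
    aucs, specs = [], {lvl: [] for lvl in SENS_LEVELS}
    selected_all = []
    for rep, splits in enumerate(splits_per_repeat):
        pooled = np.empty(len(y), dtype=float)
        for k, (tr, te) in enumerate(splits):
            sel = select_features(X[tr], y[tr], selection_cfg, classifier_cfg=cfg)
            model = train_svm(X[tr], y[tr], sel.final_set, cfg)
            pooled[te] = model.score(X[te])
            selected_all.append(frozenset(sel.final_set))
            for i in te:
                rows.append({"repeat": rep, "fold": k, "index": int(i), "y": int(y[i])})
        aucs.append(auc(pooled, y))
        sp = spec_at_sensitivity(pooled, y)
        for lvl in SENS_LEVELS:
            specs[lvl].append(sp[lvl])
        for row in rows:
            if row["repeat"] == rep and "score" not in row:
                row["score"] = float(pooled[row["index"]])
    return EvalReport(
        auc_mean=float(np.mean(aucs)),
        auc_std=float(np.std(aucs)),
        spec_at_sens={lvl: (float(np.mean(v)), float(np.std(v))) for lvl, v in specs.items()},
        per_fold_scores=pd.DataFrame(rows),
        selected_features_per_fold=selected_all,
    )


def train_test_transfer(
    X_train, y_train, X_test, y_test, cfg: ClassifierConfig | None = None, selection_cfg=None
) -> EvalReport:
    """Select + train on one cohort, evaluate once on another.

    Standardization statistics and the selected feature set come from the
    training cohort only.
    """
    from .selection import SelectionConfig, select_features

    cfg = cfg or ClassifierConfig()
    selection_cfg = selection_cfg or SelectionConfig()
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError("train/test feature matrices have different widths")
    y_train = np.asarray(y_train).astype(int)
    y_test = np.asarray(y_test).astype(int)
    sel = select_features(X_train, y_train, selection_cfg, classifier_cfg=cfg)
    model = train_svm(X_train, y_train, sel.final_set, cfg)
    scores = model.score(X_test)
    sp = spec_at_sensitivity(scores, y_test)
    rows = [
        {"repeat": 0, "fold": 0, "index": int(i), "y": int(y_test[i]), "score": float(scores[i])}
        for i in range(len(y_test))
    ]
    return EvalReport(
        auc_mean=auc(scores, y_test),
        auc_std=0.0,
        spec_at_sens={lvl: (sp[lvl], 0.0) for lvl in SENS_LEVELS},
        per_fold_scores=pd.DataFrame(rows),
        selected_features_per_fold=[frozenset(sel.final_set)],
    )
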