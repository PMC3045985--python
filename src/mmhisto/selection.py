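"""Two-stage feature selection: mRMR ranking, then SFFS refinement.

Stage 1 orders all features by the minimum-redundancy-maximal-relevance
criterion in its difference (MID) form: the first feature maximizes the
mutual information ``I(f; y)`` with the class label; each subsequent pick
maximizes ``I(f; y) - mean_g I(f; g)`` over the already-chosen set.
Features are discretized into 3 bins at mean +/- one standard deviation
before any mutual-information computation.  The candidate set is the
top-``i`` prefix (``i <= 30``) of that order whose cross-validated AUC is
highest, ties going to the smaller prefix.

Stage 2 refines the candidate with sequential floating forward selection
(SFFS): repeatedly add the feature whose inclusion maximizes the AUC, then
keep deleting the feature whose removal improves on the best AUC seen so
far; stop when the AUC reaches 1.0 or the number of additions plus
deletions exceeds a budget of 20.  The best-scoring feature set ever
encountered is returned.

All AUC ties break toward smaller feature sets, then lexicographically
smaller feature indices, making the whole procedure deterministic for a
fixed inner-CV seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import ClassifierConfig, make_auc_scorer


@dataclass
class SelectionConfig:
    i_max: int = 30        # longest mRMR prefix considered for the candidate set
    budget: int = 20       # SFFS additions + deletions
    inner_folds: int = 5   # CV folds of the AUC criterion on the training split
    inner_seed: int = 0


@dataclass
class SelectionResult:
    mrmr_order: list          # permutation of feature column indices
    relevance: np.ndarray     # I(f; y) per feature, in bits
    candidate_set: set
    final_set: set
    final_auc: float
    trace: list               # (step, "add"/"remove", feature, auc)


def discretize_3bin(X: np.ndarray) -> np.ndarray:
    """Per-column 3-level discretization at mean +/- one standard deviation."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    out = np.ones(X.shape, dtype=np.int8)
    out[X < mu - sd] = 0
    out[X > mu + sd] = 2
    return out


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information of two discrete variables, in bits."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("arrays must have equal length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz])).sum())


def mrmr_rank(X: np.ndarray, y: np.ndarray, cfg: SelectionConfig | None = None):
    """Greedy mRMR (MID form) ordering of all feature columns.

    Returns ``(order, relevance)``: the full permutation of column indices
    and the per-feature relevance ``I(f; y)``.  Ties break toward the lower
    column index.
    """
    cfg = cfg or SelectionConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have mismatched lengths")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    D = discretize_3bin(X)
    m = X.shape[1]
    relevance = np.array([mutual_information(D[:, j], y) for j in range(m)])

    pair_mi = np.full((m, m), np.nan)

    def redundancy(j: int, chosen: list) -> float:
        vals = []
        for g in chosen:
            if np.isnan(pair_mi[j, g]):
                pair_mi[j, g] = pair_mi[g, j] = mutual_information(D[:, j], D[:, g])
            vals.append(pair_mi[j, g])
        return float(np.mean(vals)) if vals else 0.0

    order: list[int] = []
    remaining = list(range(m))
    while remaining:
        scores = [(relevance[j] - redundancy(j, order), -j) for j in remaining]
        best = max(range(len(remaining)), key=lambda k: scores[k])
        order.append(remaining.pop(best))
    return order, relevance


def best_prefix(order, X, y, classifier_cfg: ClassifierConfig | None = None,
                i_max: int = 30, scorer=None) -> set:
    """mRMR prefix (length <= i_max) with the best cross-validated AUC.

    Ties break toward the smaller prefix.
    """
    if len(order) == 0:
        raise ValueError("empty feature order")
    scorer = scorer or make_auc_scorer(X, y, classifier_cfg)
    best_set, best_auc = None, -1.0
    for i in range(1, min(i_max, len(order)) + 1):
        a = scorer(order[:i])
        if a > best_auc:  # strict: ties keep the smaller prefix
            best_auc, best_set = a, set(order[:i])
    return best_set


def sffs_refine(candidate_set, X, y, classifier_cfg: ClassifierConfig | None = None,
                budget: int = 20, scorer=None, pool=None) -> tuple[set, float, list]:
    """SFFS floating search from a candidate set.

    Returns ``(best_set, best_auc, trace)`` where the trace lists each
    (step, action, feature, auc).  Stops at AUC 1.0 or after ``budget``
    additions+deletions; the best set seen anywhere wins.
    """
    if not candidate_set:
        raise ValueError("candidate set must be nonempty")
    X = np.asarray(X, dtype=float)
    scorer = scorer or make_auc_scorer(X, y, classifier_cfg)
    pool = set(range(X.shape[1])) if pool is None else set(pool)

    current = set(candidate_set)
    best_set, best_auc = set(current), scorer(current)
    trace: list[tuple[int, str, int, float]] = []
    actions = 0
    while best_auc < 1.0 and actions < budget:
        outside = sorted(pool - current)
        if not outside:
            break
        # addition: best single feature to include (ties -> smaller index)
        add_scores = [(scorer(current | {x}), -x) for x in outside]
        k = max(range(len(outside)), key=lambda i: add_scores[i])
        x_add = outside[k]
        current.add(x_add)
        actions += 1
        a = add_scores[k][0]
        trace.append((actions, "add", x_add, a))
        if a > best_auc or (a == best_auc and len(current) < len(best_set)):
            best_auc, best_set = a, set(current)
        if best_auc >= 1.0 or actions >= budget:
            break
        # conditional deletions: keep removing while it beats the best seen
        while len(current) > 1 and actions < budget:
            inside = sorted(current)
            del_scores = [(scorer(current - {x}), -x) for x in inside]
            k = max(range(len(inside)), key=lambda i: del_scores[i])
            a_del = del_scores[k][0]
            if a_del <= best_auc:
                break
            x_del = inside[k]
            current.discard(x_del)
            actions += 1
            trace.append((actions, "remove", x_del, a_del))
            best_auc, best_set = a_del, set(current)
            if best_auc >= 1.0:
                break
    return best_set, best_auc, trace


def select_features(X, y, cfg: SelectionConfig | None = None,
                    classifier_cfg: ClassifierConfig | None = None) -> SelectionResult:
    """Run both stages (mRMR candidate + SFFS refinement) on one training set."""
    cfg = cfg or SelectionConfig()
    classifier_cfg = classifier_cfg or ClassifierConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    scorer = make_auc_scorer(X, y, classifier_cfg, folds=cfg.inner_folds, seed=cfg.inner_seed)
    order, relevance = mrmr_rank(X, y, cfg)
    candidate = best_prefix(order, X, y, classifier_cfg, i_max=cfg.i_max, scorer=scorer)
    final, final_auc, trace = sffs_refine(
        candidate, X, y, classifier_cfg, budget=cfg.budget, scorer=scorer
    )
    return SelectionResult(
        mrmr_order=order,
        relevance=relevance,
        candidate_set=candidate,
        final_set=final,
        final_auc=final_auc,
        trace=trace,
    )


def selection_to_dict(res: SelectionResult, feature_names=None) -> dict:
    """JSON-serializable view of a SelectionResult."""
    name = (lambda j: feature_names[j]) if feature_names is not None else (lambda j: int(j))
    return {
        "mrmr_order": [name(j) for j in res.mrmr_order],
        "relevance": {name(j): float(res.relevance[j]) for j in range(len(res.relevance))},
        "candidate_set": sorted(name(j) for j in res.candidate_set),
        "final_set": sorted(name(j) for j in res.final_set),
        "final_auc": res.final_auc,
        "trace": [
            {"step": s, "action": a, "feature": name(f), "auc": float(v)} for s, a, f, v in res.trace
        ],
    }
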