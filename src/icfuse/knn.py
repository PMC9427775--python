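"""Distance-weighted KNN class prediction with t-test feature selection.

This reimplements the classifier used to transfer integrative-cluster
labels to external cohorts: per-class one-vs-rest Welch t statistics rank
the features, a round-robin interleave across classes balances marker
representation, and prediction is by inverse-distance-weighted votes of the
K nearest training samples (Euclidean). Hyper-parameters (K, number of
features) are tuned by leave-one-out cross-validation with feature
selection re-run inside every fold to avoid selection leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import KNNParams
from .types import ValidationError

log = logging.getLogger("icfuse")

_D_FLOOR = 1e-12


def _class_order(labels: np.ndarray) -> list:
    """Class order = order of first occurrence in the training labels."""
    seen: dict = {}
    for lab in labels:
        if lab not in seen:
            seen[lab] = len(seen)
    return list(seen)


def _welch_t(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-feature Welch t statistic, group `mask` vs rest. X: features x n."""
    a, b = X[:, mask], X[:, ~mask]
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1) if na > 1 else np.zeros(X.shape[0])
    vb = b.var(axis=1, ddof=1) if nb > 1 else np.zeros(X.shape[0])
    denom = np.sqrt(va / max(na, 1) + vb / max(nb, 1))
    diff = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / denom
    # zero-variance, zero-difference features carry no signal
    t = np.where(np.isfinite(t), t, np.where(diff != 0, np.inf * np.sign(diff), 0.0))
    return t


def select_features_ttest(X: np.ndarray, labels, n: int) -> np.ndarray:
    """Round-robin interleave of per-class one-vs-rest |t| rankings.

    Returns indices of the selected features (length min(n, n_features)).
    Every class with >= 2 samples contributes its top-ranked unseen feature
    in turn until n features are chosen.
    """
    labels = np.asarray(labels)
    n_features = X.shape[0]
    if n > n_features:
        log.info("select_features_ttest: capping n=%d at %d features", n, n_features)
        n = n_features
    classes = _class_order(labels)
    rankings = []
    for c in classes:
        mask = labels == c
        if mask.sum() < 2 or (~mask).sum() < 2:
            # can happen inside LOO folds; the class contributes no ranking
            log.warning("select_features_ttest: class %r too small for a "
                        "t statistic; skipped", c)
            continue
        t = np.abs(_welch_t(X, mask))
        rankings.append(np.argsort(-t, kind="stable"))
    if not rankings:
        raise ValidationError("no class has >= 2 samples on both sides")
    chosen: list[int] = []
    taken = np.zeros(n_features, dtype=bool)
    cursors = [0] * len(rankings)
    while len(chosen) < n:
        for ci in range(len(rankings)):
            if len(chosen) >= n:
                break
            r = rankings[ci]
            cur = cursors[ci]
            while cur < n_features and taken[r[cur]]:
                cur += 1
            cursors[ci] = cur
            if cur < n_features:
                f = r[cur]
                taken[f] = True
                chosen.append(int(f))
                cursors[ci] = cur + 1
    return np.array(chosen, dtype=int)


@dataclass
class TrainedKNN:
    selected_features: np.ndarray   # indices into the training feature axis
    feature_ids: list[str]
    X_train: np.ndarray             # selected features x training samples
    labels: np.ndarray
    K: int
    class_order: list

    @classmethod
    def fit(cls, X: np.ndarray, labels, feature_ids, K: int, n_features: int
            ) -> "TrainedKNN":
        labels = np.asarray(labels)
        sel = select_features_ttest(X, labels, n_features)
        return cls(
            selected_features=sel,
            feature_ids=[feature_ids[i] for i in sel],
            X_train=X[sel],
            labels=labels,
            K=K,
            class_order=_class_order(labels),
        )


def knn_predict(model: TrainedKNN, X_new: np.ndarray
                ) -> tuple[np.ndarray, pd.DataFrame]:
    """Predict labels for queries (selected-features x queries).

    Class score = sum of 1/d over the K nearest neighbors of that class
    (d floored at 1e-12); a neighbor at exactly zero distance decides the
    query outright. Ties break toward the earlier class in training order.
    """
    if X_new.shape[0] != model.X_train.shape[0]:
        raise ValidationError(
            f"query matrix has {X_new.shape[0]} features, model expects "
            f"{model.X_train.shape[0]}"
        )
    T = model.X_train.T  # train samples x features
    Q = X_new.T
    d2 = (
        np.sum(Q**2, axis=1)[:, None]
        + np.sum(T**2, axis=1)[None, :]
        - 2 * Q @ T.T
    )
    D = np.sqrt(np.maximum(d2, 0.0))
    classes = model.class_order
    votes = np.zeros((Q.shape[0], len(classes)))
    preds = np.empty(Q.shape[0], dtype=object)
    K = min(model.K, T.shape[0])
    for qi in range(Q.shape[0]):
        order = np.argsort(D[qi], kind="stable")[:K]
        dists = D[qi, order]
        if dists[0] < _D_FLOOR:
            winner = model.labels[order[0]]
            votes[qi, classes.index(winner)] = np.inf
            preds[qi] = winner
            continue
        w = 1.0 / np.maximum(dists, _D_FLOOR)
        for o, wt in zip(order, w):
            votes[qi, classes.index(model.labels[o])] += wt
        preds[qi] = classes[int(np.argmax(votes[qi]))]  # argmax: first max wins
    vote_table = pd.DataFrame(votes, columns=[str(c) for c in classes])
    return preds, vote_table


def align_query(model: TrainedKNN, values: pd.DataFrame) -> np.ndarray:
    """Extract the model's selected feature rows from a query matrix."""
    missing = [f for f in model.feature_ids if f not in values.index]
    if missing:
        raise ValidationError(f"query matrix lacks feature {missing[0]!r}")
    return values.loc[model.feature_ids].to_numpy(dtype=float)


def _loo_accuracy_table(
    X: np.ndarray, labels: np.ndarray, k_grid, feature_grid
) -> pd.DataFrame:
    """LOO accuracy for every (K, n_features) pair, sharing per-fold work.

    Inside each fold the per-class rankings are computed once; every
    n_features grid point is a prefix of the same round-robin order, so the
    cumulative squared distances over that order give all grid points from
    one pass.
    """
    labels = np.asarray(labels)
    n = X.shape[1]
    n_features_cap = X.shape[0]
    feat_list = sorted({min(f, n_features_cap) for f in feature_grid})
    correct = {(K, f): 0 for K in k_grid for f in feat_list}
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr = X[:, mask], labels[mask]
        counts = pd.Series(y_tr).value_counts()
        if (counts < 2).any():
            log.warning("loocv: fold %d has a class with < 2 samples", i)
        order = select_features_ttest(X_tr, y_tr, n_features_cap)
        # cumulative squared distances from the held-out sample to training
        diff2 = (X_tr[order] - X[order, i][:, None]) ** 2  # features x train
        cum = np.cumsum(diff2, axis=0)
        for f in feat_list:
            d = np.sqrt(cum[f - 1])
            nearest = np.argsort(d, kind="stable")
            for K in k_grid:
                kk = min(K, len(y_tr))
                idx = nearest[:kk]
                dd = d[idx]
                if dd[0] < _D_FLOOR:
                    pred = y_tr[idx[0]]
                else:
                    classes = _class_order(y_tr)
                    w = 1.0 / np.maximum(dd, _D_FLOOR)
                    scores = np.zeros(len(classes))
                    for o, wt in zip(idx, w):
                        scores[classes.index(y_tr[o])] += wt
                    pred = classes[int(np.argmax(scores))]
                if pred == labels[i]:
                    correct[(K, f)] += 1
    rows = [
        {"K": K, "n_features": f, "accuracy": correct[(K, f)] / n}
        for K in k_grid for f in feat_list
    ]
    return pd.DataFrame(rows)


def loocv_accuracy(X: np.ndarray, labels, K: int, n_features: int) -> float:
    """Leave-one-out accuracy at a single (K, n_features) grid point.

    Feature selection is re-run on every fold's n-1 training samples.
    """
    table = _loo_accuracy_table(X, np.asarray(labels), [K], [n_features])
    return float(table["accuracy"].iloc[0])


def grid_search(X: np.ndarray, labels, params: KNNParams
                ) -> tuple[tuple[int, int], pd.DataFrame]:
    """Exhaustive LOO evaluation over the (K, n_features) grid.

    Returns the best pair (ties -> smaller n_features, then smaller K) and
    the full accuracy table.
    """
    params.validate()
    table = _loo_accuracy_table(X, np.asarray(labels), list(params.k_grid),
                                list(params.feature_grid))
    ordered = table.sort_values(
        ["accuracy", "n_features", "K"], ascending=[False, True, True]
    )
    best = ordered.iloc[0]
    return (int(best["K"]), int(best["n_features"])), table
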