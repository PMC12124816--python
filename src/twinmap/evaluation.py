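"""Validation protocols: manifold stability and predictor performance.

Stability: the clustered model data are repeatedly split 70/30 within each
cluster, the embedding is refitted on the training part alone, the test
part is projected onto the fresh manifold, and train vs projected-test
points of each original cluster are compared with the symmetric-KL
permutation test.  The manifold is declared stable when, over the
initializations, every cluster's median p-value stays above 0.05 — i.e.
no cluster's geometry depends on the particular subsample or random
initialization.

Predictor performance: stratified 5-fold cross-validated ROC AUC and
accuracy for a random-forest and a (linear-kernel-free, RBF) support-vector
classifier on the 9 predictors against 5-year mortality, plus the forest's
impurity-based importance ranking expressed as percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .benefit import kl_permutation_test
from .exceptions import EvaluationError
from .manifold import ManifoldStratifier

TRAIN_FRACTION = 0.7
N_INITIALIZATIONS = 10
STABILITY_ALPHA = 0.05


@dataclass
class StabilityReport:
    n_initializations: int
    p_values: dict[int, list[float]]          # cluster id -> p per init
    per_cluster_median_p: dict[int, float]
    passed: bool


@dataclass
class PredictiveReport:
    auc_mean: dict[str, float]
    auc_sd: dict[str, float]
    accuracy_mean: dict[str, float]
    accuracy_sd: dict[str, float]
    importance_ranking: list[tuple[str, float]]   # predictor, percent


def stability_split(
    labels, train_fraction: float = TRAIN_FRACTION, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified per-cluster split into train/test index arrays.

    Each cluster contributes ``ceil(train_fraction * size)`` points to the
    training side; a singleton cluster goes entirely to train with a
    warning.  Train and test are disjoint and their union is everything.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cid in np.unique(labels):
        idx = np.flatnonzero(labels == cid)
        if idx.size == 1:
            warnings.warn(f"cluster {cid} has a single member; placed in train")
            train.append(idx)
            continue
        perm = rng.permutation(idx)
        n_train = int(np.ceil(train_fraction * idx.size))
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    train_idx = np.sort(np.concatenate(train))
    test_idx = np.sort(np.concatenate(test)) if test else np.array([], dtype=int)
    return train_idx, test_idx


def stability_validate(
    deviations,
    labels,
    n_init: int = N_INITIALIZATIONS,
    n_permutations: int = 200,
    seed: int | None = None,
    train_fraction: float = TRAIN_FRACTION,
    embed_kwargs: dict | None = None,
) -> StabilityReport:
    """Run the 70/30 refit-and-project stability protocol.

    For each of ``n_init`` initializations the embedding is refitted on
    the training split and the held-out points are projected onto it;
    every original cluster is then tested for train/test distributional
    agreement with the symmetric-KL permutation test.
    """
    X = np.asarray(deviations, dtype=float)
    labels = np.asarray(labels)
    ids, counts = np.unique(labels, return_counts=True)
    usable = ids[counts >= 4]
    if usable.size < 2:
        raise EvaluationError("need at least 2 clusters with >= 4 members")
    embed_kwargs = embed_kwargs or {}
    base_seed = 0 if seed is None else int(seed)
    p_values: dict[int, list[float]] = {int(c): [] for c in usable}
    for i in range(n_init):
        init_seed = base_seed + 1000 * (i + 1)
        tr, te = stability_split(labels, train_fraction, seed=init_seed)
        model = ManifoldStratifier(random_state=init_seed, **embed_kwargs)
        model.fit_embedding(X[tr])
        proj = model.transform(X[te])
        for cid in usable:
            a = model.embedding_[labels[tr] == cid]
            b = proj[labels[te] == cid]
            res = kl_permutation_test(a, b, n_permutations=n_permutations,
                                      seed=init_seed + int(cid))
            p_values[int(cid)].append(res.p_value)
    medians = {c: float(np.median(ps)) for c, ps in p_values.items()}
    return StabilityReport(
        n_initializations=n_init,
        p_values=p_values,
        per_cluster_median_p=medians,
        passed=bool(all(m > STABILITY_ALPHA for m in medians.values())),
    )


def evaluate_predictors(X, y, seed: int | None = None, n_splits: int = 5) -> PredictiveReport:
    """Cross-validated predictive power of the 9 predictors.

    Random forest and RBF support-vector classifiers, stratified k-fold;
    the SVC contributes decision scores (not hard labels) to the ROC.
    The importance ranking comes from a forest refit on all data.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise EvaluationError("outcome has a single class; cannot evaluate")

    models = {
        "RFC": RandomForestClassifier(n_estimators=200, random_state=seed),
        "SVC": make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed)),
    }
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    auc_mean, auc_sd, acc_mean, acc_sd = {}, {}, {}, {}
    for name, clf in models.items():
        aucs, accs = [], []
        for tr, te in cv.split(X, y):
            clf.fit(X[tr], y[tr])
            if hasattr(clf, "predict_proba"):
                score = clf.predict_proba(X[te])[:, 1]
            else:
                score = clf.decision_function(X[te])
            aucs.append(roc_auc_score(y[te], score))
            accs.append(accuracy_score(y[te], clf.predict(X[te])))
        auc_mean[name], auc_sd[name] = float(np.mean(aucs)), float(np.std(aucs))
        acc_mean[name], acc_sd[name] = float(np.mean(accs)), float(np.std(accs))

    forest = RandomForestClassifier(n_estimators=200, random_state=seed).fit(X, y)
    imp = 100.0 * forest.feature_importances_ / forest.feature_importances_.sum()
    ranking = sorted(zip(feature_names, imp.tolist()), key=lambda t: -t[1])
    return PredictiveReport(
        auc_mean=auc_mean, auc_sd=auc_sd,
        accuracy_mean=acc_mean, accuracy_sd=acc_sd,
        importance_ranking=[(n, float(v)) for n, v in ranking],
    )


def plot_roc(X, y, seed, path, n_splits: int = 5) -> None:
    """Mean cross-validated ROC curves for both classifiers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    y = np.asarray(y).astype(int)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    grid = np.linspace(0, 1, 101)
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, clf in (
        ("RFC", RandomForestClassifier(n_estimators=200, random_state=seed)),
        ("SVC", make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed))),
    ):
        tprs, aucs = [], []
        for tr, te in cv.split(X, y):
            clf.fit(X[tr], y[tr])
            score = (clf.predict_proba(X[te])[:, 1]
                     if hasattr(clf, "predict_proba")
                     else clf.decision_function(X[te]))
            fpr, tpr, _ = roc_curve(y[te], score)
            tprs.append(np.interp(grid, fpr, tpr))
            aucs.append(roc_auc_score(y[te], score))
        ax.plot(grid, np.mean(tprs, axis=0),
                label=f"{name} (mean AUC {np.mean(aucs):.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set(xlabel="false positive rate", ylabel="true positive rate",
           title="5-year mortality: cross-validated ROC")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
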