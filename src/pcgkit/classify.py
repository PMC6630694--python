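"""Cost-sensitive KNN and random-subspace ensemble classification with
stratified cross-validation and grid hyper-parameter search.

Classifier presets follow the conventional toolbox meanings: "fine KNN" is
k=1, Euclidean, unweighted; "weighted KNN" is k=10, Euclidean, with
inverse-squared-distance vote weights. The subspace ensemble trains base
learners (linear discriminant or weighted KNN) on seeded random feature
subsets and averages member posteriors.

Misclassification cost enters at decision time: the predicted label
minimizes expected cost over the posterior. With cost 10 for missing an
abnormal heart sound and 1 for a false alarm, the abnormal decision
threshold on p(abnormal) is 1/11, which trades specificity for the
sensitivity a screening test needs. KNN training itself is untouched.

Standardization (z-score per feature) is learned on training data only and
stored with the model; cross-validation refits it inside each fold so no
information leaks from validation folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors

from .io import DatasetManifest
from .metrics import ConfusionMatrix, MetricsReport, compute_metrics, confusion_from_labels

CLASSES = ("normal", "abnormal")  # fixed posterior column order

_METRIC_MAP = {"euclidean": "euclidean", "cityblock": "manhattan",
               "chebyshev": "chebyshev", "cosine": "cosine"}


@dataclass
class CostMatrix:
    """Asymmetric misclassification costs; correct decisions cost 0."""

    cost_fn: float = 10.0  # abnormal predicted as normal (missed disease)
    cost_fp: float = 1.0   # normal predicted as abnormal (false alarm)

    def __post_init__(self):
        if self.cost_fn < 0 or self.cost_fp < 0:
            raise ValueError("costs must be non-negative")
        if self.cost_fn == 0 and self.cost_fp == 0:
            raise ValueError("at least one cost must be positive")

    @property
    def abnormal_threshold(self) -> float:
        """Predict abnormal when p(abnormal) >= this value."""
        return self.cost_fp / (self.cost_fp + self.cost_fn)


@dataclass
class TrainedModel:
    kind: str                      # fine_knn | weighted_knn | subspace_ensemble
    hyperparameters: dict
    cost: CostMatrix
    feature_names: tuple
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    state: dict = field(default_factory=dict)  # fitted components

    def __post_init__(self):
        if len(self.feature_names) != self.scaler_mean.size:
            raise ValueError("feature_names length must match fitted dimensionality")

    def standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}")
        return (X - self.scaler_mean) / self.scaler_std


def _fit_scaler(X: np.ndarray):
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    return mean, std


def _knn_posteriors(train_X, train_y, query_X, k, metric, weighted):
    nn = NearestNeighbors(n_neighbors=min(k, train_X.shape[0]),
                          metric=_METRIC_MAP[metric], algorithm="brute")
    nn.fit(train_X)
    dist, idx = nn.kneighbors(query_X)
    post = np.zeros((query_X.shape[0], len(CLASSES)))
    y_arr = np.asarray(train_y)
    for r in range(query_X.shape[0]):
        if weighted:
            w = 1.0 / (dist[r] ** 2 + 1e-12)
        else:
            w = np.ones_like(dist[r])
        for c, cls in enumerate(CLASSES):
            post[r, c] = w[y_arr[idx[r]] == cls].sum()
    post /= post.sum(axis=1, keepdims=True)
    return post


def fit_knn(X, y, kind: str = "weighted_knn", k: int | None = None,
            metric: str = "euclidean", cost: CostMatrix | None = None,
            feature_names=None) -> TrainedModel:
    """Fit a (cost-sensitive) KNN model; kind is ``fine_knn`` or ``weighted_knn``."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    if kind not in ("fine_knn", "weighted_knn"):
        raise ValueError(f"unknown KNN kind {kind!r}")
    if metric not in _METRIC_MAP:
        raise ValueError(f"unknown metric {metric!r}; choose from {list(_METRIC_MAP)}")
    if k is None:
        k = 1 if kind == "fine_knn" else 10
    if k < 1:
        raise ValueError("k must be >= 1")
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{i}" for i in range(X.shape[1]))
    mean, std = _fit_scaler(X)
    model = TrainedModel(kind, {"k": k, "metric": metric,
                                "weighted": kind == "weighted_knn"},
                         cost or CostMatrix(), names, mean, std)
    model.state = {"train_X": (X - mean) / std, "train_y": y.copy()}
    return model


def knn_predict_proba(model: TrainedModel, X) -> np.ndarray:
    """Per-class posterior estimates (columns ordered as ``CLASSES``);
    neighbor vote fractions, distance-weighted for weighted KNN."""
    Xs = model.standardize(X)
    hp = model.hyperparameters
    return _knn_posteriors(model.state["train_X"], model.state["train_y"], Xs,
                           hp["k"], hp["metric"], hp["weighted"])


def fit_subspace_ensemble(X, y, n_learners: int = 30,
                          subspace_dim: int | None = None,
                          base: str = "discriminant", seed: int = 0,
                          cost: CostMatrix | None = None,
                          knn_k: int = 10, metric: str = "euclidean",
                          feature_names=None) -> TrainedModel:
    """Random-subspace ensemble: each member sees a seeded random feature
    subset; the ensemble posterior is the mean of member posteriors."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    p = X.shape[1]
    if subspace_dim is None:
        subspace_dim = max(1, int(np.ceil(p / 2)))
    if subspace_dim > p:
        raise ValueError("subspace_dim must be <= n_features")
    if base not in ("discriminant", "knn"):
        raise ValueError(f"unknown base learner {base!r}")
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{i}" for i in range(p))
    mean, std = _fit_scaler(X)
    Xs = (X - mean) / std
    rng = np.random.default_rng(seed)
    members = []
    for _m in range(n_learners):
        cols = np.sort(rng.choice(p, size=subspace_dim, replace=False))
        if base == "discriminant":
            lda = LinearDiscriminantAnalysis(solver="svd")
            try:
                lda.fit(Xs[:, cols], y)
            except np.linalg.LinAlgError:
                # singular within-class covariance on this subset: ridge-regularize
                warnings.warn("singular covariance in subspace member; "
                              "refitting with shrinkage")
                lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
                lda.fit(Xs[:, cols], y)
            members.append({"cols": cols, "lda": lda})
        else:
            members.append({"cols": cols})
    model = TrainedModel("subspace_ensemble",
                         {"n_learners": n_learners, "subspace_dim": subspace_dim,
                          "base": base, "k": knn_k, "metric": metric,
                          "weighted": True, "seed": seed},
                         cost or CostMatrix(), names, mean, std)
    model.state = {"members": members, "train_X": Xs, "train_y": y.copy()}
    return model


def _ensemble_posteriors(model: TrainedModel, Xs: np.ndarray) -> np.ndarray:
    hp = model.hyperparameters
    post = np.zeros((Xs.shape[0], len(CLASSES)))
    for member in model.state["members"]:
        cols = member["cols"]
        if hp["base"] == "discriminant":
            proba = member["lda"].predict_proba(Xs[:, cols])
            # align LDA class order to CLASSES
            aligned = np.zeros_like(post)
            for j, cls in enumerate(member["lda"].classes_):
                aligned[:, CLASSES.index(cls)] = proba[:, j]
            post += aligned
        else:
            post += _knn_posteriors(model.state["train_X"][:, cols],
                                    model.state["train_y"], Xs[:, cols],
                                    hp["k"], hp["metric"], True)
    return post / len(model.state["members"])


def predict_proba(model: TrainedModel, X) -> np.ndarray:
    """Posterior estimates for any trained model kind."""
    if model.kind in ("fine_knn", "weighted_knn"):
        return knn_predict_proba(model, X)
    return _ensemble_posteriors(model, model.standardize(X))


def decide_with_cost(posteriors, cost: CostMatrix | None = None) -> list:
    """Label each posterior row by minimum expected cost.

    Expected cost of predicting normal is ``p(abnormal) * cost_fn``; of
    predicting abnormal, ``p(normal) * cost_fp``. Ties go to abnormal (the
    safe screening decision). With costs (10, 1) the abnormal threshold on
    p(abnormal) is 1/11.
    """
    cost = cost or CostMatrix()
    post = np.atleast_2d(np.asarray(posteriors, float))
    if np.any(post < 0):
        raise ValueError("posteriors must be non-negative")
    p_ab = post[:, CLASSES.index("abnormal")]
    p_no = post[:, CLASSES.index("normal")]
    labels = np.where(p_no * cost.cost_fp <= p_ab * cost.cost_fn,
                      "abnormal", "normal")
    return labels.tolist()


def predict(model: TrainedModel, X) -> list:
    """Cost-sensitive labels for raw (unstandardized) feature rows."""
    return decide_with_cost(predict_proba(model, X), model.cost)


def _make_model(X, y, spec: dict, seed: int, cost: CostMatrix,
                feature_names) -> TrainedModel:
    spec = dict(spec)
    kind = spec.pop("kind", "weighted_knn")
    if kind in ("fine_knn", "weighted_knn"):
        return fit_knn(X, y, kind=kind, cost=cost, feature_names=feature_names,
                       **spec)
    if kind == "subspace_ensemble":
        spec.setdefault("seed", seed)
        return fit_subspace_ensemble(X, y, cost=cost,
                                     feature_names=feature_names, **spec)
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class CVResult:
    pooled: MetricsReport
    fold_reports: list
    fold_matrices: list
    seed: int
    model_spec: dict


def cross_validate(X, y, model_spec: dict | None = None, n_folds: int = 5,
                   seed: int = 0, cost: CostMatrix | None = None,
                   feature_names=None) -> CVResult:
    """Stratified k-fold cross-validation with in-fold standardization.

    Per-fold confusion matrices are summed and metrics computed on the
    pooled matrix as well as per fold.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    cost = cost or CostMatrix()
    model_spec = model_spec or {"kind": "weighted_knn"}
    for cls in np.unique(y):
        if np.sum(y == cls) < n_folds:
            raise ValueError(
                f"class {cls!r} has fewer than {n_folds} members; use fewer folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_matrices = []
    fold_reports = []
    for tr, te in skf.split(X, y):
        model = _make_model(X[tr], y[tr], model_spec, seed, cost, feature_names)
        labels = predict(model, X[te])
        cm = confusion_from_labels(y[te].tolist(), labels)
        fold_matrices.append(cm)
        fold_reports.append(compute_metrics(cm))
    pooled = fold_matrices[0]
    for cm in fold_matrices[1:]:
        pooled = pooled + cm
    return CVResult(compute_metrics(pooled), fold_reports, fold_matrices,
                    seed, dict(model_spec, n_folds=n_folds))


def holdout_split(manifest: DatasetManifest, test_fraction: float = 0.2,
                  seed: int = 0):
    """Stratified train/test split of a manifest into two manifests."""
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    labels = manifest.labels()
    idx = np.arange(len(manifest))
    tr, te = train_test_split(idx, test_size=test_fraction, random_state=seed,
                              stratify=labels)
    train = DatasetManifest([manifest.entries[i] for i in sorted(tr)],
                            root=manifest.root)
    test = DatasetManifest([manifest.entries[i] for i in sorted(te)],
                           root=manifest.root)
    return train, test


def tune_hyperparameters(X, y, model_spec: dict | None = None,
                         grid: dict | None = None, seed: int = 0,
                         cost: CostMatrix | None = None, n_folds: int = 5):
    """Exhaustive grid search minimizing cross-validated expected cost.

    Default grid: distance metrics (euclidean, cityblock, chebyshev,
    cosine) x k in 1..30. Ties break toward smaller k, then metric order.
    Returns ``(best_params, loss_table)`` where the table has one row per
    grid point.
    """
    cost = cost or CostMatrix()
    model_spec = model_spec or {"kind": "weighted_knn"}
    grid = grid or {"metric": ["euclidean", "cityblock", "chebyshev", "cosine"],
                    "k": list(range(1, 31))}
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    kind = model_spec.get("kind", "weighted_knn")
    if kind not in ("fine_knn", "weighted_knn", "subspace_ensemble"):
        raise ValueError(f"grid search unsupported for model kind {kind!r}")
    table = []
    best = None
    for mi, metric in enumerate(grid.get("metric", ["euclidean"])):
        for k in grid.get("k", [10]):
            spec = dict(model_spec)
            if kind == "subspace_ensemble":
                spec.update(metric=metric, knn_k=k, base="knn")
            else:
                spec.update(metric=metric, k=k)
            res = cross_validate(X, y, spec, n_folds=n_folds, seed=seed, cost=cost)
            cm = res.pooled.confusion
            loss = (cm.fn * cost.cost_fn + cm.fp * cost.cost_fp) / cm.total
            row = {"metric": metric, "k": k, "expected_cost": loss,
                   "accuracy": res.pooled.accuracy}
            table.append(row)
            key = (loss, k, mi)
            if best is None or key < best[0]:
                best = (key, row)
    return dict(best[1]), table
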