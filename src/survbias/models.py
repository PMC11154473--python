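"""Uniform adapters over the five classifier families.

Families: gradient-boosted trees (XGBoost), random forest, logistic regression,
Gaussian naive Bayes, and a small 1-D convolutional network. Every family
satisfies the same fit / predict_scores contract so the evaluation harness can
treat them interchangeably. Default hyperparameters are the configurations the
ablation protocol selects as optimal for each family.

The convolutional path additionally supports minority oversampling (SMOTE) and
an epoch-level callback that snapshots the parameters maximizing the composite
score on a validation set.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import NearestNeighbors
from xgboost import XGBClassifier

from ._cnn import Conv1DNet
from .exceptions import ConfigurationError, UndefinedMetricError
from .metrics import CompositeWeights, auc, cohens_kappa, composite_score, confusion, basic_rates

__all__ = [
    "ModelSpec",
    "ModelHandle",
    "TrainRecord",
    "FAMILIES",
    "default_spec",
    "fit",
    "predict_scores",
    "oversample_minority",
    "fit_cnn_with_callback",
    "ablation_grid",
]

logger = logging.getLogger(__name__)

# Allowed hyperparameter names and the ablation-selected defaults, per family.
FAMILIES = {
    "xgboost": {
        "objective": "binary:logistic",
        "n_estimators": 50,
        "max_depth": 7,
        "learning_rate": 0.0001,
        "gamma": 0.0,
        "reg_alpha": 2.5,
        "colsample_bytree": 0.2,
    },
    "random_forest": {
        "class_weight": "balanced",
        "n_estimators": 1000,
        "max_depth": 12,
        "min_samples_split": 12,
        "min_samples_leaf": 10,
    },
    "logistic": {
        "max_iter": 100,
        "penalty": "l2",
        "C": 10.0,
        "fit_intercept": False,
        "class_weight": "balanced",
        "solver": "newton-cg",
    },
    "naive_bayes": {
        "var_smoothing": 1e-4,
    },
    "cnn1d": {
        "filters": 64,
        "kernel": 3,
        "pool": 2,
        "dropout": 0.5,
        "dense_units": 50,
        "conv_layers": 1,
        "batch_size": 16,
        "epochs": 100,
        "learning_rate": 1e-3,
    },
}


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown model family {self.family!r}")
        unknown = set(self.hyperparameters) - set(FAMILIES[self.family])
        if unknown:
            raise ConfigurationError(
                f"unknown hyperparameters for {self.family}: {sorted(unknown)}")
        if self.family == "cnn1d" and self.hyperparameters.get("conv_layers", 1) != 1:
            raise ConfigurationError("only a single convolutional layer is supported")

    def resolved(self) -> dict:
        params = dict(FAMILIES[self.family])
        params.update(self.hyperparameters)
        return params

    def with_seed(self, seed: int) -> "ModelSpec":
        return ModelSpec(self.family, dict(self.hyperparameters), seed)


@dataclass
class ModelHandle:
    model: object
    spec: ModelSpec
    fitted: bool = False
    best_composite: float | None = None
    scaler: tuple | None = None  # (mean, sd) for families trained on standardized inputs

    def n_estimators_fitted(self) -> int | None:
        est = getattr(self.model, "estimators_", None)
        return len(est) if est is not None else None


@dataclass
class TrainRecord:
    composite_scores: list = field(default_factory=list)
    losses: list = field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_composite(self) -> float:
        return max(self.composite_scores)


def default_spec(family: str, seed: int = 0) -> ModelSpec:
    """The ablation-selected configuration for the family."""
    if family not in FAMILIES:
        raise ConfigurationError(f"unknown model family {family!r}")
    return ModelSpec(family=family, hyperparameters=dict(FAMILIES[family]), seed=seed)


def _check_training_labels(y) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    return y


def _build_estimator(spec: ModelSpec):
    p = spec.resolved()
    if spec.family == "xgboost":
        return XGBClassifier(
            objective=p["objective"], n_estimators=p["n_estimators"], max_depth=p["max_depth"],
            learning_rate=p["learning_rate"], gamma=p["gamma"], reg_alpha=p["reg_alpha"],
            colsample_bytree=p["colsample_bytree"], random_state=spec.seed,
            n_jobs=1, verbosity=0, eval_metric="logloss",
        )
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=p["n_estimators"], max_depth=p["max_depth"],
            min_samples_split=p["min_samples_split"], min_samples_leaf=p["min_samples_leaf"],
            class_weight=p["class_weight"], random_state=spec.seed, n_jobs=1,
        )
    if spec.family == "logistic":
        # sklearn >= 1.8 spells the penalty through l1_ratio (0 = ridge, 1 = lasso)
        l1_ratio = {"l2": 0.0, "l1": 1.0}[p["penalty"]]
        return LogisticRegression(
            max_iter=p["max_iter"], l1_ratio=l1_ratio, C=p["C"],
            fit_intercept=p["fit_intercept"], class_weight=p["class_weight"], solver=p["solver"],
        )
    if spec.family == "naive_bayes":
        return GaussianNB(var_smoothing=p["var_smoothing"])
    raise ConfigurationError(spec.family)


def _standardizer(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def fit(spec: ModelSpec, X_train, Y_train) -> ModelHandle:
    """Fit any family on numeric, complete-case data; returns a uniform handle.

    The logistic family (no intercept per its configuration) and the network are
    trained on training-set-standardized inputs; tree and Bayes families on raw.
    """
    X = np.asarray(X_train, dtype=float)
    y = _check_training_labels(Y_train)
    if spec.family == "cnn1d":
        p = spec.resolved()
        net = Conv1DNet(
            n_features=X.shape[1], filters=p["filters"], kernel=p["kernel"], pool=p["pool"],
            dropout=p["dropout"], dense_units=p["dense_units"], batch_size=p["batch_size"],
            learning_rate=p["learning_rate"], seed=spec.seed,
        )
        net.set_normalization(X)
        for _ in range(p["epochs"]):
            net.train_epoch(X, y)
        return ModelHandle(model=net, spec=spec, fitted=True)
    est = _build_estimator(spec)
    scaler = None
    if spec.family == "logistic":
        scaler = _standardizer(X)
        X = (X - scaler[0]) / scaler[1]
    est.fit(X, y)
    return ModelHandle(model=est, spec=spec, fitted=True, scaler=scaler)


def predict_scores(handle: ModelHandle, X) -> np.ndarray:
    """Positive-class probabilities in [0,1]; hard labels are thresholded downstream."""
    if not handle.fitted:
        raise RuntimeError("predict called before fit")
    X = np.asarray(X, dtype=float)
    if handle.spec.family == "cnn1d":
        return handle.model.predict_proba(X)
    if handle.scaler is not None:
        X = (X - handle.scaler[0]) / handle.scaler[1]
    if X.shape[1] != handle.model.n_features_in_:
        raise ValueError("feature count differs from training data")
    return handle.model.predict_proba(X)[:, 1]


def oversample_minority(X_train, Y_train, seed: int, k_neighbors: int = 5):
    """SMOTE-style balancing: synthetic minority rows interpolated between a minority
    point and one of its k nearest minority neighbors, until class counts are equal.
    Original rows are returned unchanged (prepended, in input order)."""
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(Y_train).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("both classes must be present")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = int(np.argmin(counts))
    n_needed = int(abs(counts[0] - counts[1]))
    X_min = X[y == minority]
    k = k_neighbors
    if len(X_min) <= k:
        k = len(X_min) - 1
        logger.warning("minority class too small for k=%d; reduced to k=%d", k_neighbors, k)
    if k < 1:
        raise ValueError("minority class too small for SMOTE (needs >= 2 members)")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    neighbor_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]  # drop self
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(X_min), size=n_needed)
    pick = rng.integers(0, k, size=n_needed)
    gap = rng.random(n_needed)[:, None]
    neighbors = X_min[neighbor_idx[base, pick]]
    synthetic = X_min[base] + gap * (neighbors - X_min[base])
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_needed, minority)])
    return X_out, y_out


def _validation_composite(net: Conv1DNet, X_valid, y_valid, weights: CompositeWeights):
    p = net.predict_proba(X_valid)
    y_pred = (p > 0.5).astype(int)
    a = auc(y_valid, p)
    kappa = cohens_kappa(y_valid, y_pred)
    _, recall, *_ = basic_rates(confusion(y_valid, y_pred))
    return composite_score(a, kappa, recall, weights)


def fit_cnn_with_callback(spec: ModelSpec, X_train, Y_train, X_valid, Y_valid,
                          epochs: int | None = None,
                          weights: CompositeWeights = CompositeWeights()):
    """Train the network, computing the composite score on the validation set after
    every epoch; the returned handle carries the parameters of the best epoch.

    If the validation set contains a single class (composite undefined via AUC),
    selection falls back to minimum training loss with a warning.
    """
    if spec.family != "cnn1d":
        raise ConfigurationError("callback training applies to the cnn1d family only")
    p = spec.resolved()
    T = epochs if epochs is not None else p["epochs"]
    if T < 1:
        raise ValueError("epochs must be >= 1")
    X = np.asarray(X_train, dtype=float)
    y = _check_training_labels(Y_train)
    Xv = np.asarray(X_valid, dtype=float)
    yv = np.asarray(Y_valid).astype(int)
    single_class_valid = len(np.unique(yv)) < 2
    if single_class_valid:
        logger.warning("single-class validation set; falling back to loss-based selection")
    net = Conv1DNet(
        n_features=X.shape[1], filters=p["filters"], kernel=p["kernel"], pool=p["pool"],
        dropout=p["dropout"], dense_units=p["dense_units"], batch_size=p["batch_size"],
        learning_rate=p["learning_rate"], seed=spec.seed,
    )
    net.set_normalization(X)
    record = TrainRecord()
    best_weights = net.get_weights()
    best_score = -np.inf
    for t in range(T):
        loss = net.train_epoch(X, y)
        record.losses.append(loss)
        if single_class_valid:
            cs = -loss
        else:
            cs = _validation_composite(net, Xv, yv, weights)
        record.composite_scores.append(cs)
        if cs > best_score:
            best_score = cs
            best_weights = net.get_weights()
            record.best_epoch = t
    net.set_weights(best_weights)
    handle = ModelHandle(model=net, spec=spec, fitted=True, best_composite=float(best_score))
    return handle, record


def ablation_grid(family: str, grid: dict, table, outcome: str, plan,
                  weights: CompositeWeights = CompositeWeights(), seed: int = 0):
    """Cross-validated composite score over a (<= 2-parameter) Cartesian grid.

    Returns (best_spec, surface) where surface is an ndarray shaped by the value
    lists in grid order; ties break toward the earliest grid point.
    """
    from .pipeline import run_cv  # local import: pipeline depends on this module

    if not grid:
        raise ConfigurationError("empty ablation grid")
    if len(grid) > 2:
        raise ConfigurationError("at most two parameters may be varied at a time")
    names = list(grid)
    value_lists = [list(grid[k]) for k in names]
    shape = tuple(len(v) for v in value_lists)
    surface = np.full(shape, np.nan)
    best = None
    for idx in itertools.product(*(range(s) for s in shape)):
        hp = dict(FAMILIES[family])
        for name, i in zip(names, idx):
            hp[name] = value_lists[names.index(name)][i]
        spec = ModelSpec(family=family, hyperparameters=hp, seed=seed)
        _, aggregate, _ = run_cv(spec, table, outcome, plan, weights)
        score = aggregate["composite"]["mean"]
        surface[idx] = score
        if best is None or score > best[0]:
            best = (score, spec)
    return best[1], surface
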