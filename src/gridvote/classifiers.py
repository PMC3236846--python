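"""The grid's two base learners: K-nearest neighbors and Gaussian Naive Bayes.

KNN is lazy (the fitted model stores the restricted training matrix) and
votes among the ``k`` Euclidean-nearest training samples; neighbor order
is made deterministic by sorting on ``(distance, training sample id)``,
which matters when oversampling has duplicated rows.  Naive Bayes stores
per-class feature means, (floored) variances and training-frequency
priors, and predicts by the larger ``log prior + sum log N(x; mean, var)``.
"""
from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy.spatial.distance import cdist

from .core_io import ExpressionDataset, DatasetError, POSITIVE, NEGATIVE
from .feature_select import FS_METHODS

CLF_KNN = "KNN"
CLF_NB = "NB"

# relative variance floor guarding against zero-variance features created
# by duplicated (oversampled) rows
_NB_VAR_FLOOR_REL = 1e-9
_NB_VAR_FLOOR_ABS = 1e-12


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """One grid point: ranking method, feature count, learner (+ K)."""

    endpoint_code: str
    fs_method: str
    n_features: int
    classifier: str
    k: int | None = None

    def __post_init__(self):
        if self.fs_method not in FS_METHODS:
            raise ValueError(f"unknown fs_method {self.fs_method!r}")
        if self.classifier not in (CLF_KNN, CLF_NB):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if (self.k is not None) != (self.classifier == CLF_KNN):
            raise ValueError("k must be present iff classifier is KNN")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")

    @property
    def config_id(self) -> str:
        tail = f"k{self.k:02d}" if self.classifier == CLF_KNN else "nb"
        return (f"{self.endpoint_code}|{self.fs_method}|"
                f"f{self.n_features:04d}|{self.classifier}|{tail}")


@dataclasses.dataclass
class FittedModel:
    """Frozen model: config, its feature list and learner parameters.

    ``capped`` flags configs whose requested feature count exceeded the
    surviving ranking, in which case ``selected_features`` is shorter
    than ``config.n_features``.
    """

    config: ModelConfig
    selected_features: list
    params: dict
    capped: bool = False

    def to_json(self) -> str:
        """Serialize for the frozen-model audit trail.

        NB models serialize in full; KNN (lazy) serializes its config,
        features and a reference to the stored training data shape.
        """
        payload = {
            "config": dataclasses.asdict(self.config),
            "selected_features": list(self.selected_features),
            "capped": self.capped,
        }
        if self.config.classifier == CLF_NB:
            payload["params"] = {
                "mean_pos": self.params["mean_pos"].tolist(),
                "mean_neg": self.params["mean_neg"].tolist(),
                "var_pos": self.params["var_pos"].tolist(),
                "var_neg": self.params["var_neg"].tolist(),
                "log_prior_pos": self.params["log_prior_pos"],
                "log_prior_neg": self.params["log_prior_neg"],
            }
        else:
            payload["params"] = {
                "n_train": int(self.params["X"].shape[0]),
                "train_ids": list(self.params["ids"]),
            }
        return json.dumps(payload, sort_keys=True)


# ---------------------------------------------------------------------------
# Array-level cores (shared with the cross-validation grid runner)
# ---------------------------------------------------------------------------


def knn_neighbor_order(X_train: np.ndarray, train_ids, X_eval: np.ndarray) -> np.ndarray:
    """Per eval row, training indices sorted by (distance, sample id)."""
    d2 = cdist(np.atleast_2d(X_eval), np.atleast_2d(X_train), "sqeuclidean")
    return neighbor_order_from_d2(d2, train_ids)


def neighbor_order_from_d2(d2: np.ndarray, train_ids) -> np.ndarray:
    id_rank = np.argsort(np.argsort(np.asarray([str(i) for i in train_ids])))
    tie = np.broadcast_to(id_rank, d2.shape)
    return np.lexsort((tie, d2), axis=1)


def knn_votes(order: np.ndarray, y_train: np.ndarray, k: int) -> np.ndarray:
    """Boolean predictions from a precomputed neighbor order."""
    k_eff = min(k, order.shape[1])
    votes = np.asarray(y_train, dtype=bool)[order[:, :k_eff]].sum(axis=1)
    return votes * 2 > k_eff


def nb_fit_arrays(X: np.ndarray, y: np.ndarray) -> dict:
    y = np.asarray(y, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DatasetError("Naive Bayes requires both classes in training data")
    pos, neg = X[y], X[~y]
    var_pos = pos.var(axis=0)
    var_neg = neg.var(axis=0)
    overall_var = float(X.var(axis=0).mean())
    floor = max(_NB_VAR_FLOOR_REL * overall_var, _NB_VAR_FLOOR_ABS)
    return {
        "mean_pos": pos.mean(axis=0),
        "mean_neg": neg.mean(axis=0),
        "var_pos": np.maximum(var_pos, floor),
        "var_neg": np.maximum(var_neg, floor),
        "log_prior_pos": float(np.log(n_pos / y.size)),
        "log_prior_neg": float(np.log(n_neg / y.size)),
    }


def nb_predict_arrays(params: dict, X: np.ndarray) -> np.ndarray:
    def class_ll(mean, var, log_prior):
        return log_prior - 0.5 * (
            np.log(2 * np.pi * var) + (X - mean) ** 2 / var
        ).sum(axis=1)

    ll_pos = class_ll(params["mean_pos"], params["var_pos"], params["log_prior_pos"])
    ll_neg = class_ll(params["mean_neg"], params["var_neg"], params["log_prior_neg"])
    return ll_pos > ll_neg  # tie -> negative (deterministic)


# ---------------------------------------------------------------------------
# Dataset-level fit/predict
# ---------------------------------------------------------------------------


def fit(config: ModelConfig, train: ExpressionDataset,
        selected_features) -> FittedModel:
    """Freeze one grid config on (already preprocessed) training data."""
    selected_features = [str(f) for f in selected_features]
    index = train.feature_index()
    missing = [f for f in selected_features if f not in index]
    if missing:
        raise DatasetError(f"training data lacks features: {missing[:5]}")
    cols = np.asarray([index[f] for f in selected_features], dtype=int)
    X = train.values[:, cols]
    capped = len(selected_features) < config.n_features
    if config.classifier == CLF_KNN:
        params = {"X": X.copy(), "y": train.y.copy(),
                  "ids": list(train.sample_ids)}
    else:
        params = nb_fit_arrays(X, train.y)
    return FittedModel(config, selected_features, params, capped=capped)


def predict(model: FittedModel, samples: ExpressionDataset) -> np.ndarray:
    """Deterministic per-sample labels ('P'/'N') for new samples."""
    index = samples.feature_index()
    missing = [f for f in model.selected_features if f not in index]
    if missing:
        raise DatasetError(f"samples lack features: {missing[:5]}")
    cols = np.asarray([index[f] for f in model.selected_features], dtype=int)
    X = samples.values[:, cols]
    if model.config.classifier == CLF_KNN:
        order = knn_neighbor_order(model.params["X"], model.params["ids"], X)
        pred = knn_votes(order, model.params["y"], model.config.k)
    else:
        pred = nb_predict_arrays(model.params, X)
    return np.where(pred, POSITIVE, NEGATIVE)
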