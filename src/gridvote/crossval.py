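"""Model-grid enumeration and complete repeated cross-validation.

*Complete* cross-validation re-runs the entire modeling process — batch
centering, minority oversampling, feature ranking, classifier fitting —
inside every training fold, so no information from a held-out fold (or
from the external validation set) can influence any modeling step.  With
the defaults this is 5-fold CV repeated 10 times: 50 CV runs per grid
config, whose metric averages drive both model nomination and ensemble
retention.

Feature rankings are computed once per (fold, method) and shared across
all feature-set sizes and learners of that fold (the feature sets are
nested prefixes of the ranking), and KNN distance matrices grow
incrementally over the prefix blocks; results are identical to naive
per-config recomputation.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import cdist

from .core_io import ExpressionDataset, DatasetError, RunConfig, endpoint_hash
from .preprocess import BatchCenterer, oversample_indices
from .feature_select import FS_FC_P, FS_SAM, grid_sizes, rank_indices
from .classifiers import (
    CLF_KNN,
    CLF_NB,
    ModelConfig,
    knn_votes,
    nb_fit_arrays,
    nb_predict_arrays,
    neighbor_order_from_d2,
)
from .metrics import ConfusionCounts, accuracy_sens_spec, mcc

STATUS_OK = "ok"
STATUS_SKIPPED = "skipped"


@dataclasses.dataclass
class CVPerformance:
    """Per-config averages over the complete-CV runs.

    ``oof_positive_rate`` is the fraction of training samples predicted
    positive, pooled over all out-of-fold predictions (each sample is
    predicted exactly once per repeat); it later calibrates the ensemble
    vote threshold.
    """

    config: ModelConfig
    mean_mcc: float = float("nan")
    mean_accuracy: float = float("nan")
    mean_sensitivity: float = float("nan")
    mean_specificity: float = float("nan")
    n_runs: int = 0
    oof_positive_rate: float = float("nan")
    status: str = STATUS_OK
    capped: bool = False

    @property
    def config_id(self) -> str:
        return self.config.config_id


def enumerate_grid(run_cfg: RunConfig, endpoint_codes) -> list:
    """All grid configs: endpoint x method x feature size x (KNN ks + NB)."""
    configs = []
    for code in endpoint_codes:
        for method in (FS_FC_P, FS_SAM):
            for size in run_cfg.feature_sizes:
                for k in run_cfg.knn_k_grid:
                    configs.append(ModelConfig(code, method, size, CLF_KNN, k))
                configs.append(ModelConfig(code, method, size, CLF_NB))
    return configs


def stratified_folds(y: np.ndarray, n_folds: int,
                     rng: np.random.Generator) -> list:
    """Class-stratified fold index arrays (shuffled deal, sizes within 1)."""
    y = np.asarray(y, dtype=bool)
    folds = [[] for _ in range(n_folds)]
    pointer = 0
    for cls in (True, False):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(idx.size)]
        for i in idx:
            folds[pointer % n_folds].append(int(i))
            pointer += 1
    return [np.asarray(sorted(f), dtype=int) for f in folds]


def grid_eval(X_fit: np.ndarray, y_fit: np.ndarray, ids_fit,
              X_eval: np.ndarray, rankings: dict, sizes, ks,
              want_nb: bool) -> dict:
    """Predictions of every (method, size, learner) on ``X_eval``.

    ``rankings`` maps method -> ranked feature column indices (computed on
    the fit data).  Returns ``{(method, size, clf, k): (bool preds,
    capped)}``; entries for sizes with an empty ranking are absent.
    Feature sets are nested ranking prefixes, so squared distances are
    accumulated block-by-block.
    """
    out = {}
    ks = sorted(ks)
    sizes = sorted(set(sizes))
    id_rank = None
    for method, rank in rankings.items():
        rank = np.asarray(rank, dtype=int)
        if rank.size == 0:
            continue
        eff_of = {s: min(s, rank.size) for s in sizes}
        eff_sizes = sorted(set(eff_of.values()))
        cols = rank[: eff_sizes[-1]]
        A, B = X_fit[:, cols], X_eval[:, cols]
        preds = {}
        d2 = np.zeros((X_eval.shape[0], X_fit.shape[0]))
        prev = 0
        for es in eff_sizes:
            entry = {}
            if ks:
                d2 += cdist(B[:, prev:es], A[:, prev:es], "sqeuclidean")
                order = neighbor_order_from_d2(d2, ids_fit)
                for k in ks:
                    entry[(CLF_KNN, k)] = knn_votes(order, y_fit, k)
            prev = es
            if want_nb:
                params = nb_fit_arrays(A[:, :es], y_fit)
                entry[(CLF_NB, None)] = nb_predict_arrays(params, B[:, :es])
            preds[es] = entry
        for s in sizes:
            es = eff_of[s]
            for (clf, k), pred in preds[es].items():
                out[(method, s, clf, k)] = (pred, es < s)
    return out


def _fold_seed(run_cfg: RunConfig, code: str, *extra) -> list:
    return [run_cfg.seed, endpoint_hash(code), *extra]


def prepare_fold(X: np.ndarray, y: np.ndarray, ids, batches,
                 train_idx: np.ndarray, run_cfg: RunConfig,
                 os_seed) -> tuple:
    """Batch-center and rebalance one training fold; returns the fitted
    centerer plus the (possibly oversampled) fold arrays."""
    centerer = BatchCenterer().fit(X[train_idx], [batches[i] for i in train_idx])
    X_tr = centerer.transform(X[train_idx], [batches[i] for i in train_idx])
    y_tr = y[train_idx]
    ids_tr = [ids[i] for i in train_idx]
    rng = np.random.default_rng(os_seed)
    extra = oversample_indices(y_tr, run_cfg.imbalance_threshold, rng)
    if extra.size:
        counts = {}
        dup_ids = []
        for i in extra:
            counts[i] = counts.get(i, 0) + 1
            dup_ids.append(f"{ids_tr[i]}~dup{counts[i]}")
        X_tr = np.vstack([X_tr, X_tr[extra]])
        y_tr = np.concatenate([y_tr, y_tr[extra]])
        ids_tr = ids_tr + dup_ids
    return centerer, X_tr, y_tr, ids_tr


def run_grid(train: ExpressionDataset, configs, run_cfg: RunConfig) -> list:
    """Complete repeated CV of every config on one endpoint's training set.

    Returns one :class:`CVPerformance` per config, in input order; a
    config that never obtained a usable feature ranking is returned with
    status ``"skipped"`` rather than silently dropped.  Deterministic
    given ``run_cfg.seed`` and invariant to the input sample order.
    """
    configs = list(configs)
    if not configs:
        return []
    codes = {c.endpoint_code for c in configs}
    if len(codes) > 1:
        raise ValueError(f"configs span multiple endpoints: {sorted(codes)}")
    if train.labels is None:
        raise DatasetError("complete CV requires a labeled training set")
    if train.batches is None:
        raise DatasetError("complete CV requires batch labels")
    code = configs[0].endpoint_code

    # canonical sample order (by id) so results do not depend on row order
    canon = np.argsort(np.asarray(train.sample_ids))
    X = train.values[canon]
    y = train.y[canon]
    ids = [train.sample_ids[i] for i in canon]
    batches = [train.batches[i] for i in canon]
    n = X.shape[0]
    n_min = int(min(y.sum(), (~y).sum()))
    if n_min < run_cfg.cv_folds:
        raise DatasetError(
            f"minority class ({n_min}) smaller than fold count "
            f"({run_cfg.cv_folds}); cannot stratify"
        )

    methods = sorted({c.fs_method for c in configs})
    sizes = sorted({c.n_features for c in configs})
    ks = sorted({c.k for c in configs if c.classifier == CLF_KNN})
    want_nb = any(c.classifier == CLF_NB for c in configs)
    feat_ids = np.asarray(train.feature_ids)

    acc = {
        c.config_id: {"sums": np.zeros(4), "n": 0, "oof_pos": 0,
                      "oof_tot": 0, "capped": False}
        for c in configs
    }

    for rep in range(run_cfg.cv_repeats):
        rng = np.random.default_rng(_fold_seed(run_cfg, code, rep))
        folds = stratified_folds(y, run_cfg.cv_folds, rng)
        for fi, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            centerer, X_tr, y_tr, ids_tr = prepare_fold(
                X, y, ids, batches, train_idx, run_cfg,
                _fold_seed(run_cfg, code, rep, fi, 97))
            # held-out fold transformed with the fold-fit batch centering
            X_te = centerer.transform(X[test_idx],
                                      [batches[i] for i in test_idx])
            rankings = {
                m: rank_indices(m, X_tr, y_tr, feat_ids, run_cfg.p_cutoff)
                for m in methods
            }
            preds = grid_eval(X_tr, y_tr, ids_tr, X_te, rankings, sizes, ks,
                              want_nb)
            y_te = y[test_idx]
            for c in configs:
                got = preds.get((c.fs_method, c.n_features, c.classifier, c.k))
                if got is None:
                    continue
                pred, capped = got
                counts = ConfusionCounts.from_labels(y_te, pred)
                a = acc[c.config_id]
                a["sums"][0] += mcc(counts)
                a["sums"][1:] += accuracy_sens_spec(counts)
                a["n"] += 1
                a["oof_pos"] += int(pred.sum())
                a["oof_tot"] += int(pred.size)
                a["capped"] |= capped

    out = []
    for c in configs:
        a = acc[c.config_id]
        if a["n"] == 0:
            out.append(CVPerformance(config=c, status=STATUS_SKIPPED))
            continue
        means = a["sums"] / a["n"]
        out.append(CVPerformance(
            config=c,
            mean_mcc=float(means[0]),
            mean_accuracy=float(means[1]),
            mean_sensitivity=float(means[2]),
            mean_specificity=float(means[3]),
            n_runs=int(a["n"]),
            oof_positive_rate=a["oof_pos"] / a["oof_tot"],
            capped=bool(a["capped"]),
        ))
    return out


def complete_cv(train: ExpressionDataset, config: ModelConfig,
                run_cfg: RunConfig) -> CVPerformance:
    """Complete repeated CV of a single config (see :func:`run_grid`)."""
    return run_grid(train, [config], run_cfg)[0]


def prepare_fold_sizes(run_cfg: RunConfig, n_available: int) -> list:
    """Feature-set sizes the grid realizes given surviving features."""
    return grid_sizes(n_available, run_cfg.feature_step, run_cfg.feature_max)
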