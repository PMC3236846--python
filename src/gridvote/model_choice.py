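"""The two rival deciders built on the cross-validated grid.

**Nomination** picks a single config by a hierarchical decision tree:
(1) group models by CV MCC rounded to one decimal and keep the top
group; (2) within the group prefer parsimony — keep the smallest feature
count, and among models with nearly the same number of features (within
one grid step) prefer higher accuracy, then sensitivity, then
specificity; (3) prefer the SAM ranking over FC+p; (4) prefer KNN over
Naive Bayes; residual ties fall to smaller K, then config id.

**The calibrated-vote ensemble** retains the top fraction (default 50%)
of configs by CV MCC, refits each on the fully processed training set,
and records p-bar, the mean of the retained models' training
positive-prediction rates (taken as their pooled out-of-fold rates from
complete CV).  A new sample is called positive when the fraction of
retained models voting positive, divided by p-bar, is >= 1.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np

from .core_io import (
    ExpressionDataset,
    POSITIVE,
    NEGATIVE,
    RunConfig,
    endpoint_hash,
)
from .preprocess import BatchCenterer, balance_by_oversampling, center_mean_shift
from .feature_select import FS_FC_P, FS_SAM, rank_fc_p, rank_sam
from .classifiers import CLF_KNN, FittedModel, ModelConfig, fit, predict
from .crossval import STATUS_OK, CVPerformance


class EnsembleDegenerateError(RuntimeError):
    """p-bar hit 0 or 1: every retained model predicts one class on the
    training data.  Inspect the endpoint (control endpoints and broken
    inputs are the usual causes); the vote ratio is undefined."""


def mcc_group(value: float) -> float:
    """One-decimal MCC group key (round half away from zero).

    Models whose CV MCCs agree to one decimal (0.89 and 0.91 both map to
    0.9) are treated as performing equally in Step 1 of the nomination
    tree.
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"MCC {value} outside [-1, 1]")
    sign = 1.0 if value >= 0 else -1.0
    scaled = round(abs(value) * 10.0, 6)  # shield binary representation
    return sign * math.floor(scaled + 0.5) / 10.0


def _ok(perfs) -> list:
    return [p for p in perfs if p.status == STATUS_OK]


def select_nominated(perfs, feature_step: int = 5) -> ModelConfig:
    """Apply the four-step nomination decision tree; exactly one config."""
    ok = _ok(perfs)
    if not ok:
        raise ValueError("no usable performance records")
    # Step 1: highest one-decimal MCC group
    keys = [round(mcc_group(p.mean_mcc) * 10) for p in ok]
    best = max(keys)
    group = [p for p, k in zip(ok, keys) if k == best]
    # Step 2: parsimony, then accuracy/sensitivity/specificity among
    # models with nearly the same feature count (within one grid step)
    min_n = min(p.config.n_features for p in group)
    near = [p for p in group if p.config.n_features <= min_n + feature_step]
    # Steps 3-4 and residual ties: SAM over FC+p, KNN over NB, smaller K
    chosen = min(near, key=lambda p: (
        -p.mean_accuracy,
        -p.mean_sensitivity,
        -p.mean_specificity,
        p.config.fs_method != FS_SAM,
        p.config.classifier != CLF_KNN,
        p.config.k if p.config.k is not None else 0,
        p.config.config_id,
    ))
    return chosen.config


def select_retained(perfs, fraction: float) -> list:
    """Top ``ceil(fraction * n)`` records by mean CV MCC, cut-point ties
    included; sorted best-first."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    ok = sorted(_ok(perfs), key=lambda p: (-p.mean_mcc, p.config.config_id))
    if len(ok) < 2:
        raise ValueError("need >= 2 usable performance records")
    n_keep = math.ceil(fraction * len(ok))
    cut = ok[n_keep - 1].mean_mcc
    return [p for p in ok if p.mean_mcc >= cut]


@dataclasses.dataclass
class ProcessedTraining:
    """Fully processed training set plus artifacts needed for prediction.

    ``dataset`` is the batch-centered, rebalanced training set;
    ``centerer`` can transform new samples from batches seen in training
    (unseen batches pass through); ``rankings`` maps each method to its
    full feature-id ranking on the processed data.
    """

    dataset: ExpressionDataset
    centerer: BatchCenterer
    rankings: dict


def process_training(train: ExpressionDataset,
                     run_cfg: RunConfig) -> ProcessedTraining:
    """Final-model preprocessing: center, rebalance, rank (full set)."""
    centered = center_mean_shift(train)
    centerer = BatchCenterer().fit(train.values, train.batches)
    balanced = balance_by_oversampling(
        centered, run_cfg.imbalance_threshold,
        seed=[run_cfg.seed, endpoint_hash(train.endpoint_code), 999983])
    rankings = {
        FS_FC_P: rank_fc_p(balanced, run_cfg.p_cutoff),
        FS_SAM: rank_sam(balanced),
    }
    return ProcessedTraining(balanced, centerer, rankings)


def final_fit(config: ModelConfig, proc: ProcessedTraining) -> FittedModel:
    """Refit one config on the fully processed training set."""
    ranking = proc.rankings[config.fs_method]
    if not ranking:
        raise ValueError(
            f"{config.config_id}: empty feature ranking on full training set")
    return fit(config, proc.dataset, ranking[: config.n_features])


@dataclasses.dataclass
class RetainedModel:
    config: ModelConfig
    model: FittedModel
    training_positive_rate: float


@dataclasses.dataclass
class EnsembleModel:
    """Retained refit models, their training positive rates and p-bar."""

    retained: list
    p_bar: float
    fraction: float

    @property
    def config_ids(self) -> list:
        return [r.config.config_id for r in self.retained]


def build_ensemble(perfs, train: ExpressionDataset, run_cfg: RunConfig,
                   fraction: float | None = None,
                   proc: ProcessedTraining | None = None) -> EnsembleModel:
    """Retain the top CV fraction, refit on processed training data.

    ``proc`` (optional) reuses an existing :func:`process_training`
    result; callers evaluating many fractions or the whole grid pass it
    to avoid recomputation.
    """
    fraction = run_cfg.ensemble_fraction if fraction is None else fraction
    kept = select_retained(perfs, fraction)
    if proc is None:
        proc = process_training(train, run_cfg)
    retained = [
        RetainedModel(p.config, final_fit(p.config, proc),
                      p.oof_positive_rate)
        for p in kept
    ]
    p_bar = float(np.mean([r.training_positive_rate for r in retained]))
    if not 0.0 < p_bar < 1.0:
        raise EnsembleDegenerateError(
            f"p-bar = {p_bar}: calibrated vote ratio undefined")
    return EnsembleModel(retained=retained, p_bar=p_bar, fraction=fraction)


def vote_labels(vote_fractions: np.ndarray, p_bar: float) -> np.ndarray:
    """Boolean labels from per-sample positive-vote fractions: positive
    iff ``v / p_bar >= 1``."""
    return np.asarray(vote_fractions, dtype=float) >= p_bar


def predict_ensemble(ens: EnsembleModel,
                     samples: ExpressionDataset) -> np.ndarray:
    """Per-sample 'P'/'N' labels by the calibrated vote rule."""
    votes = np.vstack([
        predict(r.model, samples) == POSITIVE for r in ens.retained
    ])
    v = votes.mean(axis=0)
    return np.where(vote_labels(v, ens.p_bar), POSITIVE, NEGATIVE)
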