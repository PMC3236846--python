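"""Batch-effect correction and class rebalancing.

Two operations open the modeling protocol:

* **center mean shift** — per feature, each batch's values are shifted so
  that all within-batch means coincide with the overall feature mean
  (``x - mean(feature, batch) + mean(feature)``);
* **minority oversampling** — when the majority/minority class ratio is
  *strictly* greater than a threshold (default 4), minority samples are
  duplicated uniformly at random with replacement until the classes are
  even.

Inside cross-validation both are fit on the training fold only; the
fitted centerer can *transform* held-out samples whose batch was seen in
the fold (unseen batches pass through unchanged, keeping external
validation blinded and untouched).
"""
from __future__ import annotations

import numpy as np

from .core_io import ExpressionDataset, DatasetError


class BatchCenterer:
    """Fit per-(batch, feature) mean shifts on training data; transform any."""

    def __init__(self):
        self.batch_means_ = None
        self.grand_mean_ = None

    def fit(self, values: np.ndarray, batches) -> "BatchCenterer":
        values = np.asarray(values, dtype=float)
        batches = np.asarray([str(b) for b in batches])
        if values.shape[0] != batches.shape[0]:
            raise DatasetError("values/batches length mismatch")
        self.grand_mean_ = values.mean(axis=0)
        self.batch_means_ = {}
        for b in np.unique(batches):
            mask = batches == b
            if not mask.any():  # pragma: no cover - unique() guarantees
                raise DatasetError(f"batch {b!r} has zero samples")
            self.batch_means_[b] = values[mask].mean(axis=0)
        return self

    def transform(self, values: np.ndarray, batches) -> np.ndarray:
        if self.batch_means_ is None:
            raise RuntimeError("BatchCenterer not fitted")
        values = np.asarray(values, dtype=float)
        out = values.copy()
        batches = np.asarray([str(b) for b in batches])
        for b, mean_b in self.batch_means_.items():
            mask = batches == b
            if mask.any():
                out[mask] += self.grand_mean_ - mean_b
        return out


def center_mean_shift(ds: ExpressionDataset) -> ExpressionDataset:
    """Equalize within-batch feature means across batches.

    Overall feature means are unchanged; with a single batch (or batches
    with identical per-feature means) the dataset is returned value-equal.
    """
    if ds.batches is None:
        raise DatasetError("center_mean_shift requires batch labels")
    centerer = BatchCenterer().fit(ds.values, ds.batches)
    corrected = centerer.transform(ds.values, ds.batches)
    return ExpressionDataset(
        sample_ids=list(ds.sample_ids),
        feature_ids=list(ds.feature_ids),
        values=corrected,
        labels=None if ds.labels is None else ds.labels.copy(),
        batches=list(ds.batches),
        endpoint_code=ds.endpoint_code,
        role=ds.role,
    )


def oversample_indices(y: np.ndarray, threshold: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Indices of minority rows to duplicate; empty when not triggered.

    Triggers only when majority/minority count ratio is strictly greater
    than ``threshold``; duplicates are drawn uniformly with replacement
    until the class counts are exactly equal.
    """
    y = np.asarray(y, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DatasetError("cannot rebalance: a class has zero samples")
    n_min, n_maj = min(n_pos, n_neg), max(n_pos, n_neg)
    if n_maj / n_min <= threshold:
        return np.empty(0, dtype=int)
    minority = np.flatnonzero(y if n_pos < n_neg else ~y)
    return rng.choice(minority, size=n_maj - n_min, replace=True)


def balance_by_oversampling(ds: ExpressionDataset, threshold: float = 4.0,
                            seed: int = 0) -> ExpressionDataset:
    """Even out skewed classes by duplicating minority samples.

    Original samples are never altered or dropped; duplicated rows get
    ``~dupN``-suffixed sample ids.  Datasets at or below the threshold
    ratio are returned unchanged.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, list, tuple)) else seed
    extra = oversample_indices(ds.y, threshold, rng)
    if extra.size == 0:
        return ds
    new_ids = list(ds.sample_ids)
    counts = {}
    for i in extra:
        counts[i] = counts.get(i, 0) + 1
        new_ids.append(f"{ds.sample_ids[i]}~dup{counts[i]}")
    return ExpressionDataset(
        sample_ids=new_ids,
        feature_ids=list(ds.feature_ids),
        values=np.vstack([ds.values, ds.values[extra]]),
        labels=np.concatenate([ds.labels, ds.labels[extra]]),
        batches=None if ds.batches is None
        else list(ds.batches) + [ds.batches[i] for i in extra],
        endpoint_code=ds.endpoint_code,
        role=ds.role,
    )
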