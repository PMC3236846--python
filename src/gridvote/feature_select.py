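"""Feature ranking statistics and the incremental feature-set grid.

Two ranking methods feed the model grid:

* **FC+p** — rank by absolute fold change (difference of class means on
  the log2 scale), after excluding every feature whose two-sided pooled
  t-test p-value fails ``p < p_cutoff``;
* **SAM relative difference** — rank by ``|d|`` where
  ``d = (mean_pos - mean_neg) / (s_i + s0)``, ``s_i`` the pooled
  standard-error term ``s_p * sqrt(1/n1 + 1/n2)`` and ``s0`` an
  exchangeability constant stabilizing low-variance features (default:
  the median of ``s_i`` over features).  No p filter is applied.

The grid then takes nested prefixes of the ranking: the top ``step``
features, then ``2*step``, ... up to ``max_n`` (capped at the number of
surviving features when fewer remain).
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .core_io import ExpressionDataset, DatasetError

FS_FC_P = "FC_P"
FS_SAM = "SAM"
FS_METHODS = (FS_FC_P, FS_SAM)


@dataclasses.dataclass
class FeatureScores:
    """Per-feature statistics used by both ranking methods."""

    feature_ids: np.ndarray
    fold_change: np.ndarray  # mean_pos - mean_neg on the log2 scale
    t_stat: np.ndarray
    p_value: np.ndarray
    sam_d: np.ndarray
    s_i: np.ndarray
    s0: float


def score_features(values: np.ndarray, y: np.ndarray,
                   feature_ids=None, s0: float | None = None) -> FeatureScores:
    """Fold change, pooled t statistic/p-value and SAM d per feature.

    ``y`` is boolean (True = positive).  ``s0=None`` uses the median of
    the per-feature pooled scatter ``s_i``.  Requires >= 2 samples per
    class; p-values that are undefined (zero pooled variance and zero
    mean difference) are reported as 1.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(y, dtype=bool)
    n1, n2 = int(y.sum()), int((~y).sum())
    if n1 < 2 or n2 < 2:
        raise DatasetError("need at least 2 samples per class to score features")
    pos, neg = values[y], values[~y]
    m1, m2 = pos.mean(axis=0), neg.mean(axis=0)
    fc = m1 - m2
    ss1 = ((pos - m1) ** 2).sum(axis=0)
    ss2 = ((neg - m2) ** 2).sum(axis=0)
    df = n1 + n2 - 2
    sp2 = (ss1 + ss2) / df
    s_i = np.sqrt((1.0 / n1 + 1.0 / n2) * sp2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / s_i
    # zero pooled scatter: t is +/-inf for a real mean gap, 0 for none
    zero_scatter = np.where(fc > 0, np.inf, np.where(fc < 0, -np.inf, 0.0))
    t = np.where(s_i > 0, t, zero_scatter)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(t), p, 0.0)
    p = np.nan_to_num(p, nan=1.0)
    s0_val = float(np.median(s_i)) if s0 is None else float(s0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = fc / (s_i + s0_val)
    d = np.nan_to_num(d, nan=0.0, posinf=np.inf, neginf=-np.inf)
    if feature_ids is None:
        feature_ids = np.arange(values.shape[1]).astype(str)
    return FeatureScores(np.asarray(feature_ids), fc, t, p, d, s_i, s0_val)


def _rank_indices_fc_p(scores: FeatureScores, p_cutoff: float) -> np.ndarray:
    keep = np.flatnonzero(scores.p_value < p_cutoff)
    if keep.size == 0:
        return keep
    # primary |FC| desc; ties by smaller p, then feature id
    order = np.lexsort((
        scores.feature_ids[keep],
        scores.p_value[keep],
        -np.abs(scores.fold_change[keep]),
    ))
    return keep[order]


def _rank_indices_sam(scores: FeatureScores) -> np.ndarray:
    order = np.lexsort((scores.feature_ids, -np.abs(scores.sam_d)))
    return np.asarray(order)


def rank_indices(method: str, values: np.ndarray, y: np.ndarray,
                 feature_ids, p_cutoff: float) -> np.ndarray:
    """Ranked feature *column indices* for the given method."""
    scores = score_features(values, y, feature_ids)
    if method == FS_FC_P:
        return _rank_indices_fc_p(scores, p_cutoff)
    if method == FS_SAM:
        return _rank_indices_sam(scores)
    raise ValueError(f"unknown feature-selection method {method!r}")


def rank_fc_p(train: ExpressionDataset, p_cutoff: float = 0.05) -> list:
    """Feature ids passing ``p < p_cutoff``, sorted by |fold change| desc."""
    idx = rank_indices(FS_FC_P, train.values, train.y, train.feature_ids, p_cutoff)
    return [train.feature_ids[i] for i in idx]


def rank_sam(train: ExpressionDataset) -> list:
    """All feature ids sorted by |SAM relative difference| descending."""
    idx = rank_indices(FS_SAM, train.values, train.y, train.feature_ids, 0.0)
    return [train.feature_ids[i] for i in idx]


def grid_sizes(n_available: int, step: int, max_n: int) -> list:
    """Feature-set sizes ``step, 2*step, ..., max_n`` capped at availability."""
    if step < 1 or max_n < step:
        raise ValueError("need step >= 1 and max_n >= step")
    top = min(max_n, n_available)
    sizes = list(range(step, top + 1, step))
    if 0 < n_available < max_n and (not sizes or sizes[-1] != n_available):
        sizes.append(n_available)
    return sizes


def feature_grid(ranked, step: int, max_n: int) -> list:
    """Nested prefix feature sets of the ranking (empty ranking -> [])."""
    ranked = list(ranked)
    return [ranked[:s] for s in grid_sizes(len(ranked), step, max_n)]
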