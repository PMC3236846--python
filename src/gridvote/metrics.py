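"""Performance metrics and comparison statistics.

The protocol's selection metric is the Matthews correlation coefficient
(MCC), the correlation-like summary of a binary confusion table; any
degenerate denominator factor (a row or column of the table empty) makes
the MCC 0 by convention, which matters because all-one-class folds do
occur at small sample sizes.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats


@dataclasses.dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=bool)
        y_pred = np.asarray(y_pred, dtype=bool)
        if y_true.shape != y_pred.shape:
            raise ValueError("label vectors differ in length")
        return cls(
            tp=int((y_true & y_pred).sum()),
            tn=int((~y_true & ~y_pred).sum()),
            fp=int((~y_true & y_pred).sum()),
            fn=int((y_true & ~y_pred).sum()),
        )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any margin is empty."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def accuracy_sens_spec(c: ConfusionCounts) -> tuple:
    """(accuracy, sensitivity, specificity); 0 on empty denominators."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    acc = (c.tp + c.tn) / c.total
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    return acc, sens, spec


@dataclasses.dataclass
class PairedTResult:
    t: float
    p: float
    n_used: int
    degenerate: bool = False


def paired_t_test(a, b, codes=None, exclude=(), one_sided: bool = False) -> PairedTResult:
    """Classic paired t-test on per-endpoint values aligned by position.

    ``codes`` (optional) names each position; endpoints listed in
    ``exclude`` (e.g. the random-label negative controls) are dropped
    before testing.  Zero variance of the differences is reported via the
    ``degenerate`` flag rather than a p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors differ in length")
    keep = np.ones(a.size, dtype=bool)
    if exclude:
        if codes is None:
            raise ValueError("exclude given without endpoint codes")
        codes = [str(c) for c in codes]
        keep = np.asarray([c not in set(exclude) for c in codes])
    a, b = a[keep], b[keep]
    n = a.size
    if n < 2:
        raise ValueError("need >= 2 paired values after exclusion")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return PairedTResult(t=float("nan"), p=float("nan"), n_used=n,
                             degenerate=True)
    res = stats.ttest_rel(a, b)
    p = float(res.pvalue) / 2 if one_sided else float(res.pvalue)
    return PairedTResult(t=float(res.statistic), p=p, n_used=n)


def pearson_r(x, y) -> float:
    """Product-moment correlation (length >= 3, nonzero variances)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def percentile_rank(value: float, population) -> float:
    """Mid-rank fraction of ``population`` at or below ``value``.

    Counts the fraction strictly below plus half of the ties, so a value
    equal to the unique maximum of n items ranks ``(n - 0.5) / n``.
    """
    pop = np.asarray(population, dtype=float)
    if pop.size == 0:
        raise ValueError("empty population")
    below = float((pop < value).sum())
    ties = float((pop == value).sum())
    return (below + 0.5 * ties) / pop.size
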