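"""Synthetic endpoint suites emulating a multi-endpoint benchmark study.

The generator produces, per endpoint, a labeled training set and a
validation set (attachable-but-blindable labels) with:

* the training/validation sample sizes and P/N class ratios of the 13
  benchmark endpoints A..M (three toxicogenomic, six clinical, two sex
  positive controls, two randomly-labeled negative controls);
* a block of *informative* features whose mean is shifted by
  ``effect_size`` in the positive class (identity covariance), i.i.d.
  Gaussian noise everywhere, and additive per-(batch, feature) Gaussian
  offsets emulating processing-batch effects;
* negative controls with zero informative features (labels independent of
  the matrix by construction) and positive controls with an effect large
  enough that the Bayes error of the optimal rule is below 1%.

Under this model the Bayes error with ``m`` informative features, shift
``delta`` and noise standard deviation ``sigma`` is
``Phi(-delta * sqrt(m) / (2 * sigma))`` (two equal-covariance Gaussians
whose means differ by ``delta`` along each of ``m`` orthogonal axes).

Each endpoint draws from its own RNG stream derived from
``(suite seed, endpoint code)``, so endpoints are independently
reproducible.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.stats import norm

from .core_io import (
    NEGATIVE,
    POSITIVE,
    TRAINING,
    VALIDATION,
    ExpressionDataset,
    endpoint_hash,
)

REAL = "real"
POSITIVE_CONTROL = "positive_control"
NEGATIVE_CONTROL = "negative_control"

#: (code, class, train_n, train P/N, validation_n, validation P/N) of the 13
#: benchmark endpoints: preclinical toxicity (A-C), breast cancer (D, E),
#: multiple myeloma (F-I) and neuroblastoma (J-M); H/L are sex positive
#: controls, I/M random-label negative controls.
ENDPOINT_TABLE = (
    ("A", REAL, 70, 0.59, 88, 0.47),
    ("B", REAL, 216, 0.51, 201, 0.40),
    ("C", REAL, 214, 0.58, 204, 0.62),
    ("D", REAL, 130, 0.34, 100, 0.18),
    ("E", REAL, 130, 1.60, 100, 1.56),
    ("F", REAL, 340, 0.18, 214, 0.14),
    ("G", REAL, 340, 0.33, 214, 0.19),
    ("H", POSITIVE_CONTROL, 340, 1.33, 214, 1.89),
    ("I", NEGATIVE_CONTROL, 340, 1.43, 214, 1.33),
    ("J", REAL, 238, 0.10, 177, 0.28),
    ("K", REAL, 239, 0.26, 193, 0.75),
    ("L", POSITIVE_CONTROL, 246, 1.44, 231, 1.36),
    ("M", NEGATIVE_CONTROL, 246, 1.44, 253, 1.36),
)

DEFAULT_N_FEATURES = 1000
REDUCED_N_FEATURES = 200
DEFAULT_N_INFORMATIVE = 30
DEFAULT_EFFECT_SIZE = 1.0
POSITIVE_CONTROL_EFFECT_SIZE = 3.0
DEFAULT_NOISE_SD = 1.0
DEFAULT_N_BATCHES = 2
DEFAULT_BATCH_SD = 0.5


def bayes_error(effect_size: float, n_informative: int, noise_sd: float) -> float:
    """Error of the optimal classifier under the generator's model."""
    if n_informative == 0:
        return 0.5
    return float(norm.cdf(-effect_size * math.sqrt(n_informative) / (2 * noise_sd)))


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (documented rule)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def class_counts(n: int, pn_ratio: float) -> tuple:
    """(n_positive, n_negative) realizing ``pn_ratio`` on ``n`` samples."""
    if n <= 0 or pn_ratio <= 0:
        raise ValueError("need n > 0 and pn_ratio > 0")
    n_pos = round_half_up(n * pn_ratio / (1.0 + pn_ratio))
    n_pos = min(max(n_pos, 1), n - 1)
    return n_pos, n - n_pos


@dataclasses.dataclass
class EndpointSpec:
    """Recipe for one synthetic endpoint (training + validation)."""

    code: str
    endpoint_class: str = REAL
    train_n: int = 100
    train_pn_ratio: float = 1.0
    validation_n: int = 100
    validation_pn_ratio: float = 1.0
    n_features: int = DEFAULT_N_FEATURES
    n_informative: int = DEFAULT_N_INFORMATIVE
    effect_size: float = DEFAULT_EFFECT_SIZE
    noise_sd: float = DEFAULT_NOISE_SD
    n_batches: int = DEFAULT_N_BATCHES
    batch_sd: float = DEFAULT_BATCH_SD
    seed: int = 0

    def __post_init__(self):
        if self.endpoint_class not in (REAL, POSITIVE_CONTROL, NEGATIVE_CONTROL):
            raise ValueError(f"unknown endpoint class {self.endpoint_class!r}")
        if self.train_n <= 0 or self.validation_n <= 0:
            raise ValueError("sample sizes must be positive")
        if self.train_pn_ratio <= 0 or self.validation_pn_ratio <= 0:
            raise ValueError("P/N ratios must be positive")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative exceeds n_features")
        if self.endpoint_class == NEGATIVE_CONTROL and self.n_informative != 0:
            raise ValueError("negative controls must have n_informative == 0")
        if self.endpoint_class == POSITIVE_CONTROL:
            err = bayes_error(self.effect_size, self.n_informative, self.noise_sd)
            if err >= 0.01:
                raise ValueError(
                    f"positive control {self.code}: Bayes error {err:.3g} >= 1%"
                )
        if self.n_batches < 1:
            raise ValueError("need at least one batch")


def make_default_suite(n_features: int = DEFAULT_N_FEATURES,
                       seed: int = 0) -> list:
    """The 13-endpoint suite A..M with the benchmark sizes and P/N ratios."""
    if n_features < 2 * DEFAULT_N_INFORMATIVE:
        raise ValueError(
            f"n_features must be >= {2 * DEFAULT_N_INFORMATIVE}"
        )
    specs = []
    for code, cls, tn, tr, vn, vr in ENDPOINT_TABLE:
        if cls == NEGATIVE_CONTROL:
            n_inf, effect = 0, 0.0
        elif cls == POSITIVE_CONTROL:
            n_inf, effect = DEFAULT_N_INFORMATIVE, POSITIVE_CONTROL_EFFECT_SIZE
        else:
            n_inf, effect = DEFAULT_N_INFORMATIVE, DEFAULT_EFFECT_SIZE
        specs.append(EndpointSpec(
            code=code, endpoint_class=cls,
            train_n=tn, train_pn_ratio=tr,
            validation_n=vn, validation_pn_ratio=vr,
            n_features=n_features, n_informative=n_inf,
            effect_size=effect, seed=seed,
        ))
    return specs


def make_reduced_suite(seed: int = 0,
                       n_features: int = REDUCED_N_FEATURES) -> list:
    """Four-endpoint reduced preset: real (D), positive control (H),
    negative control (I) and a strongly imbalanced real endpoint (J,
    train P/N 0.10, which triggers minority oversampling)."""
    keep = {"D", "H", "I", "J"}
    return [s for s in make_default_suite(n_features=n_features, seed=seed)
            if s.code in keep]


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _simulate_split(spec: EndpointSpec, rng: np.random.Generator, n: int,
                    pn_ratio: float, role: str, batch_prefix: str):
    n_pos, n_neg = class_counts(n, pn_ratio)
    labels = np.asarray([POSITIVE] * n_pos + [NEGATIVE] * n_neg)
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_features))
    if spec.n_informative and spec.effect_size:
        X[:n_pos, : spec.n_informative] += spec.effect_size
    # batch assigned round-robin over samples after label assignment, so
    # batch membership is (near-)independent of class
    batch_idx = np.arange(n) % spec.n_batches
    offsets = rng.normal(0.0, spec.batch_sd,
                         size=(spec.n_batches, spec.n_features))
    X += offsets[batch_idx]
    tag = "tr" if role == TRAINING else "va"
    ds = ExpressionDataset(
        sample_ids=[f"{spec.code}-{tag}-{i:04d}" for i in range(n)],
        feature_ids=[f"g{j:05d}" for j in range(spec.n_features)],
        values=X,
        labels=labels,
        batches=[f"{batch_prefix}{b}" for b in batch_idx],
        endpoint_code=spec.code,
        role=role,
    )
    return ds, offsets


def simulate_endpoint(spec: EndpointSpec):
    """Simulate (training, validation) datasets for one endpoint.

    Both carry labels; callers that must respect blinding take
    ``validation.blinded()`` and keep the returned labeled copy as the
    answer key.  Fully reproducible from ``(spec.seed, spec.code)``.
    Validation samples come from the same feature model but fresh batches
    (their own batch offsets and distinct batch ids).
    """
    train, val, _ = simulate_endpoint_with_truth(spec)
    return train, val


def simulate_endpoint_with_truth(spec: EndpointSpec):
    """Like :func:`simulate_endpoint` but also returns the ground truth.

    The truth dict holds the informative column indices and the injected
    per-(batch, feature) offsets of both splits; tests use it for
    parameter-recovery checks.
    """
    rng = np.random.default_rng([spec.seed, endpoint_hash(spec.code)])
    train, train_offsets = _simulate_split(
        spec, rng, spec.train_n, spec.train_pn_ratio, TRAINING, "B")
    val, val_offsets = _simulate_split(
        spec, rng, spec.validation_n, spec.validation_pn_ratio, VALIDATION, "VB")
    truth = {
        "informative": np.arange(spec.n_informative),
        "train_batch_offsets": train_offsets,
        "validation_batch_offsets": val_offsets,
    }
    return train, val, truth
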