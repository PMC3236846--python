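"""Shared data model, text-based IO and run configuration.

Every downstream stage of the pipeline consumes :class:`ExpressionDataset`
and :class:`RunConfig` only; nothing else in the package touches raw files.
Datasets travel as a TSV matrix (rows = samples, header row = feature ids,
first column = sample id) plus a JSON metadata sidecar carrying sample
order, class labels, batch labels, endpoint code and role.  A *blinded*
dataset simply has no ``labels`` entry in its sidecar.

Expression values are assumed to be log2-scale summarized intensities;
the package never re-logs or normalizes them.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import sys
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

POSITIVE = "P"
NEGATIVE = "N"
LABEL_TOKENS = (POSITIVE, NEGATIVE)

TRAINING = "training"
VALIDATION = "validation"


class DatasetError(ValueError):
    """A dataset (in memory or on disk) violates its structural contract."""


def endpoint_hash(code: str) -> int:
    """Stable small integer derived from an endpoint code, for seeding."""
    return zlib.crc32(code.encode("utf-8")) % (2**31 - 1)


@dataclasses.dataclass
class ClassRatio:
    """Positive/negative class counts and their ratio."""

    n_positive: int
    n_negative: int

    @property
    def pn_ratio(self) -> float:
        if self.n_negative == 0:
            return float("inf") if self.n_positive else 0.0
        return self.n_positive / self.n_negative


@dataclasses.dataclass
class ExpressionDataset:
    """Samples x features matrix of log2 intensities with metadata.

    Parameters
    ----------
    sample_ids, feature_ids
        Unique identifiers; ``values`` has one row per sample and one
        column per feature.
    labels
        Per-sample class token (``"P"``/``"N"``) or ``None`` when the
        dataset is blinded.
    batches
        Per-sample batch identifier strings (hybridization/processing
        batches); required by batch-effect correction.
    endpoint_code
        Short code for the prediction endpoint (``"A"``..``"M"`` in the
        default suite).
    role
        ``"training"`` or ``"validation"``.
    """

    sample_ids: list
    feature_ids: list
    values: np.ndarray
    labels: np.ndarray | None = None
    batches: list | None = None
    endpoint_code: str = ""
    role: str = TRAINING

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DatasetError("expression matrix must be 2-dimensional")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise DatasetError(
                f"matrix has {n} rows but {len(self.sample_ids)} sample ids"
            )
        if p != len(self.feature_ids):
            raise DatasetError(
                f"matrix has {p} columns but {len(self.feature_ids)} feature ids"
            )
        if len(set(self.sample_ids)) != n:
            raise DatasetError("duplicate sample ids")
        if len(set(self.feature_ids)) != p:
            raise DatasetError("duplicate feature ids")
        if not np.all(np.isfinite(self.values)):
            raise DatasetError("expression matrix contains missing/non-finite values")
        if self.labels is not None:
            self.labels = np.asarray([str(l) for l in self.labels])
            if self.labels.shape[0] != n:
                raise DatasetError("labels length does not match sample count")
            bad = set(self.labels) - set(LABEL_TOKENS)
            if bad:
                raise DatasetError(f"unknown label tokens: {sorted(bad)}")
            if self.role == TRAINING and n > 0:
                if len(set(self.labels)) < 2:
                    raise DatasetError(
                        "training dataset must contain both classes"
                    )
        if self.batches is not None:
            self.batches = [str(b) for b in self.batches]
            if len(self.batches) != n:
                raise DatasetError("batches length does not match sample count")
        if self.role not in (TRAINING, VALIDATION):
            raise DatasetError(f"unknown role {self.role!r}")

    # -- convenience ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def is_blinded(self) -> bool:
        return self.labels is None

    @property
    def y(self) -> np.ndarray:
        """Boolean label vector (True = positive class)."""
        if self.labels is None:
            raise DatasetError("dataset is blinded; labels unavailable")
        return self.labels == POSITIVE

    def class_ratio(self) -> ClassRatio:
        y = self.y
        return ClassRatio(int(y.sum()), int((~y).sum()))

    def blinded(self) -> "ExpressionDataset":
        """Copy with the class labels withheld."""
        return ExpressionDataset(
            sample_ids=list(self.sample_ids),
            feature_ids=list(self.feature_ids),
            values=self.values.copy(),
            labels=None,
            batches=None if self.batches is None else list(self.batches),
            endpoint_code=self.endpoint_code,
            role=self.role,
        )

    def feature_index(self) -> dict:
        return {f: i for i, f in enumerate(self.feature_ids)}


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

_EXPORT_DECIMALS = 6  # numeric export precision; readers accept any float


def read_dataset(matrix_path, metadata_path) -> ExpressionDataset:
    """Load a TSV matrix (+ JSON sidecar) into an :class:`ExpressionDataset`.

    The matrix file's first column holds sample ids and its header row
    feature ids; gzip-compressed TSV is accepted transparently.  Blinded
    datasets (no ``labels`` key in the sidecar) load with labels withheld.
    """
    matrix_path = Path(matrix_path)
    metadata_path = Path(metadata_path)
    try:
        frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - message passthrough
        raise DatasetError(f"{matrix_path}: cannot parse matrix ({exc})") from exc
    with open(metadata_path) as fh:
        meta = json.load(fh)

    samples = [str(s) for s in meta.get("samples", [])]
    if sorted(samples) != sorted(str(s) for s in frame.index):
        raise DatasetError(
            f"{metadata_path}: sample list does not match matrix rows in "
            f"{matrix_path} ({len(samples)} vs {len(frame.index)})"
        )
    frame = frame.loc[samples]
    if frame.isna().any().any():
        col = frame.columns[frame.isna().any()][0]
        raise DatasetError(f"{matrix_path}: missing values (e.g. feature {col})")

    labels = meta.get("labels")
    if labels is not None:
        labels = np.asarray([str(l) for l in labels])
    return ExpressionDataset(
        sample_ids=samples,
        feature_ids=[str(f) for f in frame.columns],
        values=frame.to_numpy(dtype=float),
        labels=labels,
        batches=meta.get("batches"),
        endpoint_code=str(meta.get("endpoint_code", "")),
        role=str(meta.get("role", TRAINING)),
    )


def write_dataset(ds: ExpressionDataset, matrix_path, metadata_path,
                  blinded: bool = False) -> None:
    """Write ``ds`` as TSV + JSON sidecar readable by :func:`read_dataset`.

    With ``blinded=True`` the labels entry is omitted entirely (a blinded
    sidecar has *no* labels field, not an empty one).  Values are written
    with 6 decimal places.
    """
    frame = pd.DataFrame(ds.values, index=ds.sample_ids, columns=ds.feature_ids)
    frame.index.name = "sample_id"
    matrix_path = Path(matrix_path)
    matrix_path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(matrix_path, sep="\t", float_format=f"%.{_EXPORT_DECIMALS}f")
    meta = {
        "samples": list(ds.sample_ids),
        "endpoint_code": ds.endpoint_code,
        "role": ds.role,
    }
    if ds.batches is not None:
        meta["batches"] = list(ds.batches)
    if ds.labels is not None and not blinded:
        meta["labels"] = [str(l) for l in ds.labels]
    with open(metadata_path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """Knobs of the model-development protocol.

    Defaults reproduce the full protocol: feature sets of 5,10,...,200 from
    each of two ranking methods, a 7-value K grid for KNN plus Naive Bayes,
    5-fold cross-validation repeated 10 times (50 CV runs), oversampling
    triggered by a majority/minority ratio strictly greater than 4, a raw
    p<0.05 filter for the fold-change ranking, and a 50% ensemble
    retention fraction.
    """

    feature_step: int = 5
    feature_max: int = 200
    knn_k_grid: tuple = (1, 3, 5, 7, 9, 11, 13)
    cv_folds: int = 5
    cv_repeats: int = 10
    imbalance_threshold: float = 4.0
    p_cutoff: float = 0.05
    ensemble_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.knn_k_grid = tuple(int(k) for k in self.knn_k_grid)
        if self.feature_step < 1 or self.feature_max < self.feature_step:
            raise ValueError("need feature_step >= 1 and feature_max >= feature_step")
        if self.feature_max % self.feature_step != 0:
            raise ValueError("feature_step must divide feature_max")
        if any(k < 1 for k in self.knn_k_grid) or not self.knn_k_grid:
            raise ValueError("knn_k_grid must be non-empty positive counts")
        if self.cv_folds < 2 or self.cv_repeats < 1:
            raise ValueError("need cv_folds >= 2 and cv_repeats >= 1")
        if not (0 < self.ensemble_fraction <= 1):
            raise ValueError("ensemble_fraction must be in (0, 1]")
        if not (0 < self.p_cutoff <= 1):
            raise ValueError("p_cutoff must be in (0, 1]")

    @property
    def feature_sizes(self) -> list:
        return list(range(self.feature_step, self.feature_max + 1, self.feature_step))

    @property
    def n_cv_runs(self) -> int:
        return self.cv_folds * self.cv_repeats

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["knn_k_grid"] = list(self.knn_k_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def reduced(cls, seed: int = 0) -> "RunConfig":
        """Reduced-scale preset: feature sets up to 50, 5x5 CV (25 runs)."""
        return cls(feature_max=50, cv_repeats=5, seed=seed)


# ---------------------------------------------------------------------------
# Logging
# ---------------------------------------------------------------------------


def get_logger(name: str = "gridvote", level: str = "INFO",
               logfile=None) -> logging.Logger:
    """Timestamped, leveled logger writing to stderr (and optional file)."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        fmt = logging.Formatter(
            "%(asctime)s %(levelname)s %(name)s: %(message)s",
            datefmt="%Y-%m-%dT%H:%M:%S",
        )
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(fmt)
        logger.addHandler(handler)
        if logfile is not None:
            fhandler = logging.FileHandler(logfile)
            fhandler.setFormatter(fmt)
            logger.addHandler(fhandler)
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))
    return logger
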