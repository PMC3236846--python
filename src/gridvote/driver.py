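"""End-to-end experiment orchestration on synthetic endpoint suites.

For each endpoint: simulate training + validation, run the complete-CV
grid on training only, nominate a single model and build the calibrated-
vote ensemble (training-side only), freeze both, predict the *blinded*
validation set, and score the frozen predictions against the withheld
answer key.  The suite report compares the two deciders per endpoint
(validation MCC and percentile placement among all grid configs'
validation MCCs) and suite-wide (paired t-test with negative controls
excluded, win/tie/loss counts, CV-vs-validation correlation).
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    ExpressionDataset,
    NEGATIVE,
    POSITIVE,
    RunConfig,
    get_logger,
    write_dataset,
)
from .synthetic_data import NEGATIVE_CONTROL, EndpointSpec, simulate_endpoint
from .crossval import STATUS_OK, enumerate_grid, grid_eval, run_grid
from .model_choice import (
    ProcessedTraining,
    build_ensemble,
    process_training,
    select_nominated,
    select_retained,
    vote_labels,
)
from .metrics import (
    ConfusionCounts,
    PairedTResult,
    mcc,
    paired_t_test,
    pearson_r,
    percentile_rank,
)

log = get_logger(__name__)


def score_predictions(pred, key: ExpressionDataset) -> ConfusionCounts:
    """Score frozen per-sample predictions against the labeled answer key.

    ``pred`` maps sample id -> 'P'/'N' (dict or pandas Series).  Only the
    intersection of sample ids is scored; ids missing from the key are
    reported via the logger.  This is the only stage of the pipeline that
    reads validation labels.
    """
    if key.labels is None:
        raise ValueError("answer key has no labels")
    pred = dict(pred.items()) if hasattr(pred, "items") else dict(pred)
    key_index = {s: i for i, s in enumerate(key.sample_ids)}
    shared = [s for s in pred if s in key_index]
    if not shared:
        raise ValueError("no overlap between prediction and key sample ids")
    missing = len(pred) - len(shared)
    if missing:
        log.warning("%d predicted sample ids absent from the key", missing)
    y_true = np.asarray([key.labels[key_index[s]] == POSITIVE for s in shared])
    y_pred = np.asarray([pred[s] == POSITIVE for s in shared])
    return ConfusionCounts.from_labels(y_true, y_pred)


def _grid_votes(proc: ProcessedTraining, run_cfg: RunConfig, configs,
                eval_ds: ExpressionDataset) -> dict:
    """Boolean prediction vector per config id on ``eval_ds`` (blinded).

    Every config is refit on the fully processed training set; rankings
    and KNN distances are shared across the grid exactly as in CV.
    """
    if eval_ds.feature_ids != proc.dataset.feature_ids:
        raise ValueError("evaluation features do not match training features")
    X_eval = eval_ds.values
    if eval_ds.batches is not None:
        X_eval = proc.centerer.transform(X_eval, eval_ds.batches)
    index = proc.dataset.feature_index()
    rankings = {
        m: np.asarray([index[f] for f in ranked], dtype=int)
        for m, ranked in proc.rankings.items()
    }
    sizes = sorted({c.n_features for c in configs})
    ks = sorted({c.k for c in configs if c.k is not None})
    want_nb = any(c.k is None for c in configs)
    preds = grid_eval(proc.dataset.values, proc.dataset.y,
                      proc.dataset.sample_ids, X_eval, rankings, sizes, ks,
                      want_nb)
    votes = {}
    for c in configs:
        got = preds.get((c.fs_method, c.n_features, c.classifier, c.k))
        if got is not None:
            votes[c.config_id] = got[0]
    return votes


@dataclasses.dataclass
class EndpointResult:
    code: str
    endpoint_class: str
    nominated_config: str
    nominated_mcc: float
    ensemble_mcc: float
    nominated_percentile: float
    ensemble_percentile: float
    n_retained: int
    p_bar: float
    cv_val_r: float


@dataclasses.dataclass
class ComparisonReport:
    """Suite-level comparison of the ensemble vs the nominated model."""

    rows: list
    paired_t: PairedTResult
    excluded: list
    wins: int
    ties: int
    losses: int
    run_config: dict

    def to_dict(self) -> dict:
        return {
            "endpoints": [dataclasses.asdict(r) for r in self.rows],
            "paired_t": dataclasses.asdict(self.paired_t),
            "excluded_endpoints": list(self.excluded),
            "wins": self.wins,
            "ties": self.ties,
            "losses": self.losses,
            "run_config": self.run_config,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.rows])


def run_endpoint(spec: EndpointSpec, run_cfg: RunConfig,
                 out_dir=None):
    """Full pipeline for one endpoint; returns (EndpointResult, details)."""
    train, key = simulate_endpoint(spec)
    blinded = key.blinded()
    configs = enumerate_grid(run_cfg, [spec.code])
    perfs = run_grid(train, configs, run_cfg)
    proc = process_training(train, run_cfg)
    votes = _grid_votes(proc, run_cfg, configs, blinded)

    # nominated single model
    nominated = select_nominated(perfs, feature_step=run_cfg.feature_step)
    nom_pred = {
        s: (POSITIVE if v else NEGATIVE)
        for s, v in zip(blinded.sample_ids, votes[nominated.config_id])
    }
    # calibrated-vote ensemble (training-side information only)
    ens = build_ensemble(perfs, train, run_cfg, proc=proc)
    vote_frac = np.vstack([votes[cid] for cid in ens.config_ids]).mean(axis=0)
    ens_bool = vote_labels(vote_frac, ens.p_bar)
    ens_pred = {
        s: (POSITIVE if v else NEGATIVE)
        for s, v in zip(blinded.sample_ids, ens_bool)
    }

    # scoring (the only step that touches validation labels)
    nom_mcc = mcc(score_predictions(nom_pred, key))
    ens_mcc = mcc(score_predictions(ens_pred, key))
    val_mcc = {}
    y_val = key.y
    for cid, v in votes.items():
        val_mcc[cid] = mcc(ConfusionCounts.from_labels(y_val, v))
    population = [val_mcc[c.config_id] for c in configs
                  if c.config_id in val_mcc]
    cv_by_cid = {p.config_id: p.mean_mcc for p in perfs
                 if p.status == STATUS_OK and p.config_id in val_mcc}
    try:
        cv_val_r = pearson_r(list(cv_by_cid.values()),
                             [val_mcc[cid] for cid in cv_by_cid])
    except ValueError:
        cv_val_r = float("nan")

    result = EndpointResult(
        code=spec.code,
        endpoint_class=spec.endpoint_class,
        nominated_config=nominated.config_id,
        nominated_mcc=nom_mcc,
        ensemble_mcc=ens_mcc,
        nominated_percentile=percentile_rank(nom_mcc, population),
        ensemble_percentile=percentile_rank(ens_mcc, population),
        n_retained=len(ens.retained),
        p_bar=ens.p_bar,
        cv_val_r=cv_val_r,
    )
    details = {
        "train": train, "key": key, "blinded": blinded, "perfs": perfs,
        "proc": proc, "votes": votes, "ensemble": ens,
        "nominated": nominated, "val_mcc": val_mcc,
        "nominated_pred": nom_pred, "ensemble_pred": ens_pred,
    }
    if out_dir is not None:
        _write_endpoint_artifacts(Path(out_dir), spec, run_cfg, result, details)
    return result, details


def run_suite(run_cfg: RunConfig, specs, out_dir=None) -> ComparisonReport:
    """Run every endpoint and assemble the comparison report.

    A failing endpoint is logged and marked absent from the report rather
    than aborting the suite.  Byte-identical ``report.json`` for
    identical seeds.
    """
    rows = []
    excluded = []
    for spec in specs:
        try:
            result, _ = run_endpoint(spec, run_cfg, out_dir=out_dir)
        except Exception as exc:
            log.error("endpoint %s failed: %s", spec.code, exc)
            continue
        rows.append(result)
        if spec.endpoint_class == NEGATIVE_CONTROL:
            excluded.append(spec.code)
    if len(rows) >= 2:
        codes = [r.code for r in rows]
        usable = [c for c in codes if c not in excluded]
        if len(usable) >= 2:
            t_res = paired_t_test(
                [r.ensemble_mcc for r in rows],
                [r.nominated_mcc for r in rows],
                codes=codes, exclude=excluded)
        else:
            t_res = PairedTResult(float("nan"), float("nan"), 0, True)
    else:
        t_res = PairedTResult(float("nan"), float("nan"), len(rows), True)
    wins = sum(r.ensemble_mcc > r.nominated_mcc for r in rows)
    ties = sum(r.ensemble_mcc == r.nominated_mcc for r in rows)
    report = ComparisonReport(
        rows=rows, paired_t=t_res, excluded=excluded,
        wins=int(wins), ties=int(ties),
        losses=int(len(rows) - wins - ties),
        run_config=run_cfg.to_dict(),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json() + "\n")
        report.to_frame().to_csv(out / "report.tsv", sep="\t", index=False)
    return report


def sweep_fraction(run_cfg: RunConfig, specs, fractions) -> pd.DataFrame:
    """Mean validation MCC of the ensemble at several retention fractions.

    The CV grid (and the per-config validation votes) is computed once
    per endpoint; each fraction only reselects the retained set and
    recalibrates p-bar.  Returns a table indexed by fraction with one
    column per endpoint plus ``mean_mcc``.
    """
    fractions = sorted(float(f) for f in fractions)
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    per_endpoint = {}
    for spec in specs:
        train, key = simulate_endpoint(spec)
        blinded = key.blinded()
        configs = enumerate_grid(run_cfg, [spec.code])
        perfs = run_grid(train, configs, run_cfg)
        proc = process_training(train, run_cfg)
        votes = _grid_votes(proc, run_cfg, configs, blinded)
        y_val = key.y
        rates = {p.config_id: p.oof_positive_rate for p in perfs
                 if p.status == STATUS_OK}
        col = {}
        for f in fractions:
            kept = [p.config_id for p in select_retained(perfs, f)
                    if p.config_id in votes]
            v = np.vstack([votes[cid] for cid in kept]).mean(axis=0)
            p_bar = float(np.mean([rates[cid] for cid in kept]))
            pred = vote_labels(v, p_bar)
            col[f] = mcc(ConfusionCounts.from_labels(y_val, pred))
        per_endpoint[spec.code] = col
    table = pd.DataFrame(per_endpoint)
    table.index.name = "fraction"
    table["mean_mcc"] = table.mean(axis=1)
    return table


# ---------------------------------------------------------------------------
# Artifact writing
# ---------------------------------------------------------------------------


def _write_endpoint_artifacts(out: Path, spec, run_cfg, result, details):
    code = spec.code
    ds_dir, perf_dir = out / "datasets", out / "perf"
    model_dir, pred_dir = out / "models", out / "predictions"
    for d in (ds_dir, perf_dir, model_dir, pred_dir):
        d.mkdir(parents=True, exist_ok=True)
    write_dataset(details["train"], ds_dir / f"{code}_train.tsv",
                  ds_dir / f"{code}_train.json")
    write_dataset(details["key"], ds_dir / f"{code}_validation.tsv",
                  ds_dir / f"{code}_validation_blinded.json", blinded=True)
    with open(ds_dir / f"{code}_validation_key.json", "w") as fh:
        json.dump({"samples": details["key"].sample_ids,
                   "labels": [str(l) for l in details["key"].labels]},
                  fh, indent=1, sort_keys=True)
    perf_frame = pd.DataFrame([
        {
            "config_id": p.config_id,
            "fs_method": p.config.fs_method,
            "n_features": p.config.n_features,
            "classifier": p.config.classifier,
            "k": p.config.k,
            "mean_mcc": p.mean_mcc,
            "mean_accuracy": p.mean_accuracy,
            "mean_sensitivity": p.mean_sensitivity,
            "mean_specificity": p.mean_specificity,
            "n_runs": p.n_runs,
            "oof_positive_rate": p.oof_positive_rate,
            "status": p.status,
            "capped": p.capped,
        }
        for p in details["perfs"]
    ])
    perf_frame.to_csv(perf_dir / f"{code}_perf.tsv", sep="\t", index=False)
    ens = details["ensemble"]
    with open(model_dir / f"{code}_nominated.json", "w") as fh:
        json.dump({"config_id": result.nominated_config}, fh, indent=1)
    with open(model_dir / f"{code}_ensemble.json", "w") as fh:
        json.dump({
            "p_bar": ens.p_bar,
            "fraction": ens.fraction,
            "retained": [
                {"config_id": r.config.config_id,
                 "training_positive_rate": r.training_positive_rate}
                for r in ens.retained
            ],
        }, fh, indent=1, sort_keys=True)
    pred_frame = pd.DataFrame({
        "sample_id": details["blinded"].sample_ids,
        "nominated": [details["nominated_pred"][s]
                      for s in details["blinded"].sample_ids],
        "ensemble": [details["ensemble_pred"][s]
                     for s in details["blinded"].sample_ids],
    })
    pred_frame.to_csv(pred_dir / f"{code}_predictions.tsv", sep="\t",
                      index=False)
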