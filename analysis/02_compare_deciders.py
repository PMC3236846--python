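#!/usr/bin/env python
"""Run the full comparison on one suite: CV grid, nomination, ensemble,
blinded validation, scoring.

For each endpoint this cross-validates the whole model grid on the
training set, nominates one model by the MCC-guided decision tree,
builds the calibrated-vote ensemble from the top half of the grid,
freezes both, predicts the blinded validation set and scores against
the withheld key.  Small comparison tables go to ``results/``; pass
``--artifacts`` to also dump every intermediate (datasets, per-config
performance, frozen models, predictions) to a run directory.

    python analysis/02_compare_deciders.py --seed 1 --reduced
"""
import argparse
from pathlib import Path

from gridvote.core_io import RunConfig
from gridvote.driver import run_suite
from gridvote.synthetic_data import make_default_suite, make_reduced_suite


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--artifacts", type=Path, default=None,
                    help="run directory for full intermediates "
                         "(e.g. scratch/run)")
    ap.add_argument("--reduced", action="store_true")
    ap.add_argument("--fraction", type=float, default=0.5,
                    help="ensemble retention fraction")
    args = ap.parse_args()

    if args.reduced:
        cfg = RunConfig.reduced(seed=args.seed)
        specs = make_reduced_suite(seed=args.seed)
    else:
        cfg = RunConfig(seed=args.seed)
        specs = make_default_suite(seed=args.seed)
    cfg = RunConfig(**{**cfg.to_dict(), "ensemble_fraction": args.fraction})

    report = run_suite(cfg, specs, out_dir=args.artifacts)

    print(f"{'endpoint':>8} {'class':>16} {'nominated':>10} {'ensemble':>9} "
          f"{'nom pct':>8} {'ens pct':>8}")
    for r in report.rows:
        print(f"{r.code:>8} {r.endpoint_class:>16} {r.nominated_mcc:>10.3f} "
              f"{r.ensemble_mcc:>9.3f} {r.nominated_percentile:>8.2f} "
              f"{r.ensemble_percentile:>8.2f}")
    t = report.paired_t
    print(f"\nensemble vs nominated (random-label endpoints "
          f"{report.excluded} excluded): "
          f"t = {t.t:.3f}, two-sided p = {t.p:.3f}, n = {t.n_used}")
    print(f"win/tie/loss for the ensemble: {report.wins}/{report.ties}/"
          f"{report.losses}")

    args.results.mkdir(parents=True, exist_ok=True)
    (args.results / "comparison_report.json").write_text(
        report.to_json() + "\n")
    report.to_frame().to_csv(args.results / "comparison_report.tsv",
                             sep="\t", index=False)
    print(f"\nwrote results/comparison_report.json and .tsv")


if __name__ == "__main__":
    main()
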