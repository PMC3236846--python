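#!/usr/bin/env python
"""Simulate a synthetic endpoint suite and export it as TSV + JSON.

Writes, per endpoint: the labeled training set, the blinded validation
set and a separate answer-key file.  Expression matrices are large, so
the default output directory is ``scratch/datasets`` (scratch space);
a small manifest of what was generated goes to ``results/``.

    python analysis/01_simulate_suite.py --seed 1 --reduced
"""
import argparse
import json
from pathlib import Path

import pandas as pd

from gridvote.core_io import write_dataset
from gridvote.synthetic_data import (
    make_default_suite,
    make_reduced_suite,
    simulate_endpoint,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("scratch/datasets"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--reduced", action="store_true",
                    help="4-endpoint, 200-feature preset")
    ap.add_argument("--n-features", type=int, default=None,
                    help="override the preset feature count")
    args = ap.parse_args()

    if args.reduced:
        specs = (make_reduced_suite(seed=args.seed)
                 if args.n_features is None
                 else make_reduced_suite(seed=args.seed,
                                         n_features=args.n_features))
    else:
        specs = make_default_suite(
            n_features=args.n_features or 1000, seed=args.seed)

    args.out.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in specs:
        train, key = simulate_endpoint(spec)
        write_dataset(train, args.out / f"{spec.code}_train.tsv",
                      args.out / f"{spec.code}_train.json")
        write_dataset(key, args.out / f"{spec.code}_validation.tsv",
                      args.out / f"{spec.code}_validation_blinded.json",
                      blinded=True)
        with open(args.out / f"{spec.code}_validation_key.json", "w") as fh:
            json.dump({"samples": key.sample_ids,
                       "labels": [str(l) for l in key.labels]},
                      fh, indent=1, sort_keys=True)
        tr = train.class_ratio()
        va = key.class_ratio()
        rows.append({
            "endpoint": spec.code,
            "class": spec.endpoint_class,
            "train_n": train.n_samples,
            "train_pn": round(tr.pn_ratio, 3),
            "validation_n": key.n_samples,
            "validation_pn": round(va.pn_ratio, 3),
            "n_features": spec.n_features,
            "n_informative": spec.n_informative,
            "effect_size": spec.effect_size,
        })
        print(f"endpoint {spec.code:>2} ({spec.endpoint_class:>16}): "
              f"train {train.n_samples} (P/N {tr.pn_ratio:.2f}), "
              f"validation {key.n_samples} (P/N {va.pn_ratio:.2f})")

    args.results.mkdir(parents=True, exist_ok=True)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(args.results / "suite_manifest.tsv", sep="\t",
                    index=False)
    print(f"\nwrote {len(specs)} endpoints to {args.out}/ "
          f"and manifest to {args.results}/suite_manifest.tsv")


if __name__ == "__main__":
    main()
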