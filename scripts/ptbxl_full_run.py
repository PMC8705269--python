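#!/usr/bin/env python
"""Optional full-scale run on the public PTB-XL dataset.

This script reproduces the full-dataset protocol: filter the 21,837-record
metadata down to the certainty- and subclass-population-filtered cohort
(17,232 records expected), extract consensus R-peaks, QRS segments and
entropy features, and train the module combinations with the five-seed
cross-validation protocol.  It requires a local copy of PTB-XL (500 Hz WFDB
records plus ptbxl_database.csv and scp_statements.csv) downloaded from
PhysioNet, and several hours of compute at full scale; it is deliberately
not part of the test suite.

Usage:
    python scripts/ptbxl_full_run.py --ptbxl-dir /path/to/ptb-xl \
        --out results/ptbxl [--classes 2] [--modules raw,qrs,qrs_entropy] \
        [--limit N]
"""

from __future__ import annotations

import argparse
import json
import os
import sys

import numpy as np


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(
        description="Full-scale PTB-XL reproduction (requires the PTB-XL download)")
    parser.add_argument("--ptbxl-dir", required=True,
                        help="root of the PTB-XL dataset (contains ptbxl_database.csv)")
    parser.add_argument("--out", required=True)
    parser.add_argument("--classes", type=int, default=2, choices=(2, 5, 20))
    parser.add_argument("--modules", default="raw,qrs,qrs_entropy")
    parser.add_argument("--limit", type=int, default=0,
                        help="optional cap on record count (0 = all)")
    parser.add_argument("--max-epochs", type=int, default=10_000)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args(argv)

    db_csv = os.path.join(args.ptbxl_dir, "ptbxl_database.csv")
    scp_csv = os.path.join(args.ptbxl_dir, "scp_statements.csv")
    for path in (db_csv, scp_csv):
        if not os.path.exists(path):
            print(f"error: {path} not found; download PTB-XL from PhysioNet first",
                  file=sys.stderr)
            return 2

    from ecgfusion.data_io import filter_metadata, load_ptbxl_metadata, load_record
    from ecgfusion.model import ModuleConfig
    from ecgfusion.pipeline import prepare_dataset, run_experiment
    from ecgfusion.training import TrainConfig

    rows, code_map = load_ptbxl_metadata(db_csv, scp_csv)
    kept = filter_metadata(rows, code_map)
    print(f"metadata filter: {len(rows)} -> {len(kept)} records "
          f"(expected 17,232 on the published release)")

    import pandas as pd

    db = pd.read_csv(db_csv, index_col=0)
    filenames = db["filename_hr"].to_dict()  # 500 Hz WFDB basenames

    classes = ("NORM", "CD", "STTC", "MI", "HYP")
    subclasses = sorted({r.subclass for r in kept})
    labeled = []
    for row in kept[: args.limit or None]:
        base = os.path.join(args.ptbxl_dir, filenames[int(row.record_id)])
        record = load_record(base, metadata=row)
        if args.classes == 2:
            label = record.binary_label
        elif args.classes == 5:
            label = classes.index(row.superclass)
        else:
            label = subclasses.index(row.subclass)
        labeled.append((record, label))

    modules = tuple(m.strip() for m in args.modules.split(","))
    features, dropped = prepare_dataset(labeled, modules)
    print(f"feature extraction: {len(features)} usable, {dropped} dropped")

    result = run_experiment(
        features,
        ModuleConfig(enabled=modules, n_classes=args.classes, seed=args.seed),
        TrainConfig(max_epochs=args.max_epochs, seed=args.seed),
        split_seeds=(1, 2, 3, 4, 5))
    os.makedirs(args.out, exist_ok=True)
    with open(os.path.join(args.out, "report.json"), "w") as fh:
        json.dump({"n_records": len(features),
                   "n_filtered": len(kept),
                   "aggregate": result.report.aggregate,
                   "per_seed": result.per_seed}, fh, indent=2, sort_keys=True)
    acc = result.report.aggregate["accuracy"]
    print(f"test accuracy {acc['min']:.3f}-{acc['max']:.3f} "
          f"mean {acc['mean']:.3f} std {acc['std']:.3f}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
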