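#!/usr/bin/env python
"""Summarize per-event power metrics by group and cluster.

Aggregates the duration, maximum 0-50 Hz band power, AUC, normalized
distal metrics and propagation delays computed in 02 (saturation-
excluded events carry no metrics), comparing propagated against
attenuated/nonpropagated seizures within each group, and writes
metrics_by_cluster.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ecogprop import read_tables, write_tables


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    events = read_tables(args.out_dir / "events.csv")
    seiz = events[(events["type"] == "seizure") & (~events["metrics_excluded"])]
    if "cluster_label" not in seiz.columns or seiz["cluster_label"].isna().all():
        print("no clustered seizures with metrics; run 02 and 03 first")
        return

    cols = [
        "duration_s", "max_band_power", "auc",
        "norm_max_power_d1", "norm_max_power_d2",
        "norm_auc_d1", "norm_auc_d2", "delay_d1_s", "delay_d2_s",
    ]
    summary = (
        seiz.groupby(["group", "cluster_label"])[cols]
        .agg(["mean", "median", "count"])
        .round(4)
    )
    flat = summary.copy()
    flat.columns = ["_".join(c) for c in flat.columns]
    write_tables(flat.reset_index(), args.out_dir / "metrics_by_cluster.csv")

    print(f"{len(seiz)} seizures with metrics "
          f"({int(events['metrics_excluded'].sum())} excluded for saturation)")
    for group, g in seiz.groupby("group"):
        med = g.groupby("cluster_label")[["auc", "norm_auc_d1", "norm_auc_d2"]].median()
        print(f"\n{group}: median AUC at focus and normalized at 1/2 mm")
        print(med.round(3).to_string())
    # the distal story: normalized metrics collapse for non-propagated events
    by_lab = seiz.groupby("cluster_label")["norm_auc_d2"].median()
    if {"propagated", "nonpropagated"} <= set(by_lab.index):
        ratio = by_lab["propagated"] / max(by_lab["nonpropagated"], 1e-12)
        print(f"\nnormalized 2-mm AUC, propagated vs nonpropagated median ratio: {ratio:.1f}x")


if __name__ == "__main__":
    main()
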