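#!/usr/bin/env python
"""Quantify bulk protein accumulation across G1/S/G2/M sorted fractions.

Simulates the interphase sort design (four replicates of SILAC ratios
against an asynchronous internal standard; mostly bulk-accumulating
proteins plus histone-like, mitotic-peaking and constant-per-cell classes),
then computes the per-fraction log2 ratio distributions, the mean profile,
and the through-origin exponential growth fit y = e^(m t).  On this design
the fit recovers close to exact content doubling (fold over cycle ~2); the
planted mitotic-peaking proteins show >~7-fold G1-to-M increases and the
constant-per-cell class stays flat.

Writes fraction_summaries.csv, bulk_profile.csv, growth_fit.json,
group_profiles.csv and per_protein_folds.csv under results/interphase/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from primmus.accumulation import (bulk_mean_profile,
                                  fraction_distribution_summary,
                                  group_mean_profiles, growth_fit_from_ratios,
                                  per_protein_fold)
from primmus.ergodic import PhaseFrequencyTable, build_timeline
from primmus.quant import normalize_silac, replicate_median_profile
from primmus.simulate import SimulationConfig, simulate_interphase_dataset


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results/interphase"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed, n_cells=20_000)
    ds = simulate_interphase_dataset(cfg, n_replicates=4)
    timeline = build_timeline(PhaseFrequencyTable(
        ("G1", "S", "G2", "M"), cfg.phase_boundaries, cfg.doubling_time))

    summaries = pd.DataFrame(
        [fraction_distribution_summary(ds.matrix, f)
         for f in ("G1", "S", "G2", "M")])
    summaries.to_csv(args.out_dir / "fraction_summaries.csv", index=False)
    print("Per-fraction log2 ratio distributions (vs asynchronous standard):")
    print(summaries.round(3).to_string(index=False))

    profile = bulk_mean_profile(ds.matrix, reference=None)
    profile.to_csv(args.out_dir / "bulk_profile.csv")
    fit = growth_fit_from_ratios(timeline, np.exp2(profile["mean_log2"]))
    (args.out_dir / "growth_fit.json").write_text(json.dumps(
        {"m": fit.m, "r2": fit.r2, "fold_over_cycle": fit.fold_over_cycle},
        indent=2) + "\n")
    print(f"\nExponential growth fit: m = {fit.m:.3f}, "
          f"fold over cycle = {fit.fold_over_cycle:.2f}, r2 = {fit.r2:.3f}")

    normalized = normalize_silac(ds.matrix, "per-replicate-to-reference", "G1")
    median = replicate_median_profile(normalized)
    labels = {cls: list(ds.truth.index[ds.truth["class_label"] == cls])
              for cls in ds.truth["class_label"].unique()}
    groups = group_mean_profiles(median.dropna(), labels)
    groups.to_csv(args.out_dir / "group_profiles.csv")
    print("\nMean G1-normalised profile per trajectory class:")
    print(groups.round(2).to_string())

    folds = per_protein_fold(median.dropna())
    folds.to_csv(args.out_dir / "per_protein_folds.csv")
    peak = folds.join(ds.truth["class_label"]).groupby("class_label")["fold"].median()
    print("\nMedian max/min fold change per class:")
    print(peak.round(2).to_string())


if __name__ == "__main__":
    main()
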