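#!/usr/bin/env python
"""Phosphosite dynamics: residues, CDK motifs, k=6 clusters, early risers.

Simulates a TMT-quantified phosphoproteome over the G1/S/G2/M sorted
fractions with planted temporal classes (early risers already elevated in
the G2-enriched fraction and maximal in M, late risers flat until M, and
flat sites), then reports residue frequencies (pS/pT/pY), proline-directed
and full CDK consensus ([S/T]-P-x-[K/R]) motif frequencies, a k = 6
k-means clustering of the site profiles, the early/late riser
classification against ground truth, Fisher's exact enrichment of the full
CDK motif among early risers, and the mean M-phase ratio of early vs late
risers.

Writes site tables, cluster assignments and summary JSON under
results/phospho/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from primmus.dynamics import (classify_early_risers, compare_early_late,
                              fisher_enrichment, kmeans_cluster, motif_match,
                              prepare_profiles, residue_frequencies)
from primmus.quant import replicate_median_profile
from primmus.simulate import SimulationConfig, simulate_phosphosites


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results/phospho"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed)
    meta, quant, truth = simulate_phosphosites(cfg)

    res = residue_frequencies(meta)
    motifs = pd.DataFrame([motif_match(w) for w in meta["sequence_window"]],
                          index=meta.index)
    print("Residue frequencies:", {k: round(v, 3) for k, v in res.items()})
    print(f"Proline-directed sites: {motifs['proline_directed'].mean():.1%}; "
          f"full CDK consensus: {motifs['full_cdk_consensus'].mean():.1%}")

    median = replicate_median_profile(quant)
    profiles = prepare_profiles(median)
    assignment = kmeans_cluster(profiles, k=6, seed=args.seed)
    assignment.labels.to_frame().join(truth["class_label"]).to_csv(
        args.out_dir / "site_clusters.csv")
    centro = assignment.centroids
    peaks_m = [int(c) for c in centro.index if centro.loc[c].idxmax() == "M"]
    m_peak_frac = assignment.labels.isin(peaks_m).mean()
    print(f"k=6 clustering: clusters peaking in M hold {m_peak_frac:.0%} of sites")

    significant = (median.max(axis=1) / median.min(axis=1)) > 2.0
    labels = classify_early_risers(quant, significant)
    labels.to_frame().join(meta).join(truth["class_label"]).to_csv(
        args.out_dir / "early_risers.csv")
    n_early = int((labels == "early").sum())
    agree = (labels[truth["class_label"] == "early_riser"] == "early").mean()
    print(f"Early risers called: {n_early} "
          f"(sensitivity vs planted labels {agree:.2f})")

    early_ids = labels.index[labels == "early"]
    riser_ids = labels.index[labels.isin(["early", "late"])]
    enrich = fisher_enrichment(
        early_ids, riser_ids,
        {"full_cdk_consensus": motifs.index[motifs["full_cdk_consensus"]]})
    enrich.to_csv(args.out_dir / "motif_enrichment.csv")
    row = enrich.loc["full_cdk_consensus"]
    print(f"Full CDK motif in early vs all risers: odds ratio "
          f"{row['odds_ratio']:.1f}, p = {row['p_value']:.2e}")

    comparison = compare_early_late(quant, labels)
    comparison.to_csv(args.out_dir / "early_vs_late_m_ratio.csv")
    summary = {
        "residue_frequencies": {k: float(v) for k, v in res.items()},
        "proline_directed_fraction": float(motifs["proline_directed"].mean()),
        "full_cdk_fraction": float(motifs["full_cdk_consensus"].mean()),
        "n_early_risers": n_early,
        "m_ratio_difference_log2": float(comparison.attrs["difference"]),
    }
    (args.out_dir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"Early risers' mean M-phase log2 ratio exceeds late risers' by "
          f"{comparison.attrs['difference']:.2f}")


if __name__ == "__main__":
    main()
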