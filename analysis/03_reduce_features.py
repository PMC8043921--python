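#!/usr/bin/env python
"""Cluster the cohort's radiomic features and pick screened representatives.

Average-linkage clustering on the 1-|Spearman rho| distance, cut at 60% of
the maximum linkage; one representative per cluster by lowest univariable
LRT p, screened at p < 0.2.  Writes clusters to results/clusters.json and a
feature dendrogram to results/feature_dendrogram.svg.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
from scipy.cluster.hierarchy import dendrogram

from petradiomics.reduction import cluster_patients, reduce_features

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    data = pd.read_csv(ROOT / "scratch" / "cohort.csv")
    feats = data[[c for c in data.columns if c.startswith("feat_")]]
    red = reduce_features(feats, data["response"].to_numpy())
    assign = red["assignment"]
    payload = {
        "n_clusters": assign.n_clusters,
        "cut_height": assign.cut_height,
        "assignment": assign.assignment.to_dict(),
        "representatives": red["representatives"].reset_index().to_dict("records"),
        "selected": red["selected"],
    }
    (RESULTS / "clusters.json").write_text(json.dumps(payload, indent=2))

    _, passign = cluster_patients(feats)
    print(f"{assign.n_clusters} feature clusters at the 0.6 cut "
          f"(cut height {assign.cut_height:.3f}); "
          f"{passign.n_clusters} patient clusters")
    print("representatives (feature, LRT p, kept):")
    for rec in payload["representatives"]:
        print(f"  {rec['feature']:>14s}  p={rec['p']:.3f}  keep={rec['keep']}")
    print(f"screened representatives entering L1 selection: {red['selected']}")

    fig, ax = plt.subplots(figsize=(9, 4))
    dendrogram(red["dendrogram"].linkage_matrix, ax=ax, no_labels=True,
               color_threshold=assign.cut_height)
    ax.axhline(assign.cut_height, ls="--", c="gray", lw=0.8)
    ax.set_ylabel("average linkage (1 - |Spearman rho|)")
    ax.set_title("Radiomic feature dendrogram, cut at 0.6 x max linkage")
    fig.tight_layout()
    fig.savefig(RESULTS / "feature_dendrogram.svg")
    print(f"wrote {RESULTS/'clusters.json'} and feature_dendrogram.svg")


if __name__ == "__main__":
    main()
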