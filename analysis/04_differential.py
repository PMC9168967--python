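#!/usr/bin/env python
"""Differential site-specific glycosylation analysis.

Categorizes every quantified glycopeptide (twofold cutoff), summarizes
structural feature frequencies per category, and exports the PCA
coordinates and clustering order used for expression heatmaps.  Writes
results/categories.tsv, results/feature_frequencies.tsv, results/pca.tsv
and results/cluster_order.tsv.
"""

import argparse
import pathlib

import numpy as np
import pandas as pd

from glycosite import diff
from glycosite.spectra import STUDY_CHANNELS


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", default="results")
    ap.add_argument("--cutoff", type=float, default=2.0)
    args = ap.parse_args()

    res = pathlib.Path(args.results)
    qtable = pd.read_csv(res / "quant.tsv", sep="\t")
    categorized = diff.categorize_table(diff.add_features(qtable), cutoff=args.cutoff)
    categorized.to_csv(res / "categories.tsv", sep="\t", index=False)
    counts = categorized.category.value_counts()
    print("category counts:", counts.to_dict())

    freqs = diff.feature_frequencies(categorized)
    freqs.to_csv(res / "feature_frequencies.tsv", sep="\t", index=False)
    lac = freqs[
        (freqs.category == "icc_specific_up")
        & (freqs.feature == "has_lacdinac")
        & (freqs.value == True)  # noqa: E712
    ]
    if len(lac):
        print(f"LacdiNAc share of ICC-specific-up glycopeptides: "
              f"{lac.percent.iloc[0]:.1f}%")

    med = qtable[[f"median_{c}" for c in STUDY_CHANNELS]]
    med.columns = list(STUDY_CHANNELS)
    coords, ev = diff.pca_matrix(med)
    coords.assign(explained=np.resize(ev, len(coords))).to_csv(
        res / "pca.tsv", sep="\t"
    )
    print("PCA explained variance:", np.round(ev, 3).tolist())

    changed = categorized[categorized.category != "unchanged"]
    ratios = changed[["ICC_ICCP", "HCC_HCCP", "ICC_HCC", "ICCP_HCCP"]]
    log2fc = np.log2(ratios)
    log2fc.index = changed.peptide + "@" + changed.site.astype(str)
    _, _, ordered = diff.clustering_matrix(log2fc)
    ordered.to_csv(res / "cluster_order.tsv", sep="\t")
    print(f"clustered {len(ordered)} changed glycopeptides "
          f"(Euclidean, average linkage)")


if __name__ == "__main__":
    main()
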