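"""Unbiased categorization: Ward hierarchical clustering and heatmaps.

Reads the feature table and labels, builds the three-parameter matrix
(I_h density at -140 mV, sag at -80 pA, rebound spikes at -80 pA; all
neurons) and the six-parameter matrix (adds MFR current step, FSL at
+10 pA, first ISI at +40 pA; "Others" removed), z-scores columns, runs
Ward (ward.D2) agglomeration, cuts at k=4 and k=3 respectively, and writes
linkages, dendrograms (Newick), heatmaps (PNG + TSV) and the cluster-vs-label
agreement tables under ``results/``.
"""

import json
from pathlib import Path

import pandas as pd

from bnstephys.cluster import (build_feature_matrix, standardize,
                               ward_linkage, cut_tree, agreement,
                               export_dendrogram_newick, export_heatmap,
                               scatter3d_export)

OUT = Path(__file__).resolve().parents[1] / "results"
table = pd.read_csv(OUT / "features.tsv", sep="\t", index_col=0)
labels = pd.read_csv(OUT / "labels.tsv", sep="\t",
                     index_col=0)["label"].to_dict()

summary = {}
for pset, k in (("three", 4), ("six", 3)):
    fm = build_feature_matrix(table, pset, labels=labels)
    tree = ward_linkage(standardize(fm))
    cl = cut_tree(tree, k)
    ag = agreement(cl, labels)
    pd.DataFrame(tree.merges, columns=["a", "b", "height", "size"]).to_csv(
        OUT / f"linkage_{pset}.tsv", sep="\t", index=False)
    export_dendrogram_newick(tree, OUT / f"dendrogram_{pset}.nwk")
    export_heatmap(standardize(fm), tree, type_labels=labels,
                   path=OUT / f"heatmap_{pset}.png",
                   tsv_path=OUT / f"heatmap_{pset}.tsv")
    ag["table"].to_csv(OUT / f"agreement_{pset}.tsv", sep="\t")
    summary[pset] = {"n_rows": len(fm.values), "dropped": fm.dropped,
                     "k": k, "purity": ag["purity"],
                     "majority": ag["majority"]}
    print(f"{pset}-parameter set: {len(fm.values)} neurons, k={k}, "
          f"majority types {ag['majority']}, purity {ag['purity']}")

scatter3d_export(table, labels).to_csv(OUT / "scatter3d.tsv", sep="\t")
with open(OUT / "cluster_summary.json", "w") as fh:
    json.dump(summary, fh, indent=1, sort_keys=True)
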