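"""Unbiased categorization: Ward hierarchical clustering of feature matrices.

Two standard parameter sets are defined:

* ``three``: I_h at -140 mV, voltage sag at -80 pA, rebound spikes at -80 pA;
* ``six``: the three above plus the current step giving the maximum firing
  rate, first spike latency at +10 pA, and first ISI at +40 pA.  Neurons
  labeled "Others" are excluded a priori from the six-parameter analysis
  (they lack the latency/ISI values at low current steps by definition of
  their late-firing phenotype).

Rows with any missing selected parameter are dropped (and reported).
Clustering is agglomerative Ward on Euclidean distances (the ward.D2
variant: each merge minimizes the increase in total within-cluster variance,
heights are root-squared and monotone non-decreasing).  Columns are z-scored
by default because the six parameters mix pA, mV, ms and counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

PARAMETER_SETS = {
    "three": ["ih_density_-140mV", "sag_-80pA", "rebound_-80pA"],
    "six": ["ih_density_-140mV", "sag_-80pA", "rebound_-80pA",
            "mfr_step", "fsl_+10pA", "first_isi_+40pA"],
}

SCATTER3D_COLUMNS = ["evoked_spikes_+60pA", "rebound_-80pA", "sag_-80pA"]


@dataclass
class FeatureMatrix:
    values: pd.DataFrame                   # rows: neurons, columns: parameters
    dropped: list                          # neuron ids removed (missing values)
    scaled: bool = False
    col_mean: Optional[pd.Series] = None
    col_sd: Optional[pd.Series] = None


@dataclass
class LinkageTree:
    """Agglomeration history in scipy linkage convention.

    Row i of ``merges`` is (id_a, id_b, height, size); leaves are 0..n-1 and
    the cluster created by row i has id n+i.
    """

    merges: np.ndarray
    ids: list

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def leaf_order(self) -> list:
        order = hierarchy.leaves_list(self.merges)
        return [self.ids[i] for i in order]


def build_feature_matrix(
    table: pd.DataFrame,
    parameter_set: str = "three",
    labels: Optional[dict] = None,
) -> FeatureMatrix:
    """Select the named parameter columns and drop incomplete rows.

    ``labels`` (neuron id -> type label string) is required for the
    six-parameter set so Others can be removed a priori.
    """
    if parameter_set not in PARAMETER_SETS:
        raise ValueError(f"unknown parameter set {parameter_set!r}")
    cols = PARAMETER_SETS[parameter_set]
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise ValueError(f"feature table lacks columns: {missing_cols}")
    df = table[cols].copy()
    if parameter_set == "six" and labels is not None:
        keep = [i for i in df.index if labels.get(i) != "Others"]
        df = df.loc[keep]
    complete = df.dropna()
    dropped = sorted(set(df.index) - set(complete.index))
    return FeatureMatrix(values=complete.astype(float), dropped=dropped)


def standardize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Per-column z-score; errors on constant columns."""
    df = matrix.values
    sd = df.std(axis=0, ddof=1)
    bad = sd.index[(sd == 0) | sd.isna()].tolist()
    if bad:
        raise ValueError(f"constant column(s): {bad}")
    mean = df.mean(axis=0)
    return FeatureMatrix(values=(df - mean) / sd, dropped=matrix.dropped,
                         scaled=True, col_mean=mean, col_sd=sd)


def unstandardize(matrix: FeatureMatrix) -> pd.DataFrame:
    if not matrix.scaled:
        return matrix.values
    return matrix.values * matrix.col_sd + matrix.col_mean


def ward_linkage(matrix: FeatureMatrix | pd.DataFrame | np.ndarray) -> LinkageTree:
    """Ward (ward.D2) agglomeration of the rows.

    Ties between equal-cost merges break to the lowest-index pair, which
    makes the merge sequence deterministic given the input row order.
    """
    if isinstance(matrix, FeatureMatrix):
        df = matrix.values
        X = df.to_numpy(dtype=float)
        ids = list(df.index)
    elif isinstance(matrix, pd.DataFrame):
        X = matrix.to_numpy(dtype=float)
        ids = list(matrix.index)
    else:
        X = np.asarray(matrix, dtype=float)
        ids = list(range(X.shape[0]))
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    Z = hierarchy.linkage(X, method="ward")
    return LinkageTree(merges=Z, ids=ids)


def cut_tree(tree: LinkageTree, k: int) -> dict:
    """Partition into k clusters; returns neuron id -> cluster label (1..k)."""
    if not (1 <= k <= tree.n_leaves):
        raise ValueError(f"k must be in [1, {tree.n_leaves}]")
    flat = hierarchy.fcluster(tree.merges, t=k, criterion="maxclust")
    return {i: int(c) for i, c in zip(tree.ids, flat)}


def agreement(cluster_labels: dict, type_labels: dict) -> dict:
    """Contingency table and per-cluster purity of clusters vs type labels."""
    ids = [i for i in cluster_labels if i in type_labels]
    tab = pd.crosstab(
        pd.Series({i: cluster_labels[i] for i in ids}, name="cluster"),
        pd.Series({i: type_labels[i] for i in ids}, name="type"),
    )
    purity = {}
    majority = {}
    for c in tab.index:
        row = tab.loc[c]
        purity[int(c)] = float(row.max() / row.sum())
        majority[int(c)] = str(row.idxmax())
    return {"table": tab, "purity": purity, "majority": majority}


# ---------------------------------------------------------------------------
# exports

def export_dendrogram_newick(tree: LinkageTree, path=None) -> str:
    """Serialize the linkage as an ultrametric Newick string.

    Each internal node sits at half its merge height, so a 2-leaf tree with
    merge height 2h becomes ``(a:h,b:h);``.
    """
    n = tree.n_leaves
    heights = {i: 0.0 for i in range(n)}
    children = {}
    for i, (a, b, h, _s) in enumerate(tree.merges):
        node = n + i
        children[node] = (int(a), int(b))
        heights[node] = h / 2.0

    def fmt(node: int, parent_h: float) -> str:
        bl = parent_h - heights[node]
        if node < n:
            return f"{tree.ids[node]}:{bl:.10g}"
        a, b = children[node]
        h = heights[node]
        return f"({fmt(a, h)},{fmt(b, h)}):{bl:.10g}"

    root = n + len(tree.merges) - 1
    a, b = children[root]
    h = heights[root]
    s = f"({fmt(a, h)},{fmt(b, h)});"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def export_heatmap(
    matrix: FeatureMatrix,
    tree: LinkageTree,
    type_labels: Optional[dict] = None,
    path=None,
    tsv_path=None,
) -> pd.DataFrame:
    """Row-ordered (by dendrogram leaf order) scaled matrix; optional PNG/TSV."""
    order = tree.leaf_order()
    df = matrix.values.loc[order]
    if tsv_path is not None:
        out = df.copy()
        if type_labels is not None:
            out.insert(0, "type", [type_labels.get(i, "") for i in out.index])
        out.to_csv(tsv_path, sep="\t")
    if path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(6, max(3, 0.08 * len(df) + 1.5)), dpi=110)
        im = ax.imshow(df.to_numpy(), aspect="auto", cmap="RdBu_r",
                       interpolation="nearest")
        ax.set_xticks(range(df.shape[1]))
        ax.set_xticklabels(df.columns, rotation=45, ha="right", fontsize=7)
        ax.set_yticks([])
        ax.set_ylabel(f"{len(df)} neurons (dendrogram leaf order)")
        fig.colorbar(im, ax=ax, label="z-score" if matrix.scaled else "value")
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)
    return df


def scatter3d_export(table: pd.DataFrame, labels: Optional[dict] = None
                     ) -> pd.DataFrame:
    """Raw-value table for the 3D scatter (evoked spikes at +60 pA, rebound
    spikes at -80 pA, sag at -80 pA); rows with any missing value dropped."""
    missing = [c for c in SCATTER3D_COLUMNS if c not in table.columns]
    if missing:
        if table.empty:
            return pd.DataFrame(columns=SCATTER3D_COLUMNS)
        raise ValueError(f"feature table lacks columns: {missing}")
    df = table[SCATTER3D_COLUMNS].dropna().copy()
    if labels is not None:
        df["type"] = [labels.get(i, "") for i in df.index]
    return df
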