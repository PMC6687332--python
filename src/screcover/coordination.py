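"""Coordinated fold-change structure across clusters and cluster-composition
shifts across conditions.

The coordinated-change analysis collects genes with at least a 1.5-fold
(and significant) obesity response in any leukocyte cluster, assembles
their log fold changes across *all* clusters, and orders them by
agglomerative hierarchical clustering to expose shared response modules.
Composition analysis tracks each cluster's share of cells per condition
and classifies its post-CR trajectory with the same three-way rule used
for genes, plus an Unchanged class for clusters obesity never shifted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .recovery import ClassifierParams, classify_gene

__all__ = [
    "coordinated_logfc_matrix",
    "hierarchical_cluster_genes",
    "GeneClustering",
    "cluster_composition",
    "composition_recovery",
    "COMPOSITION_CATEGORIES",
]

COMPOSITION_CATEGORIES = ("RevertedToLean", "RemainedShifted", "UniqueToCR", "Unchanged")


def coordinated_logfc_matrix(
    results: Mapping[tuple[str, str], pd.DataFrame | None],
    contrast: str = "obese_vs_lean",
    fold_threshold: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genes x clusters logFC matrix for one contrast.

    Rows are genes with |logFC| >= ln(fold_threshold) *and* adjusted
    p < alpha in at least one cluster; entries are the (unthresholded)
    logFC in every cluster, NaN where the cluster was not assessed.
    """
    per_cluster = {cl: df for (cl, nm), df in results.items() if nm == contrast}
    if not per_cluster:
        raise ValueError(f"no results for contrast {contrast!r}")
    cut = np.log(fold_threshold)
    keep: set[str] = set()
    for df in per_cluster.values():
        if df is None:
            continue
        hits = df[(df["logFC"].abs() >= cut) & (df["p_adj"] < alpha)]
        keep |= set(hits["gene"])
    if not keep:
        warnings.warn("no gene passes the fold threshold; matrix is empty")
        return pd.DataFrame(columns=sorted(per_cluster))
    genes = sorted(keep)
    cols = {}
    for cl in sorted(per_cluster):
        df = per_cluster[cl]
        if df is None:
            cols[cl] = pd.Series(np.nan, index=genes)
        else:
            cols[cl] = df.set_index("gene")["logFC"].reindex(genes)
    return pd.DataFrame(cols, index=genes)


@dataclass
class GeneClustering:
    linkage_matrix: np.ndarray
    leaf_order: list[str]
    labels: pd.Series  # gene -> flat cluster id
    imputed: list[str]  # genes with NaN entries imputed as 0
    singletons: list[str]  # constant rows set aside under correlation metric


def hierarchical_cluster_genes(
    matrix: pd.DataFrame,
    linkage: str = "complete",
    metric: str = "euclidean",
    n_clusters: int = 2,
) -> GeneClustering:
    """Agglomerative clustering of logFC rows; deterministic given input.

    Missing entries (NotAssessed clusters) are imputed as 0 and flagged.
    Under the correlation metric, constant rows (undefined distance) are
    set aside as singleton clusters with a warning.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 gene rows to cluster")
    M = matrix.to_numpy(dtype=float)
    imputed = list(matrix.index[np.isnan(M).any(axis=1)])
    M = np.nan_to_num(M, nan=0.0)
    names = list(matrix.index)
    singles: list[str] = []
    if metric == "correlation":
        const = M.std(axis=1) == 0
        if const.any():
            singles = [names[i] for i in np.flatnonzero(const)]
            warnings.warn(f"{len(singles)} constant rows set aside as singleton clusters")
            keepers = np.flatnonzero(~const)
            M = M[keepers]
            names = [names[i] for i in keepers]
    if len(names) < 2:
        raise ValueError("fewer than 2 clusterable rows")
    Z = sch.linkage(ssd.pdist(M, metric=metric), method=linkage)
    order = [names[i] for i in sch.leaves_list(Z)]
    flat = sch.fcluster(Z, t=max(1, n_clusters - len(singles)), criterion="maxclust")
    labels = pd.Series(flat, index=names, name="gene_cluster")
    next_id = labels.max() + 1 if len(labels) else 1
    for g in singles:
        labels.loc[g] = next_id
        order.append(g)
        next_id += 1
    return GeneClustering(
        linkage_matrix=Z, leaf_order=order, labels=labels, imputed=imputed, singletons=singles
    )


def cluster_composition(cells: pd.DataFrame) -> pd.DataFrame:
    """Cluster x condition matrix of cell proportions among QC-passing cells.

    Columns sum to 1; clusters absent from a condition get exactly 0.
    Conditions with zero cells are omitted with a warning.
    """
    df = cells
    if "qc_pass" in df.columns:
        df = df[df["qc_pass"].astype(bool)]
    tab = pd.crosstab(df["cluster"].astype(str), df["condition"].astype(str))
    for cond in list(tab.columns):
        if tab[cond].sum() == 0:
            warnings.warn(f"condition {cond!r} has no cells; column omitted")
            tab = tab.drop(columns=cond)
    if tab.empty:
        raise ValueError("no QC-passing cells")
    return tab / tab.sum(axis=0)


def composition_recovery(
    composition: pd.DataFrame, params: ClassifierParams | None = None
) -> pd.DataFrame:
    """Classify each cluster's proportion trajectory across conditions.

    Reuses the gene-level three-way rule on the triple (p_lean, p_obese,
    p_CR): Recovered -> RevertedToLean, NotRecovered -> RemainedShifted,
    Different -> UniqueToCR. Clusters whose obese share differs from lean
    by a relative difference <= tau are Unchanged.
    """
    params = params or ClassifierParams()
    for cond in ("lean", "obese", "CR"):
        if cond not in composition.columns:
            raise ValueError(f"composition table lacks condition {cond!r}")
    rows = []
    rename = dict(zip(("Recovered", "NotRecovered", "Different"), COMPOSITION_CATEGORIES[:3]))
    for cl, row in composition.iterrows():
        p_l, p_o, p_c = float(row["lean"]), float(row["obese"]), float(row["CR"])
        if p_l == 0 and p_o == 0 and p_c == 0:
            continue
        rel_shift = abs(p_o - p_l) / max(p_l, params.epsilon)
        if rel_shift <= params.tau:
            cat = "Unchanged"
        else:
            cat = rename[classify_gene(p_l, p_o, p_c, params)]
        rows.append((cl, p_l, p_o, p_c, cat))
    return pd.DataFrame(rows, columns=["cluster", "p_lean", "p_obese", "p_CR", "category"])
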