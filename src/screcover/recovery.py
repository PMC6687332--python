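"""Post-weight-loss gene-expression recovery stratification.

After caloric restriction (CR), each differentially expressed gene is
classified per cluster by where its CR mean expression C sits relative to
the lean mean L and the obese mean O (all on the de-logged normalized mean
scale):

* **Different** — C lies outside [min(L, O), max(L, O)] and its relative
  distance to *both* L and O exceeds the threshold tau (default 10%).
* **Recovered** — otherwise, C is strictly closer to L than to O.
* **NotRecovered** — otherwise, C is strictly closer to O (exact ties are
  conservatively called NotRecovered).

Clusters lacking enough cells in any condition (the absent-in-lean cluster)
are NotAssessed. The gene universe is every gene significantly DE in at
least one pairwise condition contrast in at least one cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from . import de as de_mod
from .de import DEFAULT_CONTRASTS, condition_stats, contrast_name

__all__ = [
    "ClassifierParams",
    "classify_gene",
    "classify_many",
    "select_recovery_genes",
    "build_recovery_table",
    "recovery_proportions",
    "cluster_overlap_distribution",
    "RECOVERY_CATEGORIES",
]

RECOVERY_CATEGORIES = ("Recovered", "NotRecovered", "Different")
NOT_ASSESSED = "NotAssessed"


@dataclass
class ClassifierParams:
    """tau: relative-difference threshold for the Different call (0.10 =
    'more than 10% different from both'); epsilon: denominator floor on the
    de-logged mean scale; alpha: significance level for gene selection."""

    tau: float = 0.10
    epsilon: float = 1e-6
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.tau < 1.0):
            raise ValueError("tau must lie in (0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def classify_many(
    L: np.ndarray, O: np.ndarray, C: np.ndarray, params: ClassifierParams | None = None
) -> np.ndarray:
    """Vectorized recovery classification of (L, O, C) mean triples."""
    params = params or ClassifierParams()
    L = np.asarray(L, dtype=float)
    O = np.asarray(O, dtype=float)
    C = np.asarray(C, dtype=float)
    if (L < 0).any() or (O < 0).any() or (C < 0).any():
        raise ValueError("condition means must be nonnegative")
    lo = np.minimum(L, O)
    hi = np.maximum(L, O)
    intermediate = (lo <= C) & (C <= hi)
    rel_l = np.abs(C - L) / np.maximum(np.abs(L), params.epsilon)
    rel_o = np.abs(C - O) / np.maximum(np.abs(O), params.epsilon)
    different = ~intermediate & (rel_l > params.tau) & (rel_o > params.tau)
    closer_lean = np.abs(C - L) < np.abs(C - O)
    out = np.where(
        different, "Different", np.where(closer_lean, "Recovered", "NotRecovered")
    )
    return out.astype(object)


def classify_gene(L: float, O: float, C: float, params: ClassifierParams | None = None) -> str:
    """Classify one gene's (lean, obese, CR) mean triple."""
    return str(classify_many(np.array([L]), np.array([O]), np.array([C]), params)[0])


def _check_contrast_families(
    results: Mapping[tuple[str, str], pd.DataFrame | None],
    contrasts: Sequence[tuple[str, str]],
) -> list[str]:
    clusters = sorted({cl for cl, _ in results})
    names = [contrast_name(a, b) for a, b in contrasts]
    for cl in clusters:
        for nm in names:
            if (cl, nm) not in results:
                raise ValueError(f"missing contrast family {nm!r} for cluster {cl!r}")
    return clusters


def select_recovery_genes(
    results: Mapping[tuple[str, str], pd.DataFrame | None],
    alpha: float = 0.05,
    contrasts: Sequence[tuple[str, str]] = DEFAULT_CONTRASTS,
) -> list[str]:
    """Genes with adjusted p < alpha in >= 1 pairwise contrast in >= 1 cluster."""
    _check_contrast_families(results, contrasts)
    selected: set[str] = set()
    for df in results.values():
        if df is None:
            continue
        selected |= set(df.loc[df["p_adj"] < alpha, "gene"])
    return sorted(selected)


def build_recovery_table(
    adata: ad.AnnData,
    genes: Iterable[str],
    params: ClassifierParams | None = None,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Classify each selected gene in each cluster.

    Returns a long table (gene, cluster, L, O, C, category). Clusters where
    any condition has fewer than ``min_cells`` QC-passing cells contribute
    only NotAssessed rows with NaN means.
    """
    params = params or ClassifierParams()
    genes = list(genes)
    if not genes:
        warnings.warn("empty gene set; recovery table is empty")
        return pd.DataFrame(columns=["gene", "cluster", "L", "O", "C", "category"])
    gidx = [adata.var_names.get_loc(g) for g in genes]
    obs = adata.obs
    passing = obs["qc_pass"].to_numpy(bool) if "qc_pass" in obs else np.ones(adata.n_obs, bool)
    clusters = obs["cluster"].astype(str).to_numpy()
    cond = obs["condition"].astype(str).to_numpy()
    rows = []
    for cl in sorted(np.unique(clusters[passing])):
        idx = {c: np.flatnonzero(passing & (clusters == cl) & (cond == c)) for c in ("lean", "obese", "CR")}
        if any(len(v) < min_cells for v in idx.values()):
            for g in genes:
                rows.append((g, cl, np.nan, np.nan, np.nan, NOT_ASSESSED))
            continue
        means = {c: condition_stats(adata, idx[c])["mean"].to_numpy()[gidx] for c in idx}
        cats = classify_many(means["lean"], means["obese"], means["CR"], params)
        for j, g in enumerate(genes):
            rows.append((g, cl, means["lean"][j], means["obese"][j], means["CR"][j], cats[j]))
    return pd.DataFrame(rows, columns=["gene", "cluster", "L", "O", "C", "category"])


def recovery_proportions(
    table: pd.DataFrame,
    denominator_rule: str = "obese_de_only",
    obese_de: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Per-cluster fraction of each recovery category.

    denominator_rule 'obese_de_only' restricts, per cluster, to genes
    differentially expressed in the obese-vs-lean contrast of that cluster
    (requires ``obese_de``: cluster -> gene set); 'all_selected' uses every
    assessed gene. Clusters with zero assessed genes are omitted.
    """
    if denominator_rule not in {"obese_de_only", "all_selected"}:
        raise ValueError(f"unknown denominator rule {denominator_rule!r}")
    if denominator_rule == "obese_de_only" and obese_de is None:
        raise ValueError("obese_de_only rule requires per-cluster obese-vs-lean DE gene sets")
    if table.empty:
        raise ValueError("recovery table is empty")
    rows = []
    for cl, sub in table.groupby("cluster", observed=True):
        assessed = sub[sub["category"] != NOT_ASSESSED]
        if denominator_rule == "obese_de_only":
            assessed = assessed[assessed["gene"].isin(set(obese_de.get(cl, ())))]
        n = len(assessed)
        if n == 0:
            warnings.warn(f"cluster {cl!r} has no assessed genes in the denominator; omitted")
            continue
        counts = assessed["category"].value_counts()
        rows.append(
            [cl, n] + [counts.get(c, 0) / n for c in RECOVERY_CATEGORIES]
        )
    return pd.DataFrame(
        rows, columns=["cluster", "n_genes", "frac_recovered", "frac_not_recovered", "frac_different"]
    )


def cluster_overlap_distribution(table: pd.DataFrame) -> pd.DataFrame:
    """For each category, how many clusters share it per gene.

    Returns a long table (category, n_clusters, n_genes): the histogram
    over genes of the number of clusters in which the gene carries that
    category (genes with zero such clusters do not contribute).
    """
    assessed = table[table["category"].isin(RECOVERY_CATEGORIES)]
    rows = []
    for cat in RECOVERY_CATEGORIES:
        counts = assessed[assessed["category"] == cat].groupby("gene", observed=True).size()
        hist = counts.value_counts().sort_index()
        for n_cl, n_genes in hist.items():
            rows.append((cat, int(n_cl), int(n_genes)))
    return pd.DataFrame(rows, columns=["category", "n_clusters", "n_genes"])
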