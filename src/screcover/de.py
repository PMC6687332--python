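"""Per-cluster pairwise differential expression and marker detection.

For every gene within a cluster, expression is compared between two
condition groups with the two-sided Wilcoxon rank-sum test on normalized
values (exact for small untied groups, otherwise normal approximation with
midrank tie correction and continuity correction), and p-values are
Benjamini-Hochberg adjusted within each (cluster, contrast) family. Log
fold changes are natural logs of de-logged group means with a pseudocount
of 1; no gene is excluded by effect-size or percent-expressing thresholds,
so fold changes remain interrogable even where significance is unreachable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qc import LOGNORM_LAYER

__all__ = [
    "MarkerParams",
    "wilcoxon_test",
    "bh_adjust",
    "condition_stats",
    "de_contrast",
    "de_all_contrasts",
    "find_markers",
    "DEFAULT_CONTRASTS",
    "contrast_name",
]

DEFAULT_CONTRASTS = (("obese", "lean"), ("CR", "lean"), ("CR", "obese"))


def contrast_name(cond_a: str, cond_b: str) -> str:
    return f"{cond_a}_vs_{cond_b}"


@dataclass
class MarkerParams:
    """Marker-gene rule: expressed in >= min_pct of the cluster's cells,
    higher in the cluster than in the rest, significant at alpha."""

    min_pct: float = 0.25
    up_only: bool = True
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_pct <= 1.0):
            raise ValueError("min_pct must lie in [0, 1]")


def wilcoxon_test(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value for one gene.

    Exact enumeration when min(n_a, n_b) <= 8 and there are no ties;
    otherwise the normal approximation with midrank tie correction and
    continuity correction. Zero rank variance (all values identical)
    yields p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if min(a.size, b.size) <= 8 and not has_ties:
        return float(stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
    if np.ptp(combined) == 0:
        return 1.0
    return float(
        stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
    )


def _ranksum_p_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Vectorized asymptotic rank-sum p for each column (gene).

    A: (n_a, G), B: (n_b, G). Matches the scalar asymptotic path of
    :func:`wilcoxon_test` (midrank ties, tie-corrected variance,
    continuity correction).
    """
    na, nb = A.shape[0], B.shape[0]
    n = na + nb
    combined = np.vstack([A, B])
    ranks = stats.rankdata(combined, axis=0)
    R_a = ranks[:na].sum(axis=0)
    U = R_a - na * (na + 1) / 2.0
    mean_U = na * nb / 2.0
    # per-gene tie correction sum(t^3 - t)
    s = np.sort(combined, axis=0)
    tie_term = np.zeros(combined.shape[1])
    for j in range(combined.shape[1]):
        _, counts = np.unique(s[:, j], return_counts=True)
        t = counts[counts > 1].astype(float)
        tie_term[j] = (t**3 - t).sum()
    var_U = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    z = np.zeros_like(U)
    ok = var_U > 0
    z[ok] = (np.abs(U[ok] - mean_U) - 0.5).clip(min=0) / np.sqrt(var_U[ok])
    p = np.where(ok, 2.0 * stats.norm.sf(z), 1.0)
    return np.minimum(p, 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _dense_layer(adata: ad.AnnData, idx: np.ndarray) -> np.ndarray:
    if LOGNORM_LAYER not in adata.layers:
        raise ValueError("normalized layer missing; run qc.normalize first")
    return np.asarray(sp.csr_matrix(adata.layers[LOGNORM_LAYER])[idx].todense())


def condition_stats(adata: ad.AnnData, cell_idx: np.ndarray) -> pd.DataFrame:
    """Per-gene mean de-logged normalized expression and detection rate.

    mean = average over cells of expm1(lognorm value); pct = fraction of
    cells with raw count > 0.
    """
    cell_idx = np.asarray(cell_idx)
    if cell_idx.size == 0:
        raise ValueError("cell subset is empty")
    vals = _dense_layer(adata, cell_idx)
    raw = sp.csr_matrix(adata.X)[cell_idx]
    mean = np.expm1(vals).mean(axis=0)
    pct = np.asarray((raw > 0).mean(axis=0)).ravel()
    return pd.DataFrame({"gene": adata.var_names, "mean": mean, "pct": pct}).set_index(
        "gene", drop=False
    )


def _contrast_frame(
    adata: ad.AnnData,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    cluster: str,
    name: str,
) -> pd.DataFrame:
    stats_a = condition_stats(adata, idx_a)
    stats_b = condition_stats(adata, idx_b)
    A = _dense_layer(adata, idx_a)
    B = _dense_layer(adata, idx_b)
    if min(len(idx_a), len(idx_b)) <= 8:
        p_raw = np.array([wilcoxon_test(A[:, j], B[:, j]) for j in range(A.shape[1])])
    else:
        p_raw = _ranksum_p_matrix(A, B)
    logfc = np.log((stats_a["mean"].to_numpy() + 1.0) / (stats_b["mean"].to_numpy() + 1.0))
    return pd.DataFrame(
        {
            "gene": adata.var_names,
            "cluster": cluster,
            "contrast": name,
            "logFC": logfc,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
            "mean_a": stats_a["mean"].to_numpy(),
            "mean_b": stats_b["mean"].to_numpy(),
            "pct_a": stats_a["pct"].to_numpy(),
            "pct_b": stats_b["pct"].to_numpy(),
        }
    )


def de_contrast(
    adata: ad.AnnData,
    cluster: str,
    cond_a: str,
    cond_b: str,
    min_cells: int = 3,
) -> pd.DataFrame | None:
    """All-gene DE for one cluster and ordered condition pair.

    Returns None (NotAssessed) when either group has fewer than
    ``min_cells`` QC-passing cells — the absent-in-lean situation.
    """
    obs = adata.obs
    passing = obs["qc_pass"].to_numpy(bool) if "qc_pass" in obs else np.ones(adata.n_obs, bool)
    in_cluster = obs["cluster"].astype(str).to_numpy() == str(cluster)
    cond = obs["condition"].astype(str).to_numpy()
    idx_a = np.flatnonzero(passing & in_cluster & (cond == cond_a))
    idx_b = np.flatnonzero(passing & in_cluster & (cond == cond_b))
    if len(idx_a) < min_cells or len(idx_b) < min_cells:
        return None
    return _contrast_frame(adata, idx_a, idx_b, str(cluster), contrast_name(cond_a, cond_b))


def de_all_contrasts(
    adata: ad.AnnData,
    contrasts: Sequence[tuple[str, str]] = DEFAULT_CONTRASTS,
    min_cells: int = 3,
) -> dict[tuple[str, str], pd.DataFrame | None]:
    """Run every contrast in every cluster; None marks NotAssessed."""
    results: dict[tuple[str, str], pd.DataFrame | None] = {}
    clusters = sorted(adata.obs["cluster"].astype(str).unique())
    for cl in clusters:
        for cond_a, cond_b in contrasts:
            results[(cl, contrast_name(cond_a, cond_b))] = de_contrast(
                adata, cl, cond_a, cond_b, min_cells=min_cells
            )
    return results


def contrasts_to_frame(results: Mapping[tuple[str, str], pd.DataFrame | None]) -> pd.DataFrame:
    """Long-format table of all assessed contrasts."""
    frames = [df for df in results.values() if df is not None]
    if not frames:
        return pd.DataFrame(
            columns=["gene", "cluster", "contrast", "logFC", "p_raw", "p_adj", "mean_a", "mean_b", "pct_a", "pct_b"]
        )
    return pd.concat(frames, ignore_index=True)


def find_markers(adata: ad.AnnData, params: MarkerParams | None = None) -> pd.DataFrame:
    """One-vs-rest marker genes per cluster.

    Keeps genes expressed in >= min_pct of the cluster's cells with
    positive logFC and p_adj < alpha, ranked by logFC descending.
    """
    params = params or MarkerParams()
    obs = adata.obs
    passing = obs["qc_pass"].to_numpy(bool) if "qc_pass" in obs else np.ones(adata.n_obs, bool)
    clusters = obs["cluster"].astype(str).to_numpy()
    labels = sorted(np.unique(clusters[passing]))
    if len(labels) < 2:
        raise ValueError("marker detection needs at least 2 clusters")
    out = []
    for cl in labels:
        idx_in = np.flatnonzero(passing & (clusters == cl))
        idx_out = np.flatnonzero(passing & (clusters != cl))
        if len(idx_in) < 3:
            warnings.warn(f"cluster {cl!r} has <3 cells; skipped")
            continue
        df = _contrast_frame(adata, idx_in, idx_out, cl, "cluster_vs_rest")
        keep = (df["pct_a"] >= params.min_pct) & (df["p_adj"] < params.alpha)
        if params.up_only:
            keep &= df["logFC"] > 0
        df = df[keep].sort_values("logFC", ascending=False)
        out.append(df)
    if not out:
        return pd.DataFrame()
    return pd.concat(out, ignore_index=True).rename(
        columns={"pct_a": "pct_in", "pct_b": "pct_out"}
    )
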