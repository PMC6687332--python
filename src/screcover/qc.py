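"""Per-cell quality control, outlier removal and depth normalization.

The QC philosophy follows droplet scRNA-seq practice for this kind of
experiment: only *high* outliers are removed — cells whose mitochondrial
fraction is high (apoptotic) or whose UMI total is high (likely doublets) —
using a one-sided median + k x scaled-MAD rule computed within each
condition sample, since each 10x run has its own depth distribution.
Clusters that do not express the pan-leukocyte marker CD45 (Ptprc) are
excluded as non-hematopoietic contamination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import scipy.sparse as sp

__all__ = ["QCParams", "compute_cell_qc", "filter_cells", "exclude_nonleukocyte_clusters", "normalize"]

LOGNORM_LAYER = "lognorm"


@dataclass
class QCParams:
    """Thresholds for cell filtering and normalization.

    mad_multiplier: k in the median + k*scaled-MAD high-outlier rule.
    mad_scale: consistency constant (1.4826 makes MAD estimate sigma for
        normal data).
    cd45_gene / cd45_min_detection: a cluster is non-leukocyte when fewer
        than this fraction of its cells detect CD45.
    scale_factor / pseudocount: ln(1 + scale_factor * count / umi_total).
    """

    mad_multiplier: float = 3.0
    mad_scale: float = 1.4826
    cd45_gene: str = "Ptprc"
    cd45_min_detection: float = 0.05
    scale_factor: float = 10000.0
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if self.mad_multiplier <= 0:
            raise ValueError("mad_multiplier must be positive")
        if not (0.0 <= self.cd45_min_detection <= 1.0):
            raise ValueError("cd45_min_detection must lie in [0, 1]")


def compute_cell_qc(adata: ad.AnnData, mito_prefix: str = "mt-") -> ad.AnnData:
    """Annotate obs with umi_total and mito_fraction; initialise qc_pass.

    Cells with zero total counts get mito_fraction 0 and qc_pass False.
    """
    X = sp.csr_matrix(adata.X)
    mito = np.array([g.startswith(mito_prefix) for g in adata.var_names])
    if not mito.any():
        warnings.warn(f"no genes match mitochondrial prefix {mito_prefix!r}; mito_fraction = 0")
    adata.var["mito"] = mito
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_total = np.asarray(X[:, mito].sum(axis=1)).ravel() if mito.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito_total / np.maximum(total, 1), 0.0)
    adata.obs["umi_total"] = total.astype(int)
    adata.obs["mito_fraction"] = frac
    adata.obs["qc_pass"] = total > 0
    adata.obs["barcode"] = adata.obs_names
    return adata


def _high_outlier_threshold(values: np.ndarray, params: QCParams) -> float:
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med + params.mad_multiplier * params.mad_scale * mad


def filter_cells(adata: ad.AnnData, params: QCParams | None = None) -> ad.AnnData:
    """Set qc_pass: fail high outliers in mito_fraction or umi_total.

    Thresholds are computed independently per condition sample. MAD = 0
    (all values equal) means no cell fails on that metric.
    """
    params = params or QCParams()
    if "umi_total" not in adata.obs:
        raise ValueError("run compute_cell_qc first")
    if adata.n_obs < 3:
        raise ValueError("need at least 3 cells to define median/MAD thresholds")
    fail = np.zeros(adata.n_obs, dtype=bool)
    cond = adata.obs["condition"].astype(str).to_numpy() if "condition" in adata.obs else np.array(["all"] * adata.n_obs)
    for c in np.unique(cond):
        sel = cond == c
        for metric in ("mito_fraction", "umi_total"):
            v = adata.obs.loc[sel, metric].to_numpy(dtype=float)
            thr = _high_outlier_threshold(v, params)
            fail[sel] |= v > thr
    adata.obs["qc_pass"] = (adata.obs["umi_total"].to_numpy() > 0) & ~fail
    return adata


def exclude_nonleukocyte_clusters(adata: ad.AnnData, params: QCParams | None = None) -> list[str]:
    """Drop clusters whose CD45 detection rate is below the cutoff.

    Returns the retained cluster labels; dropped clusters' cells get
    qc_pass False. The rule is strict less-than, so a cluster exactly at
    the cutoff is retained.
    """
    params = params or QCParams()
    if "cluster" not in adata.obs:
        raise ValueError("cluster labels are required")
    if params.cd45_gene not in adata.var_names:
        warnings.warn(f"{params.cd45_gene!r} not in gene list; retaining all clusters")
        return sorted(adata.obs["cluster"].astype(str).unique())
    col = np.asarray(sp.csr_matrix(adata.X)[:, adata.var_names.get_loc(params.cd45_gene)].todense()).ravel()
    detected = col > 0
    retained, dropped = [], []
    clusters = adata.obs["cluster"].astype(str).to_numpy()
    for cl in sorted(np.unique(clusters)):
        sel = clusters == cl
        if detected[sel].mean() < params.cd45_min_detection:
            dropped.append(cl)
        else:
            retained.append(cl)
    if not retained:
        raise ValueError("all clusters fall below the CD45 detection cutoff")
    if dropped:
        adata.obs.loc[np.isin(clusters, dropped), "qc_pass"] = False
    return retained


def normalize(adata: ad.AnnData, params: QCParams | None = None) -> ad.AnnData:
    """Depth-normalize: layer['lognorm'] = ln(1 + s * count / umi_total).

    Zero counts map to 0 exactly, so sparsity is preserved. QC-passing
    cells must have positive totals (they should have been excluded
    upstream otherwise).
    """
    params = params or QCParams()
    total = np.asarray(sp.csr_matrix(adata.X).sum(axis=1)).ravel()
    if "qc_pass" in adata.obs:
        assert (total[adata.obs["qc_pass"].to_numpy(bool)] > 0).all(), (
            "qc_pass cell with zero total counts; exclude upstream"
        )
    X = sp.csr_matrix(adata.X, dtype=float, copy=True)
    scale = np.where(total > 0, params.scale_factor / np.maximum(total, 1), 0.0)
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    adata.layers[LOGNORM_LAYER] = X.tocsr()
    return adata
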