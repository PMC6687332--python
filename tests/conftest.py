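import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import screcover as sr


def make_adata(counts, conditions=None, clusters=None, genes=None, normalized=False):
    """Small dense-count AnnData for unit tests (cells x genes)."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    genes = list(genes) if genes is not None else [f"g{j}" for j in range(n_genes)]
    barcodes = [f"bc{i}" for i in range(n_cells)]
    obs = pd.DataFrame({"barcode": barcodes}, index=barcodes)
    obs.index.name = None
    if conditions is not None:
        obs["condition"] = list(conditions)
    if clusters is not None:
        obs["cluster"] = list(clusters)
    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int32)),
        obs=obs,
        var=pd.DataFrame({"gene": genes}, index=genes),
    )
    sr.compute_cell_qc(adata)
    if normalized:
        sr.normalize(adata)
    return adata


@pytest.fixture(scope="session")
def small_cfg():
    """Tiny configuration for structural tests (fast to draw repeatedly)."""
    return sr.SimConfig.reduced(
        seed=7,
        n_genes=300,
        cells_per_condition={"lean": 160, "obese": 200, "CR": 200},
        n_planted_per_category={"Recovered": 10, "NotRecovered": 10, "Different": 10},
        n_outlier_cells=5,
        n_doublets=5,
        n_marker_genes=3,
    )


@pytest.fixture(scope="session")
def reduced_cfg():
    """The desk-scale study configuration used for parameter recovery."""
    return sr.SimConfig.reduced(seed=0)


@pytest.fixture(scope="session")
def reduced_pipeline(reduced_cfg):
    """Full pipeline products on the desk-scale dataset: (adata, truth,
    de_results, selected genes, recovery table)."""
    adata, truth = sr.simulate(reduced_cfg)
    sr.compute_cell_qc(adata)
    sr.filter_cells(adata)
    sr.exclude_nonleukocyte_clusters(adata)
    sr.normalize(adata)
    results = sr.de_all_contrasts(adata)
    genes = sr.select_recovery_genes(results)
    table = sr.build_recovery_table(adata, genes)
    return adata, truth, results, genes, table


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    adata, truth = sr.simulate(small_cfg)
    sr.compute_cell_qc(adata)
    sr.filter_cells(adata)
    sr.normalize(adata)
    return adata, truth
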