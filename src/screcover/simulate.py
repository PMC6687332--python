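"""Synthetic three-condition clustered UMI data with planted ground truth.

Generates genes x cells UMI count matrices emulating a droplet scRNA-seq
leukocyte atlas sampled under three conditions (lean, obese, CR = caloric
restriction after obesity): negative-binomial counts with log-normal per-cell
size factors, cluster-specific marker genes, one cluster absent in the lean
condition, and planted condition effects whose post-CR behaviour falls into
known Recovered / NotRecovered / Different categories. High-mitochondrial
cells and doublets can be planted so the QC stage is testable end to end.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

CONDITIONS = ("lean", "obese", "CR")
CATEGORIES = ("Recovered", "NotRecovered", "Different")

__all__ = [
    "CONDITIONS",
    "CATEGORIES",
    "SimConfig",
    "TruthTable",
    "generate_dataset",
    "plant_outliers",
    "truth_summary",
    "simulate",
]


def _default_cluster_proportions(n_clusters: int) -> dict[str, np.ndarray]:
    """Cluster mixing proportions per condition.

    Cluster c01 emulates the dominant macrophage population that expands in
    obesity and reverts with CR (16% -> 38% -> 17%); cluster c02 emulates the
    phagocytic macrophage population absent in lean tissue (0% -> 7% -> 30%).
    Remaining clusters share the residual mass evenly.
    """
    if n_clusters < 3:
        raise ValueError("need at least 3 clusters for the default design")
    rest = n_clusters - 2
    props = {}
    for cond, (p1, p2) in {"lean": (0.16, 0.0), "obese": (0.38, 0.07), "CR": (0.17, 0.30)}.items():
        v = np.full(n_clusters, (1.0 - p1 - p2) / rest)
        v[0], v[1] = p1, p2
        props[cond] = v
    return props


def _reduced_cluster_proportions(n_clusters: int) -> dict[str, np.ndarray]:
    """Near-equal proportions; cluster c02 is absent in lean and expands
    from obese to CR (the phagocytic-macrophage motif)."""
    props = {}
    for cond, p2 in {"lean": 0.0, "obese": 0.10, "CR": 0.30}.items():
        v = np.full(n_clusters, (1.0 - p2) / (n_clusters - 1))
        v[1] = p2
        props[cond] = v
    return props


@dataclass
class SimConfig:
    """Study-scale defaults mirror the source experiment: 2268 lean, 5232
    obese and 2458 CR cells over 15 leukocyte clusters, one of which is
    absent in lean tissue."""

    n_genes: int = 2000
    n_clusters: int = 15
    cells_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {"lean": 2268, "obese": 5232, "CR": 2458}
    )
    cluster_proportions: Mapping[str, np.ndarray] | None = None
    baseline_mean: float = 0.3
    dispersion: float = 10.0
    n_planted_per_category: Mapping[str, int] = field(
        default_factory=lambda: {"Recovered": 100, "NotRecovered": 100, "Different": 100}
    )
    effect_fold: float = 2.0
    divergence_fold: float = 1.25
    mito_gene_fraction: float = 0.01
    n_outlier_cells: int = 20
    n_doublets: int = 20
    seed: int = 0
    # secondary knobs (not part of the minimal surface, documented in methods)
    size_factor_sigma: float = 0.3
    gene_mean_sigma: float = 1.0
    planted_mean_range: tuple[float, float] = (2.0, 8.0)
    mito_mean_scale: float = 10.0
    cd45_gene: str = "Ptprc"
    cd45_mean: float = 3.0
    n_marker_genes: int = 8
    marker_fold: float = 8.0

    def __post_init__(self) -> None:
        if self.cluster_proportions is None:
            self.cluster_proportions = _default_cluster_proportions(self.n_clusters)
        self.validate()

    @classmethod
    def reduced(cls, seed: int = 0, **kwargs) -> "SimConfig":
        """Desk-scale configuration: 5 clusters, 200 cells per
        cluster-condition (cluster c02 absent in lean), 2000 genes, 300
        planted genes at 2-fold."""
        defaults = dict(
            n_clusters=5,
            cells_per_condition={"lean": 800, "obese": 1000, "CR": 1000},
            cluster_proportions=_reduced_cluster_proportions(5),
            seed=seed,
        )
        defaults.update(kwargs)
        return cls(**defaults)

    def validate(self) -> None:
        for cond in CONDITIONS:
            if cond not in self.cells_per_condition:
                raise ValueError(f"cells_per_condition missing condition {cond!r}")
            p = np.asarray(self.cluster_proportions[cond], dtype=float)
            if p.shape != (self.n_clusters,):
                raise ValueError(f"cluster_proportions[{cond!r}] has wrong length")
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"cluster_proportions[{cond!r}] must be a probability vector")
        pl = np.asarray(self.cluster_proportions["lean"])
        po = np.asarray(self.cluster_proportions["obese"])
        pc = np.asarray(self.cluster_proportions["CR"])
        if not ((pl == 0) & (po > 0) & (pc > 0)).any():
            raise ValueError("design requires a cluster absent in lean but present in obese and CR")
        n_planted = sum(self.n_planted_per_category.get(c, 0) for c in CATEGORIES)
        if n_planted >= self.n_genes:
            raise ValueError("planted gene total must be smaller than n_genes")
        if self.effect_fold < 1.5:
            raise ValueError("effect_fold must be >= 1.5")
        if self.divergence_fold <= 1.1:
            raise ValueError("divergence_fold must be > 1.1")
        if self.divergence_fold > (1.0 + self.effect_fold) / self.effect_fold:
            raise ValueError(
                "divergence_fold must be <= (1 + effect_fold)/effect_fold for the "
                "mass-balanced paired design"
            )
        if not (0.0 <= self.mito_gene_fraction <= 1.0):
            raise ValueError("mito_gene_fraction must lie in [0, 1]")
        if n_planted > 0 and any(self.cells_per_condition[c] == 0 for c in CONDITIONS):
            raise ValueError(
                "a condition with zero cells cannot carry planted condition effects"
            )

    def cluster_names(self) -> list[str]:
        return [f"c{i + 1:02d}" for i in range(self.n_clusters)]

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["cluster_proportions"] = {
            k: [float(x) for x in np.asarray(v)] for k, v in self.cluster_proportions.items()
        }
        d["cells_per_condition"] = dict(self.cells_per_condition)
        d["n_planted_per_category"] = dict(self.n_planted_per_category)
        d["planted_mean_range"] = list(self.planted_mean_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["cluster_proportions"] = {k: np.asarray(v, float) for k, v in d["cluster_proportions"].items()}
        d["planted_mean_range"] = tuple(d["planted_mean_range"])
        return cls(**d)


@dataclass
class TruthTable:
    """Planted ground truth: per-gene category and condition means on the raw
    count-mean scale (L*, O*, C*), per-cell outlier flags, and which genes
    were used as cluster markers."""

    genes: pd.DataFrame  # gene, category, clusters, mean_lean, mean_obese, mean_cr
    cells: pd.DataFrame  # barcode, is_planted_outlier, outlier_kind
    markers: pd.DataFrame  # gene, cluster

    def planted_genes(self, category: str | None = None) -> list[str]:
        g = self.genes
        if category is not None:
            g = g[g["category"] == category]
        return list(g["gene"])

    def planted_outlier_barcodes(self, kind: str | None = None) -> list[str]:
        c = self.cells[self.cells["is_planted_outlier"]]
        if kind is not None:
            c = c[c["outlier_kind"] == kind]
        return list(c["barcode"])

    def write(self, genes_path, cells_path) -> None:
        self.genes.to_csv(genes_path, sep="\t", index=False)
        self.cells.to_csv(cells_path, sep="\t", index=False)


def _allocate_counts(n: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n cells to clusters: deterministic,
    exact totals, and exactly zero cells for zero-proportion clusters."""
    raw = proportions * n
    base = np.floor(raw).astype(int)
    remainder = n - base.sum()
    if remainder > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:remainder]] += 1
    assert base.sum() == n and (base[proportions == 0] == 0).all()
    return base


def _gene_names(cfg: SimConfig) -> tuple[list[str], np.ndarray]:
    n_mito = int(round(cfg.mito_gene_fraction * cfg.n_genes))
    names = [f"mt-{i + 1:02d}" for i in range(n_mito)]
    if cfg.n_genes - n_mito >= 1:
        names.append(cfg.cd45_gene)
    names += [f"g{i + 1:04d}" for i in range(cfg.n_genes - len(names))]
    mito_mask = np.zeros(cfg.n_genes, dtype=bool)
    mito_mask[:n_mito] = True
    return names, mito_mask


def generate_dataset(cfg: SimConfig) -> tuple[ad.AnnData, TruthTable]:
    """Draw a clean (no planted outliers) three-condition dataset.

    Counts are negative binomial with mean = size_factor x per-gene
    cluster/condition mean and size (dispersion) parameter ``cfg.dispersion``,
    realised as a gamma-Poisson mixture. Planted genes receive condition
    means (L*, O*, C*) satisfying their category by construction:

    * Recovered:    C* = L*  (with O* = L* x effect_fold up or down)
    * NotRecovered: C* = O*
    * Different:    C* outside [min(L*, O*), max(L*, O*)], more than the
      classifier threshold away from both

    Effects are planted in mass-balanced up/down pairs so total expected
    library size is the same in every condition (see inline comment).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes, mito_mask = _gene_names(cfg)
    clusters = cfg.cluster_names()
    G, K = cfg.n_genes, cfg.n_clusters

    # per-gene baseline means (median = baseline_mean)
    base = rng.lognormal(mean=math.log(cfg.baseline_mean), sigma=cfg.gene_mean_sigma, size=G)
    base[mito_mask] *= cfg.mito_mean_scale
    cd45_idx = genes.index(cfg.cd45_gene) if cfg.cd45_gene in genes else None
    if cd45_idx is not None:
        base[cd45_idx] = cfg.cd45_mean

    # choose planted and marker genes among ordinary genes
    ordinary = np.flatnonzero(~mito_mask)
    if cd45_idx is not None:
        ordinary = ordinary[ordinary != cd45_idx]
    n_per = {c: int(cfg.n_planted_per_category.get(c, 0)) for c in CATEGORIES}
    n_planted = sum(n_per.values())
    n_marker = cfg.n_marker_genes * K
    chosen = rng.choice(ordinary, size=n_planted + n_marker, replace=False)
    planted_idx = chosen[:n_planted]
    marker_idx = chosen[n_planted:]
    lo, hi = cfg.planted_mean_range
    d, v = cfg.effect_fold, cfg.divergence_fold

    # Mass-balanced paired planting: every category is built from pairs
    # (up-regulated gene with base m, down-regulated gene with base m*d) so
    # the expected library size is identical in all three conditions and
    # depth normalization stays unbiased. Different genes sit above both
    # references in the up member and below both in the down member.
    categories = np.concatenate([[c] * n_per[c] for c in CATEGORIES]) if n_planted else np.array([])
    planted_means = np.zeros((n_planted, 3))  # columns: lean, obese, CR

    def _triples(cat: str, m: float) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
        up = {
            "Recovered": (m, d * m, m),
            "NotRecovered": (m, d * m, d * m),
            "Different": (m, d * m, d * m * v),
        }[cat]
        down = {
            "Recovered": (d * m, m, d * m),
            "NotRecovered": (d * m, m, m),
            "Different": (d * m, m, max(0.0, m * (1.0 + d - d * v))),
        }[cat]
        return up, down

    j = 0
    for cat in CATEGORIES:
        n_cat = n_per[cat]
        for _ in range(n_cat // 2):
            m = float(np.exp(rng.uniform(math.log(lo), math.log(hi / d))))
            up, down = _triples(cat, m)
            planted_means[j], planted_means[j + 1] = up, down
            j += 2
        if n_cat % 2:  # odd count: one unpaired up gene (negligible imbalance)
            m = float(np.exp(rng.uniform(math.log(lo), math.log(hi / d))))
            planted_means[j] = _triples(cat, m)[0]
            j += 1

    cond_mult = np.ones((G, len(CONDITIONS)))
    if n_planted:
        base[planted_idx] = planted_means[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            cond_mult[planted_idx] = planted_means / planted_means[:, [0]]

    # cluster marker boosts (same in every condition)
    cluster_mult = np.ones((G, K))
    marker_rows = []
    for k in range(K):
        idx = marker_idx[k * cfg.n_marker_genes : (k + 1) * cfg.n_marker_genes]
        cluster_mult[idx, k] = cfg.marker_fold
        marker_rows += [(genes[i], clusters[k]) for i in idx]

    # sample cells: stratified allocation, then NB counts block by block
    obs_rows = []
    blocks = []
    for ci, cond in enumerate(CONDITIONS):
        n_cond = int(cfg.cells_per_condition[cond])
        alloc = _allocate_counts(n_cond, np.asarray(cfg.cluster_proportions[cond], float))
        for k in range(K):
            n_block = int(alloc[k])
            if n_block == 0:
                continue
            sf = rng.lognormal(mean=-cfg.size_factor_sigma**2 / 2, sigma=cfg.size_factor_sigma, size=n_block)
            mu = base * cond_mult[:, ci] * cluster_mult[:, k]  # (G,)
            lam = sf[:, None] * mu[None, :]
            r = cfg.dispersion
            shape_mat = rng.gamma(shape=r, scale=lam / r)
            counts = rng.poisson(shape_mat).astype(np.int32)
            blocks.append(counts)
            for _ in range(n_block):
                obs_rows.append((cond, clusters[k]))
    X = np.vstack(blocks)
    obs = pd.DataFrame(obs_rows, columns=["condition", "cluster"])
    obs["barcode"] = [f"cell-{c}-{i:05d}" for i, c in enumerate(obs["condition"])]
    obs = obs[["barcode", "condition", "cluster"]].set_index("barcode", drop=False)
    obs.index.name = None

    adata = ad.AnnData(
        X=sp.csr_matrix(X),
        obs=obs,
        var=pd.DataFrame({"gene": genes, "mito": mito_mask}, index=genes),
    )
    adata.obs["condition"] = pd.Categorical(adata.obs["condition"], categories=list(CONDITIONS))

    truth_genes = pd.DataFrame(
        {
            "gene": [genes[i] for i in planted_idx],
            "category": categories,
            "clusters": "all",
            "mean_lean": base[planted_idx] * cond_mult[planted_idx, 0],
            "mean_obese": base[planted_idx] * cond_mult[planted_idx, 1],
            "mean_cr": base[planted_idx] * cond_mult[planted_idx, 2],
        }
    )
    truth_cells = pd.DataFrame(
        {
            "barcode": adata.obs["barcode"],
            "is_planted_outlier": False,
            "outlier_kind": "",
            "doublet_parents": "",
        }
    ).reset_index(drop=True)
    truth = TruthTable(
        genes=truth_genes,
        cells=truth_cells,
        markers=pd.DataFrame(marker_rows, columns=["gene", "cluster"]),
    )
    return adata, truth


def plant_outliers(
    adata: ad.AnnData, truth: TruthTable, cfg: SimConfig
) -> tuple[ad.AnnData, TruthTable]:
    """Plant high-mitochondrial cells and doublets.

    High-mito cells have their mitochondrial counts inflated to ~60% of the
    library so their mito fraction far exceeds 5x the cohort median. Doublets
    are element-wise sums of two same-condition cells drawn from above the
    60th depth percentile — the detectable two-cells-in-one-droplet motif the
    UMI outlier filter targets — appended as new barcodes.
    """
    n_out, n_dbl = cfg.n_outlier_cells, cfg.n_doublets
    if n_out + n_dbl > adata.n_obs:
        raise ValueError("more planted outliers than cells")
    mito_mask = adata.var["mito"].to_numpy()
    if n_out > 0 and not mito_mask.any():
        raise ValueError("cannot plant high-mito cells with mito_gene_fraction = 0")
    if n_out == 0 and n_dbl == 0:
        return adata, truth

    rng = np.random.default_rng([cfg.seed, 1])
    X = adata.X.tolil(copy=True)
    totals = np.asarray(adata.X.sum(axis=1)).ravel()

    out_idx = rng.choice(adata.n_obs, size=n_out, replace=False) if n_out else np.array([], int)
    mito_cols = np.flatnonzero(mito_mask)
    mito_w = np.ones(len(mito_cols)) / len(mito_cols) if len(mito_cols) else None
    for i in out_idx:
        row = np.asarray(X.getrow(int(i)).todense()).ravel()
        non_mito_total = row[~mito_mask].sum()
        target = int(math.ceil(1.5 * max(non_mito_total, 1)))  # 60% mito fraction
        new_mito = rng.multinomial(target, mito_w)
        row[mito_cols] = new_mito
        X[int(i), :] = row

    # doublets, allocated across conditions proportionally to condition size
    conds = adata.obs["condition"].to_numpy()
    dbl_rows, dbl_obs, dbl_parents = [], [], {}
    if n_dbl:
        sizes = np.array([(conds == c).sum() for c in CONDITIONS], float)
        alloc = _allocate_counts(n_dbl, sizes / sizes.sum())
        j = 0
        for ci, cond in enumerate(CONDITIONS):
            pool = np.flatnonzero(conds == cond)
            pool = np.setdiff1d(pool, out_idx)  # mito-inflated cells are not parents
            if len(pool) == 0:
                continue
            deep = pool[totals[pool] >= np.quantile(totals[pool], 0.6)]
            for _ in range(int(alloc[ci])):
                a, b = rng.choice(deep, size=2, replace=False)
                row = np.asarray((adata.X[int(a)] + adata.X[int(b)]).todense()).ravel()
                dbl_rows.append(row)
                bc = f"doublet-{j:03d}"
                dbl_obs.append((bc, cond, adata.obs["cluster"].iloc[int(a)]))
                dbl_parents[bc] = f"{adata.obs['barcode'].iloc[int(a)]};{adata.obs['barcode'].iloc[int(b)]}"
                j += 1

    X = X.tocsr()
    if dbl_rows:
        X = sp.vstack([X, sp.csr_matrix(np.vstack(dbl_rows))]).tocsr()
    obs = adata.obs[["barcode", "condition", "cluster"]].copy()
    if dbl_obs:
        extra = pd.DataFrame(dbl_obs, columns=["barcode", "condition", "cluster"]).set_index(
            "barcode", drop=False
        )
        extra.index.name = None
        obs = pd.concat([obs, extra])
    out = ad.AnnData(X=X.astype(np.int32), obs=obs, var=adata.var.copy())
    out.obs["condition"] = pd.Categorical(out.obs["condition"], categories=list(CONDITIONS))

    cells = pd.DataFrame(
        {"barcode": out.obs["barcode"], "is_planted_outlier": False, "outlier_kind": ""}
    ).reset_index(drop=True)
    planted_bc = set(adata.obs["barcode"].iloc[out_idx])
    cells.loc[cells["barcode"].isin(planted_bc), ["is_planted_outlier", "outlier_kind"]] = [
        True,
        "high_mito",
    ]
    cells.loc[cells["barcode"].str.startswith("doublet-"), ["is_planted_outlier", "outlier_kind"]] = [
        True,
        "doublet",
    ]
    cells["doublet_parents"] = cells["barcode"].map(dbl_parents).fillna("")
    new_truth = TruthTable(genes=truth.genes.copy(), cells=cells, markers=truth.markers.copy())
    return out, new_truth


def truth_summary(truth: TruthTable) -> pd.DataFrame:
    """Planted gene counts per (category, cluster) plus outlier-cell counts.

    Gene rows: one per category x affected cluster ('all' kept symbolic).
    Cell rows use category 'outlier:<kind>'.
    """
    rows = []
    if len(truth.genes):
        for cat, sub in truth.genes.groupby("category", observed=True):
            for cl, sub2 in sub.groupby("clusters", observed=True):
                rows.append((str(cat), str(cl), len(sub2)))
    outliers = truth.cells[truth.cells["is_planted_outlier"].astype(bool)]
    for kind, sub in outliers.groupby("outlier_kind"):
        rows.append((f"outlier:{kind}", "-", len(sub)))
    out = pd.DataFrame(rows, columns=["category", "cluster", "n"])
    if out.empty:
        out = pd.DataFrame(columns=["category", "cluster", "n"])
    return out


def simulate(cfg: SimConfig) -> tuple[ad.AnnData, TruthTable]:
    """generate_dataset followed by plant_outliers."""
    adata, truth = generate_dataset(cfg)
    return plant_outliers(adata, truth, cfg)
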