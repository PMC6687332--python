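"""Target-vs-background gene-set over-representation.

A generic hypergeometric (one-sided, upper-tail) test: given a target gene
list drawn from a background universe of detectably expressed genes, each
gene set's overlap k with the target is scored by P(X >= k) where
X ~ Hypergeometric(N = |background|, K = |set ∩ background|, n = |target|),
with Benjamini-Hochberg adjustment across sets. Gene sets are supplied as
GMT files; no ontology snapshot is bundled.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .recovery import NOT_ASSESSED, RECOVERY_CATEGORIES

__all__ = ["read_gmt", "write_gmt", "hypergeom_enrich", "enrich_by_category"]


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file (name, description, members...); duplicates collapse."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
            name, _desc, *genes = fields
            members = {g for g in genes if g}
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = members
    if not sets:
        warnings.warn(f"{path}: empty GMT file")
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path, descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(set(genes))]) + "\n")


def hypergeom_enrich(
    target: Iterable[str],
    background: Iterable[str],
    sets: Mapping[str, Iterable[str]],
    min_set_size: int = 1,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each gene set.

    Sets are intersected with the background before testing; the target
    must be a subset of the background. Results are sorted by adjusted
    then raw p-value.
    """
    target = set(target)
    background = set(background)
    stray = target - background
    if stray:
        raise ValueError(f"target genes outside background: {sorted(stray)[:5]}")
    N, n = len(background), len(target)
    rows = []
    for name, genes in sets.items():
        inset = set(genes) & background
        K = len(inset)
        if K < min_set_size:
            continue
        overlap = sorted(inset & target)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, n, K, N, min(p, 1.0), ",".join(overlap)))
    df = pd.DataFrame(
        rows, columns=["set", "k", "n", "K", "N", "p_raw", "overlap_genes"]
    )
    if df.empty:
        return df.assign(p_adj=pd.Series(dtype=float))
    df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
    return df.sort_values(["p_adj", "p_raw"], kind="stable").reset_index(drop=True)[
        ["set", "k", "n", "K", "N", "p_raw", "p_adj", "overlap_genes"]
    ]


def enrich_by_category(
    recovery_table: pd.DataFrame,
    background: Iterable[str],
    sets: Mapping[str, Iterable[str]],
    per_cluster: bool = False,
    min_set_size: int = 1,
) -> pd.DataFrame:
    """Over-representation per recovery category (pooled across clusters,
    optionally also per cluster).

    Adds ``frac_of_category`` = k / |category genes| — the dot-size analog
    of per-pathway gene fractions. Categories with fewer than 2 genes are
    skipped with a warning.
    """
    if recovery_table.empty:
        raise ValueError("recovery table is empty")
    background = set(background)
    scopes: list[tuple[str, pd.DataFrame]] = [("pooled", recovery_table)]
    if per_cluster:
        scopes += [
            (str(cl), sub)
            for cl, sub in recovery_table.groupby("cluster", observed=True)
            if (sub["category"] != NOT_ASSESSED).any()
        ]
    out = []
    for scope, sub in scopes:
        for cat in RECOVERY_CATEGORIES:
            genes = set(sub.loc[sub["category"] == cat, "gene"]) & background
            if len(genes) < 2:
                warnings.warn(f"category {cat!r} in scope {scope!r} has <2 genes; skipped")
                continue
            res = hypergeom_enrich(genes, background, sets, min_set_size=min_set_size)
            if res.empty:
                continue
            res.insert(0, "scope", scope)
            res.insert(1, "category", cat)
            res["frac_of_category"] = res["k"] / len(genes)
            out.append(res)
    if not out:
        return pd.DataFrame(
            columns=["scope", "category", "set", "k", "n", "K", "N", "p_raw", "p_adj", "overlap_genes", "frac_of_category"]
        )
    return pd.concat(out, ignore_index=True)
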