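import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import screcover as sr
from screcover.de import _ranksum_p_matrix, contrast_name
from conftest import make_adata
from _oracles import bh_stepup, exact_ranksum_p


def test_separated_groups_exact_p():
    # C(6,3) = 20 assignments; only the two extremes are as extreme
    assert sr.wilcoxon_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_identical_groups_give_p_one():
    assert sr.wilcoxon_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)
    assert sr.wilcoxon_test([5.0] * 4, [5.0] * 4) == pytest.approx(1.0)


def test_rank_test_invariant_to_within_group_order():
    p1 = sr.wilcoxon_test([3, 1, 2], [6, 4, 5])
    p2 = sr.wilcoxon_test([1, 2, 3], [4, 5, 6])
    assert p1 == p2


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        sr.wilcoxon_test([], [1.0])


def test_vectorized_ranksum_matches_scalar_asymptotic():
    rng = np.random.default_rng(11)
    A = np.round(rng.gamma(1.0, 2.0, size=(30, 25)), 1)  # plenty of ties
    B = np.round(rng.gamma(1.2, 2.0, size=(40, 25)), 1)
    vec = _ranksum_p_matrix(A, B)
    scalar = [sr.wilcoxon_test(A[:, j], B[:, j]) for j in range(25)]
    np.testing.assert_allclose(vec, scalar, rtol=1e-10)


def test_bh_small_example_and_identity():
    np.testing.assert_allclose(sr.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(sr.bh_adjust([0.42]), [0.42])


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_inflates_and_matches_stepup_definition(p):
    adj = sr.bh_adjust(p)
    assert (adj >= np.asarray(p) - 1e-12).all()
    assert (adj <= 1.0).all()
    np.testing.assert_allclose(adj, bh_stepup(p), rtol=1e-12)


def test_condition_stats_matches_per_cell_loop():
    rng = np.random.default_rng(5)
    counts = rng.poisson(2.0, size=(10, 10))
    adata = make_adata(counts, normalized=True)
    stats = sr.condition_stats(adata, np.arange(10))
    lognorm = adata.layers["lognorm"].toarray()
    for j in range(10):
        mean = np.mean([np.expm1(lognorm[i, j]) for i in range(10)])
        pct = np.mean([counts[i, j] > 0 for i in range(10)])
        assert stats["mean"].iloc[j] == pytest.approx(mean)
        assert stats["pct"].iloc[j] == pytest.approx(pct)
    assert stats["mean"].iloc[0] == pytest.approx(
        np.mean(10000 * counts[:, 0] / counts.sum(axis=1))
    )


def test_condition_stats_rejects_empty_subset(small_sim):
    adata, _ = small_sim
    with pytest.raises(ValueError):
        sr.condition_stats(adata, np.array([], dtype=int))


def _toy_two_condition_adata(seed=0):
    rng = np.random.default_rng(seed)
    counts = rng.poisson([3, 1, 2, 2], size=(40, 4))
    counts[:20, 0] *= 3  # gene 0 higher in lean
    conds = ["lean"] * 20 + ["obese"] * 20
    return make_adata(counts, conditions=conds, clusters=["k"] * 40, normalized=True)


def test_contrast_antisymmetry():
    adata = _toy_two_condition_adata()
    ab = sr.de_contrast(adata, "k", "obese", "lean")
    ba = sr.de_contrast(adata, "k", "lean", "obese")
    np.testing.assert_allclose(ab["logFC"], -ba["logFC"], rtol=1e-12)
    np.testing.assert_allclose(ab["p_raw"], ba["p_raw"], rtol=1e-12)
    assert (ab["pct_a"] == ba["pct_b"]).all()


def test_gene_identical_between_groups_is_null():
    counts = np.tile([[4, 7]], (12, 1))
    adata = make_adata(counts, conditions=["lean"] * 6 + ["obese"] * 6, clusters=["k"] * 12, normalized=True)
    df = sr.de_contrast(adata, "k", "obese", "lean")
    assert df["logFC"].abs().max() == pytest.approx(0.0)
    assert (df["p_raw"] == 1.0).all()


def test_contrast_not_assessed_below_min_cells(small_sim):
    adata, _ = small_sim
    assert sr.de_contrast(adata, "c02", "obese", "lean") is None
    results = sr.de_all_contrasts(adata)
    assert results[("c02", contrast_name("obese", "lean"))] is None
    assert results[("c02", contrast_name("CR", "obese"))] is not None


def test_planted_effect_detected_with_positive_logfc(reduced_pipeline):
    """A 2-fold planted obesity effect with 200 cells per group is detected
    (p_adj < 0.05) with the correct sign for nearly all planted genes."""
    adata, truth, results, _, _ = reduced_pipeline
    tg = truth.genes.set_index("gene")
    up = tg[tg["mean_obese"] > tg["mean_lean"]].index
    df = results[("c01", contrast_name("obese", "lean"))].set_index("gene")
    hits = df.loc[up]
    detected = (hits["p_adj"] < 0.05) & (hits["logFC"] > 0)
    assert detected.mean() >= 0.90


def _marker_toy():
    # 3 clusters x 12 cells, 6 genes, block structure; every cell's library
    # size is 13 so depth normalization cannot manufacture differences
    counts = np.zeros((36, 6), dtype=int)
    counts[:, 5] = 5  # housekeeping, equal everywhere
    counts[0:12, 0] = 8  # gene 0 -> cluster A
    counts[0:2, 0] = 4
    counts[0:2, 4] = 4  # gene 4: only 2/12 cells of A (pct 0.17 < 0.25)
    counts[12:24, 1] = 8  # gene 1 -> cluster B
    counts[24:36, 2] = 5  # genes 2, 3 -> cluster C
    counts[24:36, 3] = 3
    assert (counts.sum(axis=1) == 13).all()
    clusters = ["A"] * 12 + ["B"] * 12 + ["C"] * 12
    return make_adata(counts, clusters=clusters, conditions=["lean"] * 36, normalized=True)


def test_marker_rule_matches_hand_enumeration():
    mk = sr.find_markers(_marker_toy())
    got = {cl: set(sub["gene"]) for cl, sub in mk.groupby("cluster")}
    assert got["A"] == {"g0"}
    assert got["B"] == {"g1"}
    assert got["C"] == {"g2", "g3"}


def test_low_detection_gene_excluded_regardless_of_fold():
    mk = sr.find_markers(_marker_toy())
    assert "g4" not in set(mk["gene"])  # pct_in ~0.17 below the 25% rule


def test_markers_ranked_by_logfc_descending():
    mk = sr.find_markers(_marker_toy())
    for _, sub in mk.groupby("cluster"):
        assert (np.diff(sub["logFC"]) <= 1e-12).all()
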