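import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import screcover as sr
from screcover.de import contrast_name
from screcover.recovery import NOT_ASSESSED


@pytest.mark.parametrize(
    "L,O,C,expected",
    [
        (10, 20, 11, "Recovered"),
        (10, 20, 25, "Different"),  # non-intermediate, >10% from both
        (10, 20, 20.5, "NotRecovered"),  # non-intermediate but within 10% of O
        (10, 20, 15, "NotRecovered"),  # exact tie -> conservative
        (10, 20, 19, "NotRecovered"),
        (20, 10, 8, "Different"),  # below both after down-regulation
        (0, 5, 0, "Recovered"),  # silent gene returning to silence
    ],
)
def test_classifier_rules(L, O, C, expected):
    assert sr.classify_gene(L, O, C) == expected


def test_classifier_rejects_negative_means():
    with pytest.raises(ValueError):
        sr.classify_gene(-1.0, 2.0, 3.0)


@settings(derandomize=True, max_examples=200)
@given(
    st.floats(min_value=0.01, max_value=50),
    st.floats(min_value=0.01, max_value=50),
    st.floats(min_value=0.01, max_value=50),
    st.floats(min_value=0.1, max_value=100),
)
def test_classifier_scale_invariance(L, O, C, s):
    params = sr.ClassifierParams()
    if min(L, O, C) * s < params.epsilon:
        return
    assert sr.classify_gene(L, O, C) == sr.classify_gene(s * L, s * O, s * C)


def _fake_results():
    def frame(cluster, contrast, p_by_gene):
        genes = list(p_by_gene)
        return pd.DataFrame(
            {
                "gene": genes,
                "cluster": cluster,
                "contrast": contrast,
                "logFC": 0.0,
                "p_raw": list(p_by_gene.values()),
                "p_adj": list(p_by_gene.values()),
                "mean_a": 1.0,
                "mean_b": 1.0,
                "pct_a": 1.0,
                "pct_b": 1.0,
            }
        )

    names = [contrast_name(a, b) for a, b in (("obese", "lean"), ("CR", "lean"), ("CR", "obese"))]
    base = {"g1": 0.5, "g2": 0.5, "g3": 0.5, "g4": 0.5, "g5": 0.5}
    results = {}
    for cl in ("k1", "k2"):
        for nm in names:
            results[(cl, nm)] = frame(cl, nm, dict(base))
    # g1 significant in one contrast of one cluster; g2 in CR_vs_obese of k2
    results[("k1", names[0])].loc[0, "p_adj"] = 0.001
    results[("k2", names[2])].loc[1, "p_adj"] = 0.01
    return results, names


def test_select_recovery_genes_matches_hand_enumeration():
    results, _ = _fake_results()
    assert sr.select_recovery_genes(results, alpha=0.05) == ["g1", "g2"]


def test_select_recovery_genes_rejects_missing_family():
    results, names = _fake_results()
    del results[("k2", names[1])]
    with pytest.raises(ValueError, match="CR_vs_lean"):
        sr.select_recovery_genes(results)


def test_recovery_table_parameter_recovery(reduced_pipeline):
    """>= 90% of planted (gene, assessable-cluster) pairs get their planted
    category back from the fitted cluster-condition means."""
    _, truth, _, genes, table = reduced_pipeline
    tg = truth.genes.set_index("gene")
    assert set(tg.index) <= set(genes)
    assessed = table[table["category"] != NOT_ASSESSED]
    m = assessed[assessed["gene"].isin(tg.index)]
    accuracy = (m["category"].to_numpy() == tg.loc[m["gene"], "category"].to_numpy()).mean()
    assert accuracy >= 0.90


def test_absent_in_lean_cluster_is_not_assessed(reduced_pipeline):
    _, _, _, _, table = reduced_pipeline
    c02 = table[table["cluster"] == "c02"]
    assert len(c02) > 0 and (c02["category"] == NOT_ASSESSED).all()


def test_label_permutation_destroys_planted_structure(reduced_pipeline):
    """Negative control: permuting condition labels drops category accuracy
    to chance level."""
    adata, truth, _, _, table = reduced_pipeline
    tg = truth.genes.set_index("gene")
    rng = np.random.default_rng(1)
    shuffled = adata.copy()
    shuffled.obs["condition"] = pd.Categorical(
        rng.permutation(shuffled.obs["condition"].to_numpy()),
        categories=list(sr.CONDITIONS),
    )
    perm_table = sr.build_recovery_table(shuffled, list(tg.index))
    assessed = perm_table[perm_table["category"] != NOT_ASSESSED]
    acc_perm = (
        assessed["category"].to_numpy() == tg.loc[assessed["gene"], "category"].to_numpy()
    ).mean()
    real = table[(table["category"] != NOT_ASSESSED) & table["gene"].isin(tg.index)]
    acc_real = (real["category"].to_numpy() == tg.loc[real["gene"], "category"].to_numpy()).mean()
    assert acc_perm < 0.55
    assert acc_real - acc_perm > 0.3


def test_recovery_proportions_arithmetic():
    table = pd.DataFrame(
        {
            "gene": ["g1", "g2", "g3", "g4"],
            "cluster": "k",
            "L": 1.0,
            "O": 2.0,
            "C": 1.0,
            "category": ["Recovered", "Recovered", "NotRecovered", "Different"],
        }
    )
    props = sr.recovery_proportions(table, "all_selected")
    row = props.iloc[0]
    assert row["frac_recovered"] == pytest.approx(0.5)
    assert row["frac_not_recovered"] == pytest.approx(0.25)
    assert row["frac_different"] == pytest.approx(0.25)
    assert row[["frac_recovered", "frac_not_recovered", "frac_different"]].sum() == pytest.approx(1.0)


def test_recovery_proportions_requires_de_sets_for_default_rule():
    table = pd.DataFrame(
        {"gene": ["g1"], "cluster": "k", "L": 1.0, "O": 2.0, "C": 1.0, "category": ["Recovered"]}
    )
    with pytest.raises(ValueError, match="obese"):
        sr.recovery_proportions(table, "obese_de_only")
    props = sr.recovery_proportions(table, "obese_de_only", {"k": {"g1"}})
    assert props.iloc[0]["frac_recovered"] == 1.0


def test_cluster_overlap_histogram_matches_hand_tally():
    rows = []
    # g1 Recovered in 3 clusters, g2 Recovered in 1, g3 Different in all 4
    for cl in ("a", "b", "c"):
        rows.append(("g1", cl, "Recovered"))
    rows.append(("g1", "d", "NotRecovered"))
    rows.append(("g2", "a", "Recovered"))
    for cl in ("a", "b", "c", "d"):
        rows.append(("g3", cl, "Different"))
    table = pd.DataFrame(rows, columns=["gene", "cluster", "category"])
    hist = sr.cluster_overlap_distribution(table)
    rec = hist[hist["category"] == "Recovered"].set_index("n_clusters")["n_genes"]
    assert rec.to_dict() == {1: 1, 3: 1}
    nr = hist[hist["category"] == "NotRecovered"].set_index("n_clusters")["n_genes"]
    assert nr.to_dict() == {1: 1}
    diff = hist[hist["category"] == "Different"].set_index("n_clusters")["n_genes"]
    assert diff.to_dict() == {4: 1}


def test_empty_gene_set_warns_and_returns_empty(small_sim):
    adata, _ = small_sim
    with pytest.warns(UserWarning, match="empty"):
        table = sr.build_recovery_table(adata, [])
    assert table.empty
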