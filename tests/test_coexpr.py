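"""Core differential co-expression machinery: correlation contexts,
permutation null, scores, edge classification and network views."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from erynet import coexpr
from erynet.coexpr import NetworkConfig

from conftest import toy_matrix


def _random_matrix(n_genes=30, seed=0):
    rng = np.random.default_rng(seed)
    strains = ["WT"] * 6 + ["HP"] * 6
    times = ["t1", "t1", "t1", "t2", "t2", "t2"] * 2
    reps = [1, 2, 3] * 4
    return toy_matrix(rng.normal(size=(n_genes, 12)), strains, times, reps)


def test_pearson_worked_example():
    r = np.corrcoef([1, 2, 3, 4], [1, 3, 2, 4])[0, 1]
    assert r == pytest.approx(0.8)
    m = toy_matrix(
        [[1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0]],
        strains=["WT"] * 4, times=["t1", "t2", "t3", "t4"], replicates=[1] * 4,
    )
    ctx = coexpr.correlation_matrices(m, contexts=("ALL",))["ALL"]
    assert ctx.r_of("g0", "g1") == pytest.approx(0.8)


def test_contexts_split_samples(clean_matrix):
    contexts = coexpr.correlation_matrices(clean_matrix)
    assert contexts["ALL"].n_samples == 22
    assert contexts["WT"].n_samples == 10
    assert contexts["HP"].n_samples == 12
    # spot check against numpy on a submatrix
    sub = clean_matrix.values.iloc[:5][contexts["WT"].sample_ids]
    np.testing.assert_allclose(contexts["WT"].r[:5, :5], np.corrcoef(sub), atol=1e-12)


def test_constant_gene_masked_nan():
    m = _random_matrix()
    m.values.iloc[0] = 5.0  # constant
    ctx = coexpr.correlation_matrices(m, contexts=("ALL",))["ALL"]
    assert np.isnan(ctx.r[0, 1]) and np.isnan(ctx.r[0, 0])
    assert not ctx.valid[0] and ctx.valid[1]


def test_too_few_samples_raises():
    m = toy_matrix([[1.0, 2.0]], strains=["WT", "HP"], times=["t1", "t1"])
    with pytest.raises(ValueError, match="fewer than 3"):
        coexpr.correlation_matrices(m, contexts=("WT",))


def test_permutation_null_deterministic_and_shaped():
    rng = np.random.default_rng(2)
    vals = rng.normal(size=(20, 12))
    a = coexpr.permutation_null(vals, n_perm=10, seed=4)
    b = coexpr.permutation_null(vals, n_perm=10, seed=4)
    assert (a == b).all()
    assert a.size == 10 * (20 * 19) // 2
    c = coexpr.permutation_null(vals, n_perm=10, seed=5)
    assert not (a == c).all()
    with pytest.raises(ValueError):
        coexpr.permutation_null(vals, n_perm=0, seed=0)


def test_permutation_null_subsampling_cap():
    rng = np.random.default_rng(3)
    vals = rng.normal(size=(50, 10))  # 1225 pairs
    capped = coexpr.permutation_null(vals, n_perm=3, seed=0, max_values_per_round=100)
    assert capped.size == 300


def test_corr_pvalues_manual_count():
    null = np.sort(np.abs(np.array([-0.9, -0.1, 0.2, 0.5, 0.7])))
    # |r|=0.6: null values >= 0.6 are {0.7, 0.9} -> p = (1+2)/(1+5)
    assert coexpr.corr_pvalues(0.6, null) == pytest.approx(3.0 / 6.0)
    # r exceeding the whole null: add-one floor
    assert coexpr.corr_pvalues(0.95, null) == pytest.approx(1.0 / 6.0)
    # ties count as >= (side="left")
    assert coexpr.corr_pvalues(0.5, null) == pytest.approx(4.0 / 6.0)
    out = coexpr.corr_pvalues(np.array([0.6, np.nan]), null)
    assert np.isnan(out[1]) and out[0] == pytest.approx(0.5)


def test_permutation_p_matches_t_based_p():
    """The reshuffling null must agree with the exact t-based Pearson p."""
    rng = np.random.default_rng(6)
    n = 22
    diffs = []
    for i in range(20):
        x, y = rng.normal(size=n), rng.normal(size=n)
        r = np.corrcoef(x, y)[0, 1]
        null = np.sort(np.abs(coexpr.permutation_null(
            np.vstack([x, y]), n_perm=4000, seed=50 + i)))
        p_perm = coexpr.corr_pvalues(r, null)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p_t = 2 * stats.t.sf(abs(t), n - 2)
        diffs.append(abs(p_perm - p_t))
    assert np.mean(diffs) < 0.02


def test_bh_qvalues_matches_brute_force():
    rng = np.random.default_rng(7)
    p = rng.uniform(size=500)
    q = coexpr.bh_qvalues(p)
    order = np.argsort(p, kind="stable")
    brute = np.empty_like(p)
    prev = 1.0
    for rank in range(len(p) - 1, -1, -1):
        i = order[rank]
        prev = min(prev, p[i] * len(p) / (rank + 1))
        brute[i] = prev
    np.testing.assert_array_equal(q, brute)
    withnan = coexpr.bh_qvalues(np.array([0.01, np.nan, 0.5]))
    assert np.isnan(withnan[1]) and not np.isnan(withnan[0])


def test_anchor_scores_hand_computed():
    m = toy_matrix(
        [[1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0], [4.0, 3.0, 2.0, 1.0]],
        strains=["WT"] * 4, times=["t1", "t2", "t3", "t4"], replicates=[1] * 4,
    )
    ctx = coexpr.correlation_matrices(m, contexts=("ALL",))["ALL"]
    scores = coexpr.anchor_scores(ctx, ery_members=["g0", "g1"], mutated_genes=["g2"])
    # g2: r to g0 = -1, to g1 = -0.8 -> ery_score = 1 + 0.64
    assert scores.loc["g2", "ery_score"] == pytest.approx(1.64)
    # g0: member itself -> only r(g0,g1)^2 counts (self excluded)
    assert scores.loc["g0", "ery_score"] == pytest.approx(0.64)
    # mut_score of g0 = r(g0,g2)^2 = 1; of g2 itself = 0 (self excluded)
    assert scores.loc["g0", "mut_score"] == pytest.approx(1.0)
    assert scores.loc["g2", "mut_score"] == 0.0


def test_top_fraction_filter_ties_and_bounds():
    s = pd.Series([5.0, 4.0, 4.0, 1.0], index=list("abcd"))
    sel = coexpr.top_fraction_filter(s, 0.5)
    assert set(sel) == {"a", "b", "c"}  # tie at the boundary included
    assert set(coexpr.top_fraction_filter(s, 1.0)) == set("abcd")
    with pytest.raises(ValueError):
        coexpr.top_fraction_filter(s, 0.0)


def test_classify_edge_branches():
    ce = coexpr.classify_edge
    assert ce(0.9, 0.001, 0.9, 0.001) == "maintained"
    assert ce(0.9, 0.001, -0.9, 0.001) == "perturbed"      # sign flip
    assert ce(0.9, 0.001, 0.1, 0.5) == "perturbed"         # lost in HP
    assert ce(0.9, 0.001, 0.5, 0.02) == "none"             # grey zone
    assert ce(0.2, 0.5, 0.2, 0.5, p_all=0.001) == "global"
    assert ce(0.2, 0.5, 0.2, 0.5, p_all=0.5) == "none"
    assert ce(np.nan, np.nan, 0.9, 0.001) == "none"
    assert ce(0.9, 0.001, np.nan, np.nan) == "perturbed"   # undefined in HP


def test_classify_edges_symmetric(clean_matrix):
    contexts = coexpr.correlation_matrices(clean_matrix)
    coexpr.attach_permutation_null(contexts, clean_matrix, n_perm=20, seed=0)
    genes = list(clean_matrix.genes[:6])
    e1 = coexpr.classify_edges(contexts, genes)
    e2 = coexpr.classify_edges(contexts, genes[::-1])
    m1 = {frozenset((a, b)): c for a, b, c in zip(e1["gene1"], e1["gene2"], e1["class"])}
    m2 = {frozenset((a, b)): c for a, b, c in zip(e2["gene1"], e2["gene2"], e2["class"])}
    assert m1 == m2


def test_pvalues_require_attached_null(clean_matrix):
    ctx = coexpr.correlation_matrices(clean_matrix, contexts=("ALL",))["ALL"]
    with pytest.raises(ValueError, match="null not attached"):
        ctx.pvalues(0.5)


def test_build_network_modes(clean_matrix, default_sim):
    _, truth = default_sim
    contexts = coexpr.correlation_matrices(clean_matrix)
    coexpr.attach_permutation_null(contexts, clean_matrix, n_perm=100, seed=0)
    ery = truth.module_genes("ery")
    mutated = truth.mutated_genes
    change = truth.expected_logfc.abs().max(axis=1)
    cfg = NetworkConfig(mut_p_maintained=0.005, mut_p_perturbed=0.005)

    g_m = coexpr.build_network("maintained_mutation", contexts, ery, mutated,
                               change_score=change, config=cfg)
    assert g_m.number_of_edges() > 0
    assert all(d["edge_class"] == "maintained" for _, _, d in g_m.edges(data=True))

    g_p = coexpr.build_network("fig3c", contexts, ery, mutated,
                               change_score=change, config=cfg)
    assert all(d["edge_class"] == "perturbed" for _, _, d in g_p.edges(data=True))

    g_g = coexpr.build_network("global_anchor", contexts, ery, mutated,
                               change_score=change, config=cfg)
    assert set(g_g.nodes) <= set(coexpr.top_fraction_filter(change, cfg.change_top_fraction))

    g_r = coexpr.build_network("anchor_regulators", contexts, ery, mutated,
                               regulator_genes=["G0025", "G0026"], config=cfg)
    for u, v in g_r.edges():
        assert (u in set(ery)) != (v in set(ery))

    with pytest.raises(ValueError, match="unknown network mode"):
        coexpr.build_network("nope", contexts, ery, mutated)
    with pytest.raises(ValueError, match="change score"):
        coexpr.build_network("global_anchor", contexts, ery, mutated)
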