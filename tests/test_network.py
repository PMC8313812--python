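"""Similarity panels, permutation/bootstrap edge tests, measure merging and
network assembly."""

import numpy as np
import pytest
from scipy import stats

import coresponse as cr
from coresponse.network import MergedEdge, RebootResult, merge_measures


# ---------------------------------------------------------------------------
# Similarity measures


def test_pair_score_closed_forms():
    x = np.arange(1.0, 10.0)
    assert cr.pair_score(x, 2.0 * x, "pearson") == pytest.approx(1.0)
    assert cr.pair_score(x, x, "bray_curtis") == pytest.approx(0.0)
    assert cr.pair_score(x, x, "kld") == pytest.approx(0.0)
    # (2,1) vs (1,2): Bray-Curtis 2/6; symmetrized KL (1/3) ln 2
    assert cr.pair_score([2, 1], [1, 2], "bray_curtis") == pytest.approx(1 / 3)
    assert cr.pair_score([2, 1], [1, 2], "kld") == pytest.approx(np.log(2) / 3)


def test_pair_score_matches_reference_implementations():
    rng = np.random.default_rng(0)
    x, y = rng.lognormal(0, 1, 9), rng.lognormal(0, 1, 9)
    assert cr.pair_score(x, y, "pearson") == pytest.approx(
        stats.pearsonr(x, y).statistic)
    assert cr.pair_score(x, y, "spearman") == pytest.approx(
        stats.spearmanr(x, y).statistic)
    from scipy.spatial.distance import braycurtis

    assert cr.pair_score(x, y, "bray_curtis") == pytest.approx(braycurtis(x, y))
    p, q = x / x.sum(), y / y.sum()
    expected = 0.5 * (stats.entropy(p, q) + stats.entropy(q, p))
    assert cr.pair_score(x, y, "kld") == pytest.approx(expected)


@pytest.mark.parametrize("measure", cr.MEASURES)
def test_score_pairs_matches_pairwise_calls_and_is_symmetric(measure, bs_design):
    import pandas as pd

    rng = np.random.default_rng(4)
    table = cr.OtuTable(
        pd.DataFrame(rng.integers(1, 100, (6, 6)).astype(float),
                     index=list("abcdef"), columns=bs_design.sample_ids),
        "counts")
    ratios = cr.compute_ratios(table, bs_design, "BS")
    panel = cr.score_pairs(ratios, measure)
    for a, b in [("a", "b"), ("c", "f"), ("e", "d")]:
        direct = cr.pair_score(ratios.data.loc[a], ratios.data.loc[b], measure)
        assert panel.score(a, b) == pytest.approx(direct)
        assert panel.score(b, a) == pytest.approx(direct)


def test_zero_variance_profile_gives_nan_correlation(bs_design):
    import pandas as pd

    cols = bs_design.sample_ids
    table = cr.OtuTable(
        pd.DataFrame([[5.0] * 6, [1, 2, 3, 4, 5, 6]], index=["flat", "var"],
                     columns=cols), "counts")
    ratios = cr.compute_ratios(table, bs_design, "BS")
    panel = cr.score_pairs(ratios, "pearson")
    assert np.isnan(panel.score("flat", "var"))


# ---------------------------------------------------------------------------
# ReBoot test


def test_identical_vectors_are_strongly_associated():
    x = np.arange(1.0, 10.0)
    for measure in cr.MEASURES:
        res = cr.reboot_test(x, x.copy(), measure, n_perm=1000, n_boot=200, seed=5)
        assert res.direction == "associated"
        assert res.p < 0.01


def test_constant_vector_is_degenerate():
    res = cr.reboot_test(np.ones(9), np.arange(1.0, 10.0), "pearson", seed=1)
    assert res.p == 1.0 and res.direction is None


def test_reboot_is_symmetric_in_arguments():
    rng = np.random.default_rng(9)
    x, y = rng.lognormal(0, 1, 9), rng.lognormal(0, 1, 9)
    for measure in cr.MEASURES:
        a = cr.reboot_test(x, y, measure, n_perm=200, seed=7)
        b = cr.reboot_test(y, x, measure, n_perm=200, seed=7)
        assert a.p == b.p and a.direction == b.direction
        assert a.observed == pytest.approx(b.observed)


def test_anticorrelated_vectors_are_anti_associated():
    x = np.arange(1.0, 10.0)
    y = x[::-1].copy()
    res = cr.reboot_test(x, y, "spearman", n_perm=500, seed=3)
    assert res.direction == "anti-associated"
    assert res.p < 0.05


def test_small_n_perm_warns():
    x = np.arange(1.0, 10.0)
    with pytest.warns(UserWarning, match="n_perm"):
        cr.reboot_test(x, x + 1, "pearson", n_perm=50, seed=0)


def test_pooled_z_variant_is_stricter_under_the_null():
    """The bootstrap-vs-permutation pooled z penalizes unstable scores."""
    rng = np.random.default_rng(12)
    ps_perm, ps_pool = [], []
    for i in range(40):
        x, y = rng.uniform(0.1, 10, 9), rng.uniform(0.1, 10, 9)
        ps_perm.append(cr.reboot_test(x, y, "pearson", n_perm=200, n_boot=200,
                                      seed=i).p)
        ps_pool.append(cr.reboot_test(x, y, "pearson", n_perm=200, n_boot=200,
                                      seed=i, p_method="pooled_z").p)
    assert np.mean(ps_pool) > np.mean(ps_perm) - 0.05
    assert np.mean(np.array(ps_pool) < 0.05) <= np.mean(np.array(ps_perm) < 0.05)


# ---------------------------------------------------------------------------
# Measure merging


def _res(measure, p, direction="associated"):
    return RebootResult(measure, 0.5, p, direction)


def test_unanimous_measures_merge_no_worse_than_each():
    results = [_res(m, 0.01) for m in cr.MEASURES]
    merged = merge_measures(results, method="fisher")
    assert merged is not None and merged.sign == 1
    assert merged.p <= 0.01
    merged_brown = merge_measures(results, method="brown",
                                  score_correlations=np.eye(4))
    assert merged_brown.p <= 0.01


def test_split_directions_rejected():
    results = [_res("pearson", 0.01), _res("spearman", 0.01),
               _res("bray_curtis", 0.01, "anti-associated"),
               _res("kld", 0.01, "anti-associated")]
    assert merge_measures(results, min_support=3) is None
    assert merge_measures(results, min_support=2) is None  # tie -> no majority


def test_fisher_combination_arithmetic():
    """p = (0.1, 0.1): X^2 = -2(ln .1 + ln .1) = 9.210, df 4 -> p = 0.0562."""
    results = [_res("pearson", 0.1), _res("spearman", 0.1)]
    merged = merge_measures(results, method="fisher", min_support=2)
    assert merged.p == pytest.approx(0.056052, abs=1e-4)


def test_brown_correction_discounts_dependent_measures():
    results = [_res(m, 0.01) for m in cr.MEASURES]
    indep = merge_measures(results, method="brown", score_correlations=np.eye(4))
    dep = merge_measures(results, method="brown",
                         score_correlations=np.ones((4, 4)))
    assert dep.p > indep.p  # perfectly dependent evidence counts once


def test_anti_associated_majority_gives_negative_sign():
    results = [_res(m, 0.02, "anti-associated") for m in cr.MEASURES[:3]]
    results.append(_res("kld", 0.5))
    merged = merge_measures(results)
    assert merged.sign == -1 and merged.support == 3


def test_all_undefined_rejected():
    results = [RebootResult(m, np.nan, 1.0, None) for m in cr.MEASURES]
    assert merge_measures(results) is None


# ---------------------------------------------------------------------------
# Network assembly


def test_benjamini_hochberg_matches_brute_force():
    """statsmodels' BH step-up agrees with a from-scratch implementation."""
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(8)
    for _ in range(20):
        m = int(rng.integers(1, 40))
        ps = rng.uniform(0, 1, m)
        reject, _, *_ = multipletests(ps, alpha=0.05, method="fdr_bh")
        order = np.argsort(ps)
        k = 0
        for rank, idx in enumerate(order, start=1):
            if ps[idx] <= 0.05 * rank / m:
                k = rank
        expected = np.zeros(m, bool)
        expected[order[:k]] = True
        np.testing.assert_array_equal(reject, expected)


def test_single_planted_pair_recovered(small_network):
    net, table, taxonomy, design, truth, filtered = small_network
    members = [o for o, m in truth.modules.items() if m is not None]
    found = [(a, b) for a, b, _ in truth.planted_edges
             if net.graph.get_edge_data(a, b)]
    assert found, "no planted edge recovered"
    for a, b, sign in truth.planted_edges:
        e = net.graph.get_edge_data(a, b)
        if e:
            assert e["sign"] == ("positive" if sign > 0 else "negative")


def test_network_structure_invariants(small_network):
    net = small_network[0]
    g = net.graph
    assert all(a != b for a, b in g.edges)  # no self-loops
    assert all(g.degree(n) >= 1 for n in g.nodes)  # no isolated nodes
    assert sum(dict(g.degree()).values()) == 2 * g.number_of_edges()
    table = net.edge_table()
    assert (table["q"] <= net.config.alpha_edge).all()
    assert (table["support"] >= net.config.min_support).all()


def test_build_network_is_deterministic(bs_design):
    import pandas as pd

    rng = np.random.default_rng(2)
    table = cr.OtuTable(
        pd.DataFrame(rng.integers(1, 200, (12, 6)).astype(float),
                     index=[f"o{i}" for i in range(12)],
                     columns=bs_design.sample_ids), "counts")
    ratios = cr.compute_ratios(table, bs_design, "BS")
    cfg = cr.NetworkConfig(seed=9, n_perm=200, n_boot=0)
    t1 = cr.build_network(ratios, None, cfg).edge_table()
    t2 = cr.build_network(ratios, None, cfg).edge_table()
    pd.testing.assert_frame_equal(t1, t2)


def test_prefilter_only_reduces_tested_pairs(bs_design):
    import pandas as pd

    rng = np.random.default_rng(6)
    table = cr.OtuTable(
        pd.DataFrame(rng.integers(1, 200, (15, 6)).astype(float),
                     index=[f"o{i}" for i in range(15)],
                     columns=bs_design.sample_ids), "counts")
    ratios = cr.compute_ratios(table, bs_design, "BS")
    full = cr.build_network(ratios, None, cr.NetworkConfig(seed=1, n_perm=200, n_boot=0))
    pre = cr.build_network(ratios, None,
                           cr.NetworkConfig(seed=1, n_perm=200, n_boot=0,
                                            prefilter_quantile=0.05))
    assert pre.n_pairs_tested < full.n_pairs_tested


def test_graphml_and_edge_list_exports(small_network, tmp_path):
    import networkx as nx

    net = small_network[0]
    net.write_edge_list(tmp_path / "edges.tsv")
    net.write_graphml(tmp_path / "net.graphml")
    back = nx.read_graphml(tmp_path / "net.graphml")
    assert back.number_of_edges() == net.graph.number_of_edges()
    first = next(iter(back.nodes(data=True)))[1]
    assert {"kingdom", "phylum"} <= set(first)
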