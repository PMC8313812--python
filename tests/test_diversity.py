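"""Rarefaction, Shannon, group comparison, Bray-Curtis/PCoA/UPGMA and
differential abundance."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import coresponse as cr
from coresponse import diversity as dv
from coresponse.tables import DegenerateInputError


# ---------------------------------------------------------------------------
# Shannon


def test_shannon_closed_forms():
    assert dv.shannon([5, 5, 5, 5], base=2) == pytest.approx(2.0)
    assert dv.shannon([7, 0, 0], base=2) == pytest.approx(0.0)
    # [1,1,2]: -(0.25 ln 0.25 * 2 + 0.5 ln 0.5)
    assert dv.shannon([1, 1, 2], base=np.e) == pytest.approx(1.039720, abs=1e-6)
    with pytest.raises(DegenerateInputError):
        dv.shannon([0, 0])


def test_shannon_maximal_at_uniform_and_evenness_monotone():
    rng = np.random.default_rng(0)
    for _ in range(20):
        v = rng.integers(1, 100, 6).astype(float)
        assert dv.shannon(v) <= dv.shannon(np.full(6, v.mean())) + 1e-12
    # transferring abundance from a rich to a poor OTU raises H
    v = np.array([50.0, 10.0, 10.0])
    assert dv.shannon([45, 15, 10]) > dv.shannon(v)


# ---------------------------------------------------------------------------
# Rarefaction


def test_rarefy_exhaustive_and_impossible_draws():
    counts = np.array([4, 0, 3])
    np.testing.assert_array_equal(dv.rarefy(counts, 7, seed=1), counts)
    sub = dv.rarefy(np.array([5, 0]), 3, seed=2)
    assert sub[1] == 0 and sub.sum() == 3
    with pytest.raises(ValueError, match="depth"):
        dv.rarefy(counts, 8, seed=0)


def test_rarefy_mean_matches_hypergeometric():
    """[500, 500] at depth 100: mean first-OTU count within 50 +- 5."""
    rng = np.random.default_rng(11)
    draws = [dv.rarefy(np.array([500, 500]), 100, rng)[0] for _ in range(1000)]
    assert abs(np.mean(draws) - 50) <= 5
    expected_var = 100 * 0.5 * 0.5 * (900 / 999)
    assert np.var(draws) == pytest.approx(expected_var, rel=0.2)


def test_rarefaction_series_grid():
    table = cr.OtuTable(pd.DataFrame({"s": [10.0, 10.0]}, index=["a", "b"]),
                        "counts")
    res = dv.rarefaction_series(table, increment=20, iterations=10,
                                max_depth=20, seed=0)
    assert len(res.records) == 10
    assert (res.records["depth"] == 20).all()
    assert (res.records["richness"] <= 2).all()


@pytest.mark.parametrize("increment,max_depth", [(3900, 39000), (1400, 14000)])
def test_survey_depth_grids_have_ten_points(increment, max_depth):
    """Both marker-gene configurations step through 10 depth points."""
    table = cr.OtuTable(
        pd.DataFrame({"s": [float(max_depth)]}, index=["a"]), "counts")
    res = dv.rarefaction_series(table, increment=increment, iterations=1,
                                max_depth=max_depth, seed=0)
    assert sorted(res.records["depth"].unique()) == [
        increment * k for k in range(1, 11)]


def test_shallow_sample_excluded_with_warning():
    table = cr.OtuTable(pd.DataFrame({"deep": [100.0], "shallow": [5.0]},
                                     index=["a"]), "counts")
    with pytest.warns(UserWarning, match="shallow"):
        res = dv.rarefaction_series(table, increment=50, iterations=2,
                                    max_depth=100, seed=0)
    assert set(res.records["sample"]) == {"deep"}


# ---------------------------------------------------------------------------
# Alpha comparison


def _design_two_groups():
    rows = []
    for comp, trt in [("BS", "FI"), ("BS", "DI")]:
        for rep in (1, 2, 3):
            rows.append((f"{comp}-{trt}-{rep}", comp, trt, rep))
    return cr.SampleDesign(pd.DataFrame(
        [(c, t, r) for _, c, t, r in rows], index=[s for s, *_ in rows],
        columns=["compartment", "treatment", "replicate"]))


def _fake_result(values_by_sample, depth=100):
    rows = [(s, depth, i, v, float(v)) for s, vals in values_by_sample.items()
            for i, v in enumerate(vals)]
    records = pd.DataFrame(rows, columns=["sample", "depth", "iteration",
                                          "richness", "shannon"])
    return dv.RarefactionResult(records, max_depth=depth, increment=depth,
                                iterations=len(next(iter(values_by_sample.values()))))


def test_identical_groups_not_significant():
    design = _design_two_groups()
    result = _fake_result({s: [7.0] * 10 for s in design.sample_ids})
    cmp_res = dv.compare_alpha(result, design)
    assert cmp_res.kruskal_p == 1.0
    letters = set(cmp_res.letters.values())
    assert len(letters) == 1  # same letter everywhere


def test_shifted_groups_detected_by_dunn():
    rng = np.random.default_rng(5)
    design = _design_two_groups()
    values = {}
    for s in design.samples("BS", "FI"):
        values[s] = list(10 + rng.normal(0, 0.5, 10))
    for s in design.samples("BS", "DI"):
        values[s] = list(30 + rng.normal(0, 0.5, 10))
    cmp_res = dv.compare_alpha(_fake_result(values), design)
    assert cmp_res.kruskal_p < 0.05
    assert (cmp_res.dunn["p"] < 0.05).all()
    assert cmp_res.letters["BS-FI"] != cmp_res.letters["BS-DI"]


def test_kruskal_matches_brute_force_rank_statistic():
    """H from pooled mean ranks on a 3-group toy equals scipy's value."""
    groups = [[1.2, 3.4, 5.6], [2.2, 8.8, 9.9, 4.4], [0.1, 0.2]]
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        start += len(g)
    h *= 12 / (n * (n + 1))
    assert stats.kruskal(*groups).statistic == pytest.approx(h)


# ---------------------------------------------------------------------------
# Beta diversity


def test_bray_curtis_closed_forms():
    frame = pd.DataFrame({"a": [2.0, 1.0], "b": [1.0, 2.0], "c": [2.0, 1.0],
                          "d": [3.0, 0.0], "e": [0.0, 3.0]}, index=["x", "y"])
    dm = dv.bray_curtis(cr.OtuTable(frame, "counts"))
    f = dm.to_frame()
    assert f.loc["a", "c"] == pytest.approx(0.0)      # identical samples
    assert f.loc["d", "e"] == pytest.approx(1.0)      # disjoint support
    assert f.loc["a", "b"] == pytest.approx(1 / 3)    # |2-1|+|1-2| over 6


def test_bray_curtis_bounds_and_degenerate_pair():
    rng = np.random.default_rng(2)
    frame = pd.DataFrame(rng.integers(0, 30, (8, 5)).astype(float),
                         index=[f"o{i}" for i in range(8)],
                         columns=list("abcde"))
    frame += 0.1  # avoid all-zero columns
    dm = dv.bray_curtis(cr.OtuTable(frame, "counts"))
    assert ((dm.matrix >= 0) & (dm.matrix <= 1)).all()
    bad = pd.DataFrame({"a": [0.0], "b": [0.0], "c": [1.0]}, index=["x"])
    with pytest.raises(DegenerateInputError):
        dv.bray_curtis(cr.OtuTable(bad, "counts"))


def test_aggregate_to_rank_sums_and_conserves(planted_community):
    table, taxonomy, _, _ = planted_community
    agg = dv.aggregate_to_rank(table, taxonomy, "phylum")
    np.testing.assert_allclose(agg.values().sum(axis=0),
                               table.values().sum(axis=0))
    kingdoms = dv.aggregate_to_rank(table, taxonomy, "kingdom")
    assert kingdoms.shape[0] == 2  # Bacteria and Fungi


def test_aggregate_two_otus_same_phylum():
    frame = pd.DataFrame({"s": [3.0, 4.0]}, index=["o1", "o2"])
    taxonomy = cr.TaxonomyMap.from_strings(
        {"o1": "k__Bacteria;p__Firmicutes", "o2": "k__Bacteria;p__Firmicutes"})
    agg = dv.aggregate_to_rank(cr.OtuTable(frame, "counts"), taxonomy, "phylum")
    assert agg.shape == (1, 1)
    assert agg.values()[0, 0] == 7.0


def test_pcoa_equilateral_and_duplicates():
    dm = dv.DistanceMatrix(("a", "b", "c"),
                           np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
    ord_res = dv.pcoa(dm)
    pos = ord_res.eigenvalues[ord_res.eigenvalues > 1e-9]
    assert len(pos) == 2 and pos[0] == pytest.approx(pos[1])
    # duplicated sample lands on the same coordinates
    m = np.array([[0, 0, 2], [0, 0, 2], [2, 2, 0]], float)
    dup = dv.pcoa(dv.DistanceMatrix(("a", "a2", "b"), m))
    np.testing.assert_allclose(dup.coordinates.iloc[0], dup.coordinates.iloc[1],
                               atol=1e-9)


def test_pcoa_recovers_euclidean_configuration():
    """Distances among PCoA coordinates reproduce the input within 1e-8."""
    rng = np.random.default_rng(1)
    pts = rng.normal(0, 2, (6, 2))
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(pts))
    ord_res = dv.pcoa(dv.DistanceMatrix(tuple("abcdef"), d))
    assert (ord_res.eigenvalues > -1e-9).all()
    back = squareform(pdist(ord_res.coordinates.to_numpy()))
    np.testing.assert_allclose(back, d, atol=1e-8)


def test_pcoa_rejects_asymmetric_input():
    with pytest.raises(ValueError, match="symmetric"):
        dv.DistanceMatrix(("a", "b"), np.array([[0, 1], [2, 0]], float))


def test_upgma_two_and_three_leaves():
    two = dv.upgma(dv.DistanceMatrix(("A", "B"), np.array([[0, 2], [2, 0]], float)))
    assert two == "(A:1,B:1);"
    m = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], float)
    three = dv.upgma(dv.DistanceMatrix(("A", "B", "C"), m))
    assert three.startswith("(C:2,(A:0.5,B:0.5)")  # A,B join first


def _tip_distances(newick: str) -> dict:
    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick))
    tips = sorted(t.name for t in tree.tips())
    out = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1:]:
            out[(a, b)] = tree.find(a).distance(tree.find(b))
    return out


def test_upgma_matches_scipy_cophenetic_distances():
    """Tip-to-tip path lengths equal scipy average-linkage cophenetics."""
    from scipy.cluster.hierarchy import cophenet, linkage
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(3)
    ids = tuple("abcdef")
    for _ in range(10):
        condensed = rng.uniform(1, 10, 15)
        d = squareform(condensed)
        newick = dv.upgma(dv.DistanceMatrix(ids, d))
        coph = squareform(cophenet(linkage(condensed, method="average")))
        dists = _tip_distances(newick)
        for (a, b), val in dists.items():
            i, j = ids.index(a), ids.index(b)
            assert val == pytest.approx(coph[i, j], abs=1e-8)


def test_upgma_is_ultrametric():
    from skbio import TreeNode

    rng = np.random.default_rng(4)
    from scipy.spatial.distance import squareform

    d = squareform(rng.uniform(1, 10, 21))
    newick = dv.upgma(dv.DistanceMatrix(tuple("abcdefg"), d))
    tree = TreeNode.read(io.StringIO(newick))
    depths = {t.name: tree.find(t.name).accumulate_to_ancestor(tree)
              for t in tree.tips()}
    vals = list(depths.values())
    assert max(vals) - min(vals) < 1e-9


# ---------------------------------------------------------------------------
# Differential abundance


def test_t_statistic_matches_hand_computation():
    """FI = (1,2,3), DI = (11,12,13): pooled-variance t = -12.247."""
    design = _design_two_groups()
    cols = design.samples("BS", "FI") + design.samples("BS", "DI")
    frame = pd.DataFrame([[1.0, 2.0, 3.0, 11.0, 12.0, 13.0]], index=["o"],
                         columns=cols)
    out = dv.differential_taxa(cr.OtuTable(frame, "counts"), design, "BS",
                               alpha=0.05)
    row = out.iloc[0]
    assert row["t"] == pytest.approx(-12.247, abs=1e-3)
    assert row["significant"] and row["direction"] == "DI"


def test_identical_groups_and_zero_variance():
    design = _design_two_groups()
    cols = design.samples("BS", "FI") + design.samples("BS", "DI")
    frame = pd.DataFrame([[4.0, 5.0, 6.0, 4.0, 5.0, 6.0],
                          [2.0, 2.0, 2.0, 2.0, 2.0, 2.0]],
                         index=["same", "flat"], columns=cols)
    out = dv.differential_taxa(cr.OtuTable(frame, "counts"), design, "BS")
    same = out[out["taxon"] == "same"].iloc[0]
    flat = out[out["taxon"] == "flat"].iloc[0]
    assert not same["significant"]
    assert not flat["significant"] and np.isnan(flat["t"])


def test_planted_enrichment_detected():
    rng = np.random.default_rng(6)
    design = _design_two_groups()
    cols = design.samples("BS", "FI") + design.samples("BS", "DI")
    fi = rng.normal(10, 0.5, 3)
    di = rng.normal(100, 2.0, 3)
    frame = pd.DataFrame([np.concatenate([fi, di])], index=["up"], columns=cols)
    out = dv.differential_taxa(cr.OtuTable(frame, "counts"), design, "BS")
    assert out.iloc[0]["significant"] and out.iloc[0]["direction"] == "DI"


# ---------------------------------------------------------------------------
# Property: Bray-Curtis of non-negative samples always lies in [0, 1]


from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp


@settings(max_examples=25, deadline=None, derandomize=True)
@given(hnp.arrays(np.int64, (5, 4), elements=st.integers(0, 500)))
def test_bray_curtis_always_bounded(counts):
    counts = counts.astype(float)
    counts[0] += 1  # keep every sample non-empty
    table = cr.OtuTable(
        pd.DataFrame(counts, index=[f"o{i}" for i in range(5)],
                     columns=list("wxyz")), "counts")
    dm = dv.bray_curtis(table)
    assert ((dm.matrix >= 0) & (dm.matrix <= 1)).all()
    assert np.allclose(dm.matrix, dm.matrix.T)
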