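"""Ordinal coding, UPGMA trees, newick serialisation, Robinson-Foulds."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chctax.chemotaxonomy import (
    CodingScheme,
    Dendrogram,
    build_coded_matrix,
    code_profile,
    code_value,
    coded_distances,
    compare_trees,
    upgma,
)
from chctax.multivariate import DistanceMatrix


# ---------------------------------------------------------------------------
# ordinal coding

@pytest.mark.parametrize(
    "pct, expected",
    [(0.02, 1), (39.4, 4), (0.4999, 1), (0.5, 2), (0.99, 2), (1.0, 3),
     (5.0, 3), (5.0001, 4), (0.0, 0)],
)
def test_code_value_bins(pct, expected):
    assert code_value(pct) == expected


def test_nd_codes_zero_regardless_of_value():
    assert code_value(0.3, detected=False) == 0


def test_negative_percentage_errors():
    with pytest.raises(ValueError):
        code_value(-0.1)


def test_code_profile_series():
    s = pd.Series({"a": 0.02, "b": 39.4, "c": 0.0})
    assert code_profile(s).tolist() == [1, 4, 0]


def test_custom_scheme_override():
    scheme = CodingScheme(trace_upper=0.1, minor_upper=2.0, major_upper=10.0)
    assert code_value(0.5, scheme=scheme) == 2
    assert code_value(7.0, scheme=scheme) == 3


def test_coded_matrix_from_population_fixture(catalog, population_profiles):
    means, _, detected = population_profiles
    coded = build_coded_matrix(means, detected, catalog=catalog)
    assert coded.shape == (6, 30)
    assert set(np.unique(coded.values)) <= {0, 1, 2, 3, 4}
    # zero codes exactly equal the number of nd cells
    assert int((coded == 0).sum().sum()) == int((~detected).sum().sum()) == 17
    # re-building from the same summaries is stable
    assert build_coded_matrix(means, detected, catalog=catalog).equals(coded)


def test_coded_matrix_unknown_component_errors(catalog):
    means = pd.DataFrame({"T1": [1.0]}, index=["n-C_99"])
    with pytest.raises(KeyError):
        build_coded_matrix(means, catalog=catalog)


def test_all_nd_taxon_warns(catalog):
    means = pd.DataFrame({"T1": [0.0] * 30}, index=list(catalog.labels))
    with pytest.warns(UserWarning):
        coded = build_coded_matrix(means, catalog=catalog)
    assert (coded.loc["T1"] == 0).all()


# ---------------------------------------------------------------------------
# UPGMA

def test_upgma_three_taxa_closed_form():
    d = DistanceMatrix(np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], float),
                       ("A", "B", "C"))
    tree = upgma(d)
    assert tree.root.height == pytest.approx(4.0)
    (inner,) = [c for c in tree.root.children if not c.is_leaf]
    assert set(inner.leaf_names()) == {"A", "B"}
    assert inner.height == pytest.approx(1.0)


def _upgma_oracle_cophenetic(dm):
    """Independent naive UPGMA using label-set bookkeeping."""
    clusters = {frozenset([i]): 0.0 for i in range(len(dm))}
    dist = {
        frozenset([frozenset([i]), frozenset([j])]): dm[i, j]
        for i in range(len(dm)) for j in range(i + 1, len(dm))
    }
    coph = np.zeros_like(dm)
    while len(clusters) > 1:
        pair, dmin = min(dist.items(), key=lambda kv: kv[1])
        a, b = tuple(pair)
        for i in a:
            for j in b:
                coph[i, j] = coph[j, i] = dmin
        merged = a | b
        new = {}
        for c in clusters:
            if c in (a, b):
                continue
            dac = dist[frozenset([a, c])]
            dbc = dist[frozenset([b, c])]
            new[frozenset([merged, c])] = (len(a) * dac + len(b) * dbc) / len(merged)
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
        dist.update(new)
        del clusters[a], clusters[b]
        clusters[merged] = dmin / 2.0
    return coph


def test_upgma_matches_exhaustive_oracle_on_random_matrices():
    rng = np.random.default_rng(4)
    for n in (4, 5, 6):
        for _ in range(10):
            cond = rng.uniform(0.1, 1.0, size=n * (n - 1) // 2)
            from scipy.spatial.distance import squareform

            mat = squareform(cond)
            d = DistanceMatrix(mat, tuple(chr(65 + i) for i in range(n)))
            tree = upgma(d)
            coph = tree.cophenetic()
            oracle = _upgma_oracle_cophenetic(mat)
            # oracle indexes by position; tree cophenetic sorts labels,
            # which here coincide with positions (A, B, C, ...)
            assert np.allclose(coph.values, oracle, atol=1e-12)


def test_upgma_matches_scipy_average_linkage():
    from scipy.cluster.hierarchy import cophenet, linkage
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(7)
    cond = rng.uniform(0.1, 1.0, size=21)  # 7 items, distinct distances
    d = DistanceMatrix(squareform(cond), tuple(chr(65 + i) for i in range(7)))
    mine = upgma(d).cophenetic().values
    theirs = squareform(cophenet(linkage(cond, method="average")))
    assert np.allclose(mine, theirs, atol=1e-12)


def test_upgma_output_is_ultrametric():
    rng = np.random.default_rng(10)
    from scipy.spatial.distance import squareform

    mat = squareform(rng.uniform(0.1, 1.0, size=45))  # 10 items
    tree = upgma(DistanceMatrix(mat, tuple(f"t{i}" for i in range(10))))

    def check(node):
        for ch in node.children:
            assert ch.height <= node.height + 1e-12
            check(ch)

    check(tree.root)
    # three-point condition on cophenetic distances
    c = tree.cophenetic().values
    for i, j, k in itertools.combinations(range(10), 3):
        assert max(c[i, j], c[i, k], c[j, k]) == pytest.approx(
            sorted([c[i, j], c[i, k], c[j, k]])[1], abs=1e-12
        )


def test_upgma_deterministic_under_ties():
    d = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ("D", "C", "B", "A"))
    assert upgma(d).to_newick() == upgma(d).to_newick()
    # lexicographic tie-break merges A,B first
    assert upgma(d).to_newick().startswith("(((A:0.5,B:0.5)")


def test_population_tree_joins_ghim_with_ychl_first(catalog, population_profiles):
    """UPGMA on Bray-Curtis of the coded population matrix pairs GHIM and
    YCHL before either joins any other population."""
    means, _, detected = population_profiles
    coded = build_coded_matrix(means, detected, catalog=catalog)
    tree = upgma(coded_distances(coded))

    def smallest_clade_with(node, a, b):
        for ch in node.children:
            hit = smallest_clade_with(ch, a, b)
            if hit is not None:
                return hit
        names = set(node.leaf_names())
        if a in names and b in names:
            return names
        return None

    assert smallest_clade_with(tree.root, "GHIM", "YCHL") == {"GHIM", "YCHL"}


# ---------------------------------------------------------------------------
# newick serialisation

def test_newick_roundtrip_byte_stable():
    rng = np.random.default_rng(3)
    from scipy.spatial.distance import squareform

    mat = squareform(rng.uniform(0.1, 1.0, size=10))
    tree = upgma(DistanceMatrix(mat, ("E", "A", "C", "B", "D")))
    nwk = tree.to_newick()
    again = Dendrogram.from_newick(nwk).to_newick()
    assert again == nwk
    third = Dendrogram.from_newick(again).to_newick()
    assert third == nwk


def test_newick_roundtrip_preserves_heights():
    d = DistanceMatrix(np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], float),
                       ("A", "B", "C"))
    tree = upgma(d)
    back = Dendrogram.from_newick(tree.to_newick())
    assert np.allclose(back.cophenetic().values, tree.cophenetic().values)


def test_non_ultrametric_newick_rejected():
    with pytest.raises(ValueError):
        Dendrogram.from_newick("((A:1,B:2):1,C:5);")


# ---------------------------------------------------------------------------
# Robinson-Foulds

def test_rf_identical_trees_zero():
    nwk = "((A:1,B:1):1,(C:1,D:1):1);"
    res = compare_trees(nwk, nwk)
    assert res.rf == 0
    assert res.normalized == 0.0


def test_rf_distinct_four_leaf_topologies():
    a = "((A:1,B:1):1,(C:1,D:1):1);"
    b = "((A:1,C:1):1,(B:1,D:1):1);"
    res = compare_trees(a, b)
    assert res.rf == 2
    assert res.normalized == 1.0


def test_rf_caterpillar_vs_balanced_six_leaves():
    cat = "(((((A:1,B:1):1,C:2):1,D:3):1,E:4):1,F:5);"
    bal = "(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):2);"

    def oracle_bipartitions(nested, leaves):
        # brute force: collect leaf sets of every internal edge
        out = set()

        def walk(node):
            if isinstance(node, str):
                return frozenset([node])
            s = frozenset().union(*(walk(ch) for ch in node))
            if 2 <= len(s) <= len(leaves) - 2:
                out.add(frozenset([s, frozenset(leaves) - s]))
            return s

        walk(nested)
        return out

    leaves = {"A", "B", "C", "D", "E", "F"}
    pa = oracle_bipartitions(((((("A", "B"), "C"), "D"), "E"), "F"), leaves)
    pb = oracle_bipartitions(((("A", "B"), ("C", "D")), ("E", "F")), leaves)
    expected = len(pa ^ pb)
    assert compare_trees(cat, bal).rf == expected


def test_rf_matches_dendropy_on_random_trees():
    import dendropy
    from dendropy.calculate import treecompare
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(21)
    labels = tuple("ABCDEF")
    for _ in range(10):
        m1 = squareform(rng.uniform(0.1, 1.0, size=15))
        m2 = squareform(rng.uniform(0.1, 1.0, size=15))
        t1 = upgma(DistanceMatrix(m1, labels)).to_newick()
        t2 = upgma(DistanceMatrix(m2, labels)).to_newick()
        mine = compare_trees(t1, t2).rf
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1, schema="newick", taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=t2, schema="newick", taxon_namespace=tns)
        assert mine == treecompare.symmetric_difference(d1, d2)


def test_rf_mismatched_leaves_error():
    with pytest.raises(ValueError, match="only in"):
        compare_trees("((A:1,B:1):1,C:2);", "((A:1,B:1):1,D:2);")
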