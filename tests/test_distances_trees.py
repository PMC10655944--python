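import io

import numpy as np
import pytest

from morphoblocks.distances_trees import (
    DistanceMatrix,
    geographic_matrix,
    haversine_km,
    mahalanobis_matrix,
    mantel_test,
    neighbor_joining,
    permutation_significance,
    write_newick,
)


def whitened_groups(rng, means, n_per_group=6):
    """Groups whose pooled within-group covariance is exactly identity."""
    g = len(means)
    d = len(means[0])
    n = g * n_per_group
    resid = rng.normal(size=(n, d))
    # remove group means, then whiten the pooled SSCP exactly
    labels = np.repeat([f"g{i}" for i in range(g)], n_per_group)
    for lbl in np.unique(labels):
        resid[labels == lbl] -= resid[labels == lbl].mean(axis=0)
    w = resid.T @ resid / (n - g)
    resid = resid @ np.linalg.inv(np.linalg.cholesky(w)).T
    x = resid + np.repeat(np.asarray(means, float), n_per_group, axis=0)
    return x, labels


class TestMahalanobis:
    def test_identity_covariance_equals_euclidean(self, rng):
        means = [[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]]
        x, labels = whitened_groups(rng, means)
        dm = mahalanobis_matrix(x, labels)
        # group means shift slightly when residuals are re-centred; use
        # the realised means
        real = {g: x[labels == g].mean(axis=0) for g in dm.labels}
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                expected = np.linalg.norm(real[a] - real[b])
                assert dm.values[i, j] == pytest.approx(expected,
                                                        abs=1e-12)

    def test_univariate_reduces_to_pooled_sd_units(self, rng):
        a = rng.normal(0, 2, 30)
        b = rng.normal(5, 2, 20)
        x = np.concatenate([a, b])[:, None]
        labels = ["a"] * 30 + ["b"] * 20
        dm = mahalanobis_matrix(x, labels)
        pooled_var = ((a - a.mean()) ** 2).sum() + \
            ((b - b.mean()) ** 2).sum()
        pooled_sd = np.sqrt(pooled_var / (50 - 2))
        assert dm.values[0, 1] == pytest.approx(
            abs(a.mean() - b.mean()) / pooled_sd, rel=1e-12)

    def test_hand_built_sscp_three_groups(self, rng):
        x = rng.normal(size=(18, 2))
        labels = np.repeat(list("abc"), 6)
        x[labels == "b"] += [2, 1]
        dm = mahalanobis_matrix(x, labels)
        # independent arithmetic: pooled covariance then quadratic form
        w = np.zeros((2, 2))
        means = {}
        for g in "abc":
            xg = x[labels == g]
            means[g] = xg.mean(axis=0)
            r = xg - means[g]
            w += r.T @ r
        s = w / (18 - 3)
        diff = means["a"] - means["b"]
        expected = np.sqrt(diff @ np.linalg.solve(s, diff))
        assert dm.values[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(30, 3))
        labels = np.repeat(list("abc"), 10)
        x[labels == "c"] += 1
        a = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        d1 = mahalanobis_matrix(x, labels)
        d2 = mahalanobis_matrix(x @ a + rng.normal(size=3), labels)
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-8)


class TestPermutationSignificance:
    def test_seed_determinism(self, rng):
        x = rng.normal(size=(30, 2))
        labels = np.repeat(list("abc"), 10)
        t1 = permutation_significance(x, labels, n_perm=99, seed=3)
        t2 = permutation_significance(x, labels, n_perm=99, seed=3)
        assert t1.p.tolist() == t2.p.tolist()

    def test_separated_groups_attain_minimal_p(self, rng):
        x = rng.normal(size=(20, 2))
        labels = np.repeat(["a", "b"], 10)
        x[np.asarray(labels) == "b"] += 50
        table = permutation_significance(x, labels, n_perm=99, seed=0)
        # minimal attainable p is 1/(n_perm+1); a random permutation can
        # reproduce the true split by chance, so allow one collision
        assert table.p.iloc[0] <= 2 / 100
        assert bool(table.significant.iloc[0])

    def test_null_p_values_calibrated(self):
        rng = np.random.default_rng(17)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            x = rng.normal(size=(16, 2))
            labels = np.repeat(["a", "b"], 8)
            table = permutation_significance(x, labels, n_perm=99,
                                             seed=rng, alpha=0.05)
            if table.p.iloc[0] <= 0.05:
                hits += 1
        assert abs(hits / n_sim - 0.05) < 3 * np.sqrt(
            0.05 * 0.95 / n_sim) + 0.01

    def test_requires_enough_permutations(self, rng):
        x = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="99"):
            permutation_significance(x, ["a"] * 5 + ["b"] * 5, n_perm=10)


class TestGeographic:
    def test_same_point_zero(self):
        dm = geographic_matrix(["a", "b"], [10.0, 10.0], [20.0, 20.0])
        assert dm.values[0, 1] == 0.0

    def test_one_degree_longitude_on_equator(self):
        assert haversine_km(0, 0, 0, 1) == pytest.approx(111.195, abs=2e-3)

    def test_antipodal_half_circumference(self):
        assert haversine_km(0, 0, 0, 180) == pytest.approx(
            np.pi * 6371.0088, rel=1e-9)

    def test_group_centroids_averaged(self):
        dm = geographic_matrix(["a", "a", "b"], [0.0, 0.0, 0.0],
                               [0.0, 2.0, 5.0])
        assert dm.values[0, 1] == pytest.approx(haversine_km(0, 1, 0, 5),
                                                rel=1e-9)

    def test_missing_coordinates_listed(self):
        with pytest.raises(ValueError, match="b"):
            geographic_matrix(["a", "b"], [0.0, np.nan], [0.0, 1.0])


class TestDistanceMatrix:
    def test_asymmetry_rejected(self):
        v = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b"), v)

    def test_nonzero_diagonal_rejected(self):
        v = np.array([[1.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(("a", "b"), v)

    def test_negative_rejected(self):
        v = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError, match="nonnegative"):
            DistanceMatrix(("a", "b"), v)


def random_distance_matrix(rng, m, labels=None):
    pts = rng.normal(size=(m, 3))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(labels or (f"L{i}" for i in range(m))), d)


class TestMantel:
    def test_proportional_matrices_perfect_r(self, rng):
        m1 = random_distance_matrix(rng, 8)
        m2 = DistanceMatrix(m1.labels, 2.0 * m1.values)
        r, p = mantel_test(m1, m2, n_perm=99, seed=1)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(1 / 100)

    def test_label_mismatch_rejected(self, rng):
        m1 = random_distance_matrix(rng, 5)
        m2 = random_distance_matrix(rng, 5, labels=list("vwxyz"))
        with pytest.raises(ValueError, match="mismatch"):
            mantel_test(m1, m2, n_perm=99)

    def test_invariant_to_consistent_relabeling(self, rng):
        m1 = random_distance_matrix(rng, 7)
        m2 = random_distance_matrix(rng, 7, labels=m1.labels)
        r1, _ = mantel_test(m1, m2, n_perm=99, seed=0)
        perm = rng.permutation(7)
        m1p = DistanceMatrix(tuple(m1.labels[i] for i in perm),
                             m1.values[np.ix_(perm, perm)])
        m2p = DistanceMatrix(m1p.labels, m2.values[np.ix_(perm, perm)])
        r2, _ = mantel_test(m1p, m2p, n_perm=99, seed=0)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_agrees_with_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkbioDm
        from skbio.stats.distance import mantel as skbio_mantel
        m1 = random_distance_matrix(rng, 9)
        m2 = random_distance_matrix(rng, 9, labels=m1.labels)
        r, _ = mantel_test(m1, m2, n_perm=99, seed=0)
        r_ref, _, _ = skbio_mantel(SkbioDm(m1.values), SkbioDm(m2.values),
                                   permutations=0)
        assert r == pytest.approx(r_ref, abs=1e-10)

    def test_zero_variance_rejected(self):
        flat = DistanceMatrix(("a", "b", "c"),
                              np.ones((3, 3)) - np.eye(3))
        other = random_distance_matrix(np.random.default_rng(0), 3,
                                       labels=flat.labels)
        with pytest.raises(ValueError, match="variance"):
            mantel_test(flat, other, n_perm=99)


def random_additive_tree(rng, m):
    """Random unrooted binary tree with positive lengths and its exact
    leaf path-length matrix."""
    labels = [f"t{i}" for i in range(m)]
    # grow by random edge subdivision on an explicit edge list
    nodes = {0: None, 1: None}
    edges = {(0, 1): rng.uniform(0.5, 2.0)}
    leaf_of = {0: labels[0], 1: labels[1]}
    next_node = 2
    for leaf in labels[2:]:
        edge = list(edges)[rng.integers(len(edges))]
        length = edges.pop(edge)
        mid, tip = next_node, next_node + 1
        next_node += 2
        cut = rng.uniform(0.2, 0.8) * length
        edges[(edge[0], mid)] = cut
        edges[(mid, edge[1])] = length - cut
        edges[(mid, tip)] = rng.uniform(0.5, 2.0)
        leaf_of[tip] = leaf
    import networkx as nx
    g = nx.Graph()
    for (a, b), w in edges.items():
        g.add_edge(a, b, weight=w)
    leaf_ids = sorted(leaf_of, key=lambda i: leaf_of[i])
    dist = dict(nx.all_pairs_dijkstra_path_length(g))
    vals = np.array([[0.0 if i == j else dist[i][j] for j in leaf_ids]
                     for i in leaf_ids])
    vals = (vals + vals.T) / 2.0     # exact symmetry despite float noise
    return DistanceMatrix(tuple(leaf_of[i] for i in leaf_ids), vals)


class TestNeighborJoining:
    def test_four_leaf_additive_exact(self):
        d = np.array([[0, 5, 9, 9],
                      [5, 0, 10, 10],
                      [9, 10, 0, 8],
                      [9, 10, 8, 0]], float)
        dm = DistanceMatrix(("A", "B", "C", "D"), d)
        tree = neighbor_joining(dm)
        np.testing.assert_allclose(tree.path_length_matrix().values, d,
                                   atol=1e-12)

    def test_three_leaves_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C"), d))
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_random_additive_trees_recovered(self, rng):
        for _ in range(30):
            m = int(rng.integers(4, 11))
            dm = random_additive_tree(rng, m)
            tree = neighbor_joining(dm)
            recovered = tree.path_length_matrix()
            assert recovered.labels == tuple(sorted(dm.labels))
            order = [dm.labels.index(l) for l in recovered.labels]
            np.testing.assert_allclose(
                recovered.values, dm.values[np.ix_(order, order)],
                atol=1e-9)

    def test_matches_skbio_topology(self, rng):
        from skbio import DistanceMatrix as SkbioDm
        from skbio.tree import nj
        dm = random_additive_tree(rng, 7)
        mine = neighbor_joining(dm)
        ref = nj(SkbioDm(dm.values, ids=list(dm.labels)))
        ref_dm = ref.tip_tip_distances(list(sorted(dm.labels)))
        np.testing.assert_allclose(mine.path_length_matrix().values,
                                   ref_dm.data, atol=1e-9)

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError, match="3"):
            neighbor_joining(DistanceMatrix(
                ("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_negative_branch_warned_not_clamped(self):
        # non-additive matrix known to force a negative fitted length
        d = np.array([[0.0, 0.345, 0.301, 0.136],
                      [0.345, 0.0, 0.211, 0.482],
                      [0.301, 0.211, 0.0, 0.441],
                      [0.136, 0.482, 0.441, 0.0]])
        dm = DistanceMatrix(("a", "b", "c", "d"), d)
        with pytest.warns(RuntimeWarning):
            tree = neighbor_joining(dm)
        lengths = [n.length for n in _all_nodes(tree.root)
                   if n.length is not None]
        assert min(lengths) < 0


def _all_nodes(node):
    yield node
    for c in node.children:
        yield from _all_nodes(c)


class TestNewick:
    def test_three_leaf_star_format(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C"), d))
        text = write_newick(tree)
        assert text.startswith("(") and text.endswith(";")
        assert "A:1" in text and "B:2" in text and "C:3" in text

    def test_round_trip_through_dendropy(self, rng):
        import dendropy
        for _ in range(5):
            dm = random_additive_tree(rng, 8)
            tree = neighbor_joining(dm)
            text = write_newick(tree)
            parsed = dendropy.Tree.get(data=text, schema="newick")
            pdm = parsed.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in parsed.taxon_namespace}
            labels = sorted(dm.labels)
            for i, a in enumerate(labels):
                for j in range(i + 1, len(labels)):
                    b = labels[j]
                    expected = dm.values[dm.labels.index(a),
                                         dm.labels.index(b)]
                    got = pdm.patristic_distance(taxa[a], taxa[b])
                    assert got == pytest.approx(expected, abs=1e-5)
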