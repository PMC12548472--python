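"""Gower distance, patristic distances, complete linkage and silhouettes,
each checked against an independent oracle (per-pair loops, graph shortest
paths, scipy linkage, sklearn silhouette)."""

import itertools

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from phagepanel import (
    DistanceMatrix,
    FeatureSpec,
    Partition,
    PhenotypeTable,
    cut_k,
    gower_matrix,
    hclust_complete,
    patristic_distances,
    select_k,
    silhouette_avg,
)

from conftest import random_distance_matrix, random_phenotype_table


def gower_oracle(table, weights=None):
    """Per-pair, per-feature literal evaluation of the Gower formula."""
    ids = table.phage_ids
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = den = 0.0
            for f in table.features:
                w = weights.get(f.name, f.weight) if weights else f.weight
                xi = table.values.at[ids[i], f.name]
                xj = table.values.at[ids[j], f.name]
                if np.isnan(xi) or np.isnan(xj):
                    continue
                if f.kind == "binary":
                    delta = float(xi != xj)
                else:
                    col = table.values[f.name].dropna()
                    rng_ = col.max() - col.min()
                    delta = abs(xi - xj) / rng_ if rng_ > 0 else 0.0
                num += w * delta
                den += w
            out[i, j] = num / den
    return out


class TestGower:
    def test_identical_rows_have_zero_distance(self):
        df = pd.DataFrame({"b": [1.0, 1.0], "q": [3.0, 3.0]}, index=["x", "y"])
        t = PhenotypeTable(["x", "y"], [FeatureSpec("b", "binary"),
                                        FeatureSpec("q", "quantitative")], df)
        assert gower_matrix(t).values[0, 1] == 0.0

    def test_hand_computed_mixed_example(self):
        # mismatch (1) + match (0) + |diff|/range = 5/10 over 3 features
        df = pd.DataFrame(
            {"b1": [1.0, 0.0], "b2": [1.0, 1.0], "q": [0.0, 5.0]},
            index=["x", "y"],
        )
        # third item stretches the quantitative range to 10
        df.loc["z"] = [0.0, 1.0, 10.0]
        t = PhenotypeTable(
            ["x", "y", "z"],
            [FeatureSpec("b1", "binary"), FeatureSpec("b2", "binary"),
             FeatureSpec("q", "quantitative")],
            df,
        )
        d = gower_matrix(t)
        assert d.values[0, 1] == pytest.approx((1 + 0 + 0.5) / 3)

    def test_matches_per_pair_oracle(self, rng):
        for _ in range(10):
            t = random_phenotype_table(rng, 6, n_binary=3, n_quant=2,
                                       p_missing=0.15)
            d = gower_matrix(t)
            assert np.allclose(d.values, gower_oracle(t), atol=1e-12)

    def test_weights_respected(self, rng):
        t = random_phenotype_table(rng, 5)
        w = {f.name: float(rng.uniform(0.1, 3)) for f in t.features}
        assert np.allclose(gower_matrix(t, w).values, gower_oracle(t, w),
                           atol=1e-12)

    def test_bounded_in_unit_interval_and_permutation_equivariant(self, rng):
        t = random_phenotype_table(rng, 7, p_missing=0.1)
        d = gower_matrix(t)
        assert (d.values >= 0).all() and (d.values <= 1 + 1e-12).all()
        perm = rng.permutation(len(t.phage_ids))
        ids = [t.phage_ids[i] for i in perm]
        t2 = PhenotypeTable(ids, t.features, t.values.loc[ids])
        d2 = gower_matrix(t2)
        assert np.allclose(d2.values, d.values[np.ix_(perm, perm)], atol=1e-12)

    def test_disjoint_features_error_names_pair(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [np.nan, 2.0]},
                          index=["x", "y"])
        t = PhenotypeTable(["x", "y"], [FeatureSpec("a", "quantitative"),
                                        FeatureSpec("b", "quantitative")], df)
        with pytest.raises(ValueError, match="'x'.*'y'"):
            gower_matrix(t)

    def test_zero_range_feature_contributes_zero(self):
        df = pd.DataFrame({"q": [5.0, 5.0], "b": [0.0, 1.0]}, index=["x", "y"])
        t = PhenotypeTable(["x", "y"], [FeatureSpec("q", "quantitative"),
                                        FeatureSpec("b", "binary")], df)
        assert gower_matrix(t).values[0, 1] == pytest.approx(0.5)


def _tree_graph(tree):
    g = nx.Graph()
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            g.add_edge(id(node.parent_node), id(node), weight=node.edge.length)
    leaves = {leaf.taxon.label: id(leaf) for leaf in tree.leaf_node_iter()}
    return g, leaves


class TestPatristic:
    def test_three_leaf_tree(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")
        d = patristic_distances(tree)
        df = d.to_frame()
        assert df.at["A", "B"] == pytest.approx(2.0)
        assert df.at["A", "C"] == pytest.approx(4.0)
        assert df.at["B", "C"] == pytest.approx(4.0)

    def test_star_tree_equal_branches(self):
        tree = dendropy.Tree.get(data="(A:3,B:3,C:3,D:3);", schema="newick")
        d = patristic_distances(tree)
        off = d.values[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 6.0)

    def test_random_tree_matches_shortest_path_oracle(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        for seed in range(3):
            tree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=8,
                rng=__import__("random").Random(seed),
            )
            for i, leaf in enumerate(tree.leaf_node_iter()):
                leaf.taxon.label = taxa[i]
            d = patristic_distances(tree)
            g, leaves = _tree_graph(tree)
            sp = dict(nx.all_pairs_dijkstra_path_length(g))
            for a, b in itertools.combinations(taxa, 2):
                expected = sp[leaves[a]][leaves[b]]
                assert d.to_frame().at[a, b] == pytest.approx(expected, abs=1e-12)

    def test_four_point_condition_on_additive_trees(self, rng):
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=7,
            rng=__import__("random").Random(7),
        )
        d = patristic_distances(tree).to_frame()
        ids = list(d.index)
        for quad in itertools.combinations(ids, 4):
            i, j, k, l = quad
            sums = sorted([d.at[i, j] + d.at[k, l],
                           d.at[i, k] + d.at[j, l],
                           d.at[i, l] + d.at[j, k]])
            assert sums[2] - sums[1] < 1e-9  # two largest sums equal

    def test_negative_branch_length_rejected(self):
        tree = dendropy.Tree.get(data="((A:1,B:-1):1,C:2);", schema="newick")
        with pytest.raises(ValueError, match="negative"):
            patristic_distances(tree)


def linkage_oracle(d):
    """Brute-force complete linkage over frozensets of leaves."""
    n = len(d)
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            h = max(d.values[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        merges.append((a, b, h, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return merges


class TestCompleteLinkage:
    def test_two_separated_pairs_merge_first(self):
        vals = np.full((4, 4), 0.9)
        np.fill_diagonal(vals, 0.0)
        vals[0, 1] = vals[1, 0] = 0.1
        vals[2, 3] = vals[3, 2] = 0.1
        d = DistanceMatrix(list("abcd"), vals)
        dendro = hclust_complete(d)
        assert {(dendro.merges[0][0], dendro.merges[0][1]),
                (dendro.merges[1][0], dendro.merges[1][1])} == {(0, 1), (2, 3)}
        assert dendro.merges[0][2] == pytest.approx(0.1)

    def test_hand_sized_instance_matches_bruteforce_oracle(self, rng):
        for _ in range(15):
            d = random_distance_matrix(rng, 4)
            assert hclust_complete(d).merges == linkage_oracle(d)

    def test_matches_scipy_heights_on_random_matrices(self, rng):
        # heights (and cluster contents at each cut) agree with scipy's
        # complete linkage; random continuous distances make ties a.s. absent
        for _ in range(5):
            d = random_distance_matrix(rng, 9)
            ours = hclust_complete(d)
            Z = linkage(squareform(d.values), method="complete")
            assert np.allclose([m[2] for m in ours.merges], Z[:, 2], atol=1e-12)
            for k in range(2, 9):
                part = cut_k(ours, k)
                from scipy.cluster.hierarchy import fcluster

                sp = fcluster(Z, t=k, criterion="maxclust")
                groups_ours = {frozenset(np.flatnonzero(
                    np.array(part.labels) == lab)) for lab in set(part.labels)}
                groups_scipy = {frozenset(np.flatnonzero(sp == lab))
                                for lab in set(sp)}
                assert groups_ours == groups_scipy

    def test_heights_nondecreasing(self, rng):
        for _ in range(10):
            d = random_distance_matrix(rng, 8)
            heights = [m[2] for m in hclust_complete(d).merges]
            assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestCutK:
    def test_extreme_cuts(self, rng):
        d = random_distance_matrix(rng, 6)
        dendro = hclust_complete(d)
        assert cut_k(dendro, 6).n_groups == 6
        assert cut_k(dendro, 1).n_groups == 1
        with pytest.raises(ValueError):
            cut_k(dendro, 0)
        with pytest.raises(ValueError):
            cut_k(dendro, 7)

    def test_two_blob_recovery_and_nesting(self, rng):
        centers = np.array([0.0, 5.0])
        pts = np.concatenate([centers[0] + rng.normal(0, 0.1, 5),
                              centers[1] + rng.normal(0, 0.1, 5)])
        vals = np.abs(pts[:, None] - pts[None, :])
        d = DistanceMatrix([f"i{k}" for k in range(10)], vals)
        dendro = hclust_complete(d)
        p2 = cut_k(dendro, 2)
        assert sorted(map(len, p2.groups().values())) == [5, 5]
        # partitions nest as k decreases
        prev = cut_k(dendro, 10)
        for k in range(9, 0, -1):
            cur = cut_k(dendro, k)
            cur_groups = [set(g) for g in cur.groups().values()]
            for g in prev.groups().values():
                assert any(set(g) <= cg for cg in cur_groups)
            prev = cur


class TestSilhouette:
    def test_perfect_separation_scores_one(self):
        vals = np.array([[0, 0, 1, 1], [0, 0, 1, 1],
                         [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float)
        d = DistanceMatrix(list("abcd"), vals)
        p = Partition(list("abcd"), ["x", "x", "y", "y"])
        assert silhouette_avg(d, p) == pytest.approx(1.0)

    def test_two_singletons_score_zero(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        p = Partition(["a", "b"], ["x", "y"])
        assert silhouette_avg(d, p) == 0.0

    def test_matches_sklearn_on_random_instances(self, rng):
        for _ in range(15):
            n = int(rng.integers(5, 12))
            d = random_distance_matrix(rng, n)
            labels = rng.integers(0, 3, size=n)
            if len(set(labels.tolist())) < 2:
                continue
            p = Partition(d.item_ids, [str(x) for x in labels])
            expected = silhouette_score(d.values, labels, metric="precomputed")
            assert silhouette_avg(d, p) == pytest.approx(expected, abs=1e-12)

    def test_single_cluster_rejected(self, rng):
        d = random_distance_matrix(rng, 4)
        with pytest.raises(ValueError):
            silhouette_avg(d, Partition(d.item_ids, ["x"] * 4))


class TestSelectK:
    def test_two_perfect_blobs_select_two(self, rng):
        pts = np.concatenate([rng.normal(0, 0.05, 6), rng.normal(9, 0.05, 6)])
        vals = np.abs(pts[:, None] - pts[None, :])
        d = DistanceMatrix([f"i{k}" for k in range(12)], vals)
        assert select_k(d).chosen_k == 2

    def test_zero_noise_planted_groups_recover_k(self, rng):
        # 4 groups with zero within-group variance: silhouette peaks at k=4
        from phagepanel import SyntheticConfig, gower_matrix, simulate_dataset

        bundle = simulate_dataset(SyntheticConfig(
            n_phages=13, n_types=4, noise_sd=0.0, epsilon=0.0,
            p_spurious_drop=0.0, sigma=0.0, seed=5))
        sweep = select_k(gower_matrix(bundle.phenotypes))
        assert sweep.chosen_k == 4

    def test_sweep_scores_equal_per_k_recomputation(self, rng):
        d = random_distance_matrix(rng, 9)
        sweep = select_k(d, 2, 8)
        dendro = hclust_complete(d)
        for k, s in zip(sweep.ks, sweep.scores):
            assert s == pytest.approx(silhouette_avg(d, cut_k(dendro, k)),
                                      abs=1e-12)
        best = max(sweep.scores)
        assert sweep.chosen_k == min(
            k for k, s in zip(sweep.ks, sweep.scores) if s == best)

    def test_invalid_range_rejected(self, rng):
        d = random_distance_matrix(rng, 5)
        with pytest.raises(ValueError):
            select_k(d, 2, 5)  # k_max must stay below n
        with pytest.raises(ValueError):
            select_k(d, 3, 2)
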