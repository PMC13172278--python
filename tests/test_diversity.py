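"""TD/PD/FD maps, trait imputation, Gower distances, UPGMA clustering."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from conftest import make_atlas, make_tree
from refugia.diversity import (
    faith_pd_map,
    fdend_map,
    gower_matrix,
    impute_traits,
    richness_map,
    upgma_dendrogram,
)
from refugia.grids import GridSpec
from refugia.synthetic import TraitMatrix, generate_phylogeny, generate_traits
from refugia.trees import branch_sums, edge_matrix, tip_depths, total_length


def pd_oracle(tree: dendropy.Tree, present: set[str]) -> float:
    """Edge-marking oracle: walk root-ward from every present tip, marking
    edges; PD is the sum of marked edge lengths."""
    marked = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label in present:
            node = leaf
            while node.parent_node is not None:
                marked.add(node)
                node = node.parent_node
    return sum(float(n.edge.length or 0.0) for n in marked)


def random_tree(n_tips: int, seed: int) -> dendropy.Tree:
    return generate_phylogeny(n_tips, seed=seed)


class TestRichness:
    def test_identical_and_disjoint_ranges(self, grid10):
        p = np.zeros(grid10.shape, bool)
        p[:3, :3] = True
        q = np.zeros(grid10.shape, bool)
        q[7:, 7:] = True
        same = make_atlas(grid10, {"a": p, "b": p.copy()})
        assert richness_map(same, "current").values.max() == 2
        disjoint = make_atlas(grid10, {"a": p, "b": q})
        assert richness_map(disjoint, "current").values.max() == 1

    def test_matches_brute_force_stacking(self, grid10):
        rng = np.random.default_rng(0)
        pres = {f"s{i}": rng.random(grid10.shape) < 0.3 for i in range(10)}
        atlas = make_atlas(grid10, pres)
        sr = richness_map(atlas, "current").values
        expected = sum(v.astype(int) for v in pres.values())
        np.testing.assert_array_equal(sr, expected)


class TestFaithPD:
    def test_full_assemblage_scores_total_tree_length(self, grid10):
        tree = random_tree(6, seed=1)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        full = np.ones(grid10.shape, bool)
        atlas = make_atlas(grid10, {t: full.copy() for t in tips})
        pd_map = faith_pd_map(atlas, tree, "current")
        np.testing.assert_allclose(pd_map.values[grid10.analysis_mask], total_length(tree))

    def test_single_species_cell_scores_root_to_tip_path(self, grid10):
        tree = random_tree(5, seed=2)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        p = np.zeros(grid10.shape, bool)
        p[4, 4] = True
        atlas = make_atlas(grid10, {tips[0]: p, **{t: np.zeros(grid10.shape, bool) for t in tips[1:]}})
        pd_map = faith_pd_map(atlas, tree, "current")
        assert pd_map.values[4, 4] == pytest.approx(tip_depths(tree)[tips[0]])
        assert pd_map.values[4, 4] > 0

    @pytest.mark.parametrize("seed", range(10))
    def test_all_subsets_match_edge_marking_oracle(self, seed):
        tree = random_tree(5, seed=seed)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        lengths, inc = edge_matrix(tree, tips)
        subsets = list(itertools.chain.from_iterable(
            itertools.combinations(tips, k) for k in range(len(tips) + 1)
        ))
        presence = np.array([[t in s for s in subsets] for t in tips])
        got = branch_sums(lengths, inc, presence)
        expected = [pd_oracle(tree, set(s)) for s in subsets]
        np.testing.assert_allclose(got, expected)

    def test_species_missing_from_tree_excluded_with_warning(self, grid10):
        tree = make_tree("((a:1,b:1):1,c:2):0;")
        p = np.ones(grid10.shape, bool)
        atlas = make_atlas(grid10, {"a": p, "b": p.copy(), "ghost": p.copy()})
        with pytest.warns(UserWarning, match="ghost"):
            pd_map = faith_pd_map(atlas, tree, "current")
        assert pd_map.values.max() == pytest.approx(3.0)  # a + b subtree only

    def test_monotone_in_species_addition(self, grid10):
        tree = random_tree(6, seed=3)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        p = np.zeros(grid10.shape, bool)
        p[0, 0] = True
        empty = np.zeros(grid10.shape, bool)
        values = []
        for k in range(1, len(tips) + 1):
            pres = {t: (p.copy() if i < k else empty.copy()) for i, t in enumerate(tips)}
            atlas = make_atlas(grid10, pres)
            values.append(faith_pd_map(atlas, tree, "current").values[0, 0])
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestImputation:
    def test_equal_distance_neighbors_average(self):
        tree = make_tree("((a:1,b:1):1,(c:1,d:1):1):0;")
        data = pd.DataFrame(
            {"t": [np.nan, 2.0, 4.0, np.nan]}, index=["a", "b", "c", "d"]
        )
        # a's neighbors: b at distance 2, c and d at 4. With k=1 only b counts.
        tm = TraitMatrix(data, {"t": "continuous"})
        out = impute_traits(tm, tree, k=1)
        assert out.data.loc["a", "t"] == pytest.approx(2.0)
        assert out.imputed.loc["a", "t"]

    def test_two_equidistant_donors_average_evenly(self):
        tree = make_tree("((a:1,b:1):1,(c:1,d:1):1):0;")
        data = pd.DataFrame({"t": [np.nan, np.nan, 2.0, 4.0]}, index=["a", "b", "c", "d"])
        data.loc["b", "t"] = np.nan
        # a is equidistant (4) from both donors c and d -> mean of 2 and 4
        tm = TraitMatrix(data, {"t": "continuous"})
        out = impute_traits(tm, tree, k=5)
        assert out.data.loc["a", "t"] == pytest.approx(3.0)

    def test_complete_matrix_is_identity(self):
        tree = random_tree(6, seed=4)
        tm = generate_traits(tree, 2, 1, missing_fraction=0.0, seed=5)
        out = impute_traits(tm, tree, k=3)
        pd.testing.assert_frame_equal(out.data, tm.data)
        assert not out.imputed.any().any()

    def test_categorical_plurality_and_tie_break(self):
        tree = make_tree("(((a:1,b:1):1,c:2):1,(d:1.5,e:1.5):1.5):0;")
        data = pd.DataFrame(
            {"t": [np.nan, "x", "x", "y", "y"]}, index=["a", "b", "c", "d", "e"]
        )
        out = impute_traits(TraitMatrix(data, {"t": "categorical"}), tree, k=4)
        assert out.data.loc["a", "t"] == "x"  # plurality broken toward nearest

    def test_beats_grand_mean_imputation(self):
        """Phylogenetic neighbors recover Brownian traits better than the
        grand mean, on average over replicates."""
        wins = 0
        reps = 40
        for rep in range(reps):
            tree = random_tree(30, seed=100 + rep)
            tm = generate_traits(tree, 1, 0, signal=1.0, missing_fraction=0.0, seed=200 + rep)
            truth = tm.data["cont1"].copy()
            rng = np.random.default_rng(300 + rep)
            mask_idx = rng.choice(30, size=6, replace=False)
            data = tm.data.copy()
            data.iloc[mask_idx, 0] = np.nan
            out = impute_traits(TraitMatrix(data, dict(tm.kinds)), tree, k=5)
            est = out.data["cont1"].iloc[mask_idx].astype(float)
            true_vals = truth.iloc[mask_idx]
            rmse_phylo = np.sqrt(((est - true_vals) ** 2).mean())
            rmse_mean = np.sqrt(((data["cont1"].mean() - true_vals) ** 2).mean())
            wins += rmse_phylo < rmse_mean
        assert wins / reps > 0.6


class TestGower:
    def test_identical_rows_and_full_mismatch(self):
        data = pd.DataFrame({"c": [1.0, 1.0], "k": ["x", "x"]}, index=["a", "b"])
        d = gower_matrix(TraitMatrix(data, {"c": "continuous", "k": "categorical"}))
        assert d.loc["a", "b"] == 0.0
        data2 = pd.DataFrame({"k": ["x", "y"]}, index=["a", "b"])
        d2 = gower_matrix(TraitMatrix(data2, {"k": "categorical"}))
        assert d2.loc["a", "b"] == 1.0

    def test_hand_computed_mixed_example(self):
        # continuous 1 vs 3 on observed range [1, 5] -> 0.5; matching category -> 0
        data = pd.DataFrame(
            {"c": [1.0, 3.0, 5.0], "k": ["x", "x", "y"]}, index=["a", "b", "z"]
        )
        d = gower_matrix(TraitMatrix(data, {"c": "continuous", "k": "categorical"}))
        assert d.loc["a", "b"] == pytest.approx((0.5 + 0.0) / 2)

    def test_pairwise_deletion_weights(self):
        # trait2 unobserved for b: d(a,b) uses only trait1
        data = pd.DataFrame(
            {"c1": [0.0, 1.0, 0.5], "c2": [0.0, np.nan, 1.0]}, index=["a", "b", "z"]
        )
        d = gower_matrix(TraitMatrix(data, {"c1": "continuous", "c2": "continuous"}))
        assert d.loc["a", "b"] == pytest.approx(1.0)  # |0-1|/range(=1) over 1 trait
        assert d.loc["a", "z"] == pytest.approx((0.5 + 1.0) / 2)

    def test_no_comparable_traits_raises(self):
        data = pd.DataFrame(
            {"c1": [0.0, np.nan], "c2": [np.nan, 1.0]}, index=["a", "b"]
        )
        with pytest.raises(ValueError, match="a.*b"):
            gower_matrix(TraitMatrix(data, {"c1": "continuous", "c2": "continuous"}))

    def test_matrix_properties(self):
        tree = random_tree(10, seed=6)
        tm = generate_traits(tree, 3, 2, missing_fraction=0.0, seed=7)
        d = gower_matrix(tm).to_numpy()
        assert (d >= 0).all() and (d <= 1).all()
        np.testing.assert_allclose(d, d.T)
        assert np.diag(d).sum() == 0


def upgma_oracle(dist: pd.DataFrame):
    """Brute-force UPGMA recomputing every cluster mean from the raw matrix."""
    clusters = [(s,) for s in dist.index]
    heights = {c: 0.0 for c in clusters}
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                d = np.mean([[dist.loc[x, y] for y in b] for x in a])
                la, lb = min(a), min(b)
                key = (d, min(la, lb), max(la, lb))
                if best is None or key < best[0:3]:
                    best = (*key, a, b)
        d, _, _, a, b = best
        clusters.remove(a)
        clusters.remove(b)
        merged = tuple(sorted(a + b))
        clusters.append(merged)
        heights[merged] = d / 2
        merges.append((merged, d / 2))
    return merges


class TestUpgma:
    def test_three_taxon_worked_example(self):
        dist = pd.DataFrame(
            [[0, 2, 6], [2, 0, 6], [6, 6, 0]], index=list("ABC"), columns=list("ABC"), dtype=float
        )
        tree = upgma_dendrogram(dist)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(1.0)
        assert lengths["C"] == pytest.approx(3.0)
        assert total_length(tree) == pytest.approx(7.0)

    def test_equal_distances_tie_break_deterministic(self):
        dist = pd.DataFrame(np.ones((4, 4)) - np.eye(4), index=list("abcd"), columns=list("abcd"))
        t1 = upgma_dendrogram(dist).as_string(schema="newick")
        t2 = upgma_dendrogram(dist).as_string(schema="newick")
        assert t1 == t2
        depths = tip_depths(upgma_dendrogram(dist))
        np.testing.assert_allclose(list(depths.values()), 0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_matrices_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        labels = [f"t{i}" for i in range(n)]
        dist = pd.DataFrame(m, index=labels, columns=labels)
        tree = upgma_dendrogram(dist)
        got_heights = sorted(
            tip_depths_at(tree, node) for node in tree.preorder_internal_node_iter()
        )
        expected = sorted(h for _, h in upgma_oracle(dist))
        np.testing.assert_allclose(got_heights, expected)

    def test_nonsymmetric_matrix_rejected(self):
        dist = pd.DataFrame([[0, 1], [2, 0]], index=["a", "b"], columns=["a", "b"], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            upgma_dendrogram(dist)

    def test_matches_scipy_average_linkage_heights(self):
        """Independent cross-check on a tie-free matrix."""
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(42)
        pts = rng.random((7, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(7)]
        dist = pd.DataFrame(d, index=labels, columns=labels)
        tree = upgma_dendrogram(dist)
        ours = sorted(tip_depths_at(tree, n) * 2 for n in tree.preorder_internal_node_iter())
        scipy_heights = sorted(linkage(squareform(d), method="average")[:, 2])
        np.testing.assert_allclose(ours, scipy_heights, rtol=1e-9)


def tip_depths_at(tree, node) -> float:
    """Height of an internal node = distance to any descendant tip (tree is
    ultrametric)."""
    h = 0.0
    n = node
    while not n.is_leaf():
        n = n.child_nodes()[0]
        h += float(n.edge.length or 0.0)
    return h


class TestFdend:
    def test_fd_equals_pd_routine_on_dendrogram(self, grid10):
        dist = pd.DataFrame(
            [[0, 2, 6], [2, 0, 6], [6, 6, 0]], index=list("ABC"), columns=list("ABC"), dtype=float
        )
        dendro = upgma_dendrogram(dist)
        p = np.zeros(grid10.shape, bool)
        p[1, 1] = True
        empty = np.zeros(grid10.shape, bool)
        atlas = make_atlas(grid10, {"A": p, "B": p.copy(), "C": empty})
        fd = fdend_map(atlas, dendro, "current")
        # {A, B} under the worked dendrogram: 1 + 1 + 2 (root-inclusive)
        assert fd.values[1, 1] == pytest.approx(4.0)
        pd_alias = faith_pd_map(atlas, dendro, "current")
        np.testing.assert_allclose(fd.values, pd_alias.values)

    def test_full_assemblage_is_total_dendrogram_length(self, grid10):
        tree = random_tree(8, seed=8)
        tm = generate_traits(tree, 3, 1, missing_fraction=0.0, seed=9)
        dendro = upgma_dendrogram(gower_matrix(tm))
        tips = [l.taxon.label for l in dendro.leaf_node_iter()]
        full = np.ones(grid10.shape, bool)
        atlas = make_atlas(grid10, {t: full.copy() for t in tips})
        fd = fdend_map(atlas, dendro, "current")
        np.testing.assert_allclose(fd.values[grid10.analysis_mask], total_length(dendro))


def test_pd_fd_coupling_under_strong_signal(grid10):
    """With near-noiseless Brownian traits, cellwise PD and FD agree better
    than after permuting trait rows across species (ordering check only)."""
    from refugia.gap_refugia import kendall_tau

    tree = random_tree(12, seed=10)
    tips = [l.taxon.label for l in tree.leaf_node_iter()]
    tm = generate_traits(tree, 5, 0, signal=1.0, missing_fraction=0.0, seed=11)
    rng = np.random.default_rng(12)
    pres = {t: rng.random(grid10.shape) < 0.35 for t in tips}
    atlas = make_atlas(grid10, pres)
    pd_map = faith_pd_map(atlas, tree, "current")

    dendro = upgma_dendrogram(gower_matrix(tm))
    fd_map = fdend_map(atlas, dendro, "current")

    permuted = tm.data.copy()
    permuted.index = list(rng.permutation(permuted.index))
    dendro_perm = upgma_dendrogram(gower_matrix(TraitMatrix(permuted.sort_index(), dict(tm.kinds))))
    fd_perm = fdend_map(atlas, dendro_perm, "current")

    mask = grid10.analysis_mask
    tau_real = kendall_tau(pd_map.values, fd_map.values, mask)
    tau_perm = kendall_tau(pd_map.values, fd_perm.values, mask)
    assert tau_real > tau_perm
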