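"""Yule simulator, community generators, and full synthetic studies."""

import numpy as np
import pytest

from ethnophylo import (
    SimConfig,
    generate_study,
    mpd,
    sample_community,
    ses_metric,
    simulate_yule_tree,
)
from ethnophylo.synthetic_data import assign_clades


class TestYule:
    def test_two_tips_is_a_cherry_with_equal_depths(self):
        tree = simulate_yule_tree(2, seed=0)
        assert tree.n_tips == 2
        leaves = list(tree.dendropy_tree.leaf_node_iter())
        depths = [leaf.edge.length for leaf in leaves]
        assert depths[0] == pytest.approx(depths[1])  # ultrametric cherry
        d = tree.distance_matrix()
        a, b = d.labels
        assert d.distance(a, b) == pytest.approx(2 * depths[0])

    @pytest.mark.parametrize("n", [2, 3, 7, 33, 100])
    def test_tip_count_exact_and_labels_unique(self, n):
        tree = simulate_yule_tree(n, seed=n)
        assert tree.n_tips == n
        assert len(set(tree.tip_labels)) == n

    @pytest.mark.parametrize("seed", range(10))
    def test_ultrametric(self, seed):
        tree = simulate_yule_tree(20, seed=seed)
        dtree = tree.dendropy_tree
        depths = []
        for leaf in dtree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length
                node = node.parent_node
            depths.append(d)
        assert np.allclose(depths, depths[0], rtol=1e-9)

    def test_deterministic_under_seed(self):
        a = simulate_yule_tree(15, seed=5).to_newick()
        b = simulate_yule_tree(15, seed=5).to_newick()
        c = simulate_yule_tree(15, seed=6).to_newick()
        assert a == b
        assert a != c

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_yule_tree(1, seed=0)
        with pytest.raises(ValueError):
            simulate_yule_tree(5, birth_rate=0.0, seed=0)

    def test_lineage_growth_matches_yule_expectation(self):
        """E[#lineages at time t] = exp(lambda * t) for the pure-birth
        process; checked within 3 standard errors over 500 replicates."""
        lam, t_check, reps = 1.0, 2.0, 500
        counts = []
        for seed in range(reps):
            tree = simulate_yule_tree(60, birth_rate=lam, seed=seed)
            dtree = tree.dendropy_tree
            root = dtree.seed_node
            # absolute times: the root's own edge spans [0, root split];
            # each other edge spans [end(parent), end(node)]
            end = {id(root): root.edge.length}
            n = 0
            for node in dtree.preorder_node_iter():
                if node is root:
                    birth = 0.0
                else:
                    birth = end[id(node.parent_node)]
                    end[id(node)] = birth + node.edge.length
                if birth <= t_check < end[id(node)]:
                    n += 1  # lineage alive at t_check
            counts.append(n)
        counts = np.array(counts, dtype=float)
        expected = np.exp(lam * t_check)
        se = counts.std(ddof=1) / np.sqrt(reps)
        assert abs(counts.mean() - expected) < 3 * se


class TestAssignClades:
    def test_partition_covers_all_tips(self):
        tree = simulate_yule_tree(50, seed=2)
        clades = assign_clades(tree, 5)
        assert set(clades.index) == set(tree.tip_labels)
        assert clades.nunique() == 5
        sizes = clades.value_counts()
        assert sizes["clade_1"] == sizes.max()


@pytest.fixture(scope="module")
def tree_dist():
    tree = simulate_yule_tree(64, seed=11)
    return tree, tree.distance_matrix()


class TestSampleCommunity:
    def test_basic_shape_and_membership(self, tree_dist):
        tree, dist = tree_dist
        for mode in ("null", "clustered", "overdispersed"):
            comm = sample_community(tree, 8, mode=mode, seed=1, dist=dist)
            assert comm.k == 8
            assert len(set(comm.members)) == 8
            assert set(comm.members) <= set(dist.labels)

    def test_invalid_k_and_mode(self, tree_dist):
        tree, dist = tree_dist
        with pytest.raises(ValueError):
            sample_community(tree, 1, seed=0, dist=dist)
        with pytest.raises(ValueError):
            sample_community(tree, 64, seed=0, dist=dist)
        with pytest.raises(ValueError):
            sample_community(tree, 8, mode="bogus", seed=0, dist=dist)

    def test_deterministic_under_seed(self, tree_dist):
        tree, dist = tree_dist
        for mode in ("null", "clustered", "overdispersed"):
            a = sample_community(tree, 8, mode=mode, seed=3, dist=dist)
            b = sample_community(tree, 8, mode=mode, seed=3, dist=dist)
            assert a.members == b.members

    def test_clustered_lowers_mpd_overdispersed_raises_it(self, tree_dist):
        """Mean observed MPD orders as clustered < null < overdispersed."""
        tree, dist = tree_dist
        means = {}
        for mode in ("null", "clustered", "overdispersed"):
            vals = [
                mpd(sample_community(tree, 8, mode=mode, strength=1.0,
                                     seed=s, dist=dist))
                for s in range(40)
            ]
            means[mode] = np.mean(vals)
        assert means["clustered"] < means["null"] < means["overdispersed"]

    def test_clustered_sign_of_ses(self, tree_dist):
        tree, dist = tree_dist
        ses = [
            ses_metric(
                sample_community(tree, 8, mode="clustered", strength=1.0,
                                 seed=s, dist=dist),
                "mpd", runs=199, seed=s,
            ).ses
            for s in range(30)
        ]
        assert np.mean(ses) > 0.5

    def test_overdispersed_sign_of_ses(self, tree_dist):
        tree, dist = tree_dist
        ses = [
            ses_metric(
                sample_community(tree, 8, mode="overdispersed", strength=1.0,
                                 seed=s, dist=dist),
                "mpd", runs=199, seed=s,
            ).ses
            for s in range(30)
        ]
        assert np.mean(ses) < -0.5

    def test_fallback_when_no_clade_large_enough(self, caplog):
        from ethnophylo import parse_newick

        tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        with caplog.at_level("WARNING", logger="ethnophylo.synthetic_data"):
            comm = sample_community(tree, 3, mode="clustered", seed=0)
        assert comm.k == 3
        assert "top-up" in caplog.text


class TestGenerateStudy:
    def test_shapes_match_config(self):
        cfg = SimConfig(n_tips=100, seed=1)
        tree, matrix, truth = generate_study(cfg)
        assert tree.n_tips == 100
        assert len(matrix.categories) == 15
        assert len(truth) == 15
        n_med = int(round(cfg.medicinal_fraction * 100))
        assert matrix.n_species == n_med
        assert matrix.families.notna().all()

    def test_no_all_zero_rows(self):
        cfg = SimConfig(n_tips=80, seed=4)
        _, matrix, _ = generate_study(cfg)
        assert (matrix.row_sums() >= 1).all()

    def test_deterministic_under_seed(self):
        a = generate_study(SimConfig(n_tips=80, seed=9))
        b = generate_study(SimConfig(n_tips=80, seed=9))
        assert a[0].to_newick() == b[0].to_newick()
        assert a[1].values.equals(b[1].values)
        assert a[2].equals(b[2])

    def test_truth_table_records_modes(self):
        modes = ("clustered", "overdispersed") + ("null",) * 13
        cfg = SimConfig(n_tips=100, seed=2, modes=modes)
        _, matrix, truth = generate_study(cfg)
        assert tuple(truth["mode"]) == modes
        # planted community sizes approximately match the prevalences
        n_med = matrix.n_species
        for _, r in truth.iterrows():
            assert r["k"] == int(round(
                cfg.prevalences[list(cfg.categories).index(r["category"])] * n_med
            ))

    def test_prevalence_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_tips=100, prevalences=(0.0,) + (0.5,) * 14)

    def test_infeasible_prevalence_rejected(self):
        with pytest.raises(ValueError, match="< 2"):
            generate_study(
                SimConfig(n_tips=20, medicinal_fraction=0.5,
                          prevalences=(0.05,) + (0.5,) * 14, seed=0)
            )
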