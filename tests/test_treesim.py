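"""Robinson-Foulds comparison and the leave-out placement simulation."""

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from ampliplace.io_formats import parse_newick, write_newick
from ampliplace.placement import extend, place_query
from ampliplace.synthetic import make_reference, sim_tree
from ampliplace.treesim import (
    SimConfig,
    bipartitions,
    induced_subtree,
    random_baseline,
    random_resolved_tree,
    rf_normalized,
    run_simulation,
)


def _dendropy_rf(t1, t2):
    """Independent normalised RF via dendropy's bipartition machinery."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=write_newick(t1), schema="newick", taxon_namespace=tns)
    b = dendropy.Tree.get(data=write_newick(t2), schema="newick", taxon_namespace=tns)
    for t in (a, b):
        t.is_rooted = False
        t.collapse_basal_bifurcation()
        t.encode_bipartitions()
    sym = treecompare.symmetric_difference(a, b)
    denom = sum(
        1 for t in (a, b) for e in t.preorder_internal_edge_iter(exclude_seed_edge=True)
    )
    return sym / denom if denom else 0.0


class TestBipartitions:
    def test_five_leaf_binary_tree_has_two_splits(self):
        tree = parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        splits = bipartitions(tree)
        assert len(splits) == 2  # n - 3 internal edges
        sides = {frozenset(s) for s in splits} | {
            frozenset({"A", "B", "C", "D", "E"} - s) for s in splits
        }
        assert frozenset({"A", "B"}) in sides and frozenset({"D", "E"}) in sides

    def test_star_tree_has_no_splits(self):
        tree = parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        assert bipartitions(tree) == set()

    def test_small_trees_have_no_splits(self):
        assert bipartitions(parse_newick("(A:1,(B:1,C:1):1);")) == set()

    def test_rooting_does_not_duplicate_the_root_split(self):
        rooted = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        unrooted = parse_newick("(A:1,B:1,(C:1,D:1):1);")
        assert bipartitions(rooted) == bipartitions(unrooted)


class TestRFNormalized:
    def test_self_distance_is_zero(self):
        tree = sim_tree(10, seed=4)
        assert rf_normalized(tree, tree) == 0.0

    def test_disjoint_quartets_give_one(self):
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        t2 = parse_newick("((A:1,C:1):1,(B:1,D:1):1,E:1);")
        assert rf_normalized(t1, t2) == 1.0

    def test_leaf_set_mismatch_reports_names(self):
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_newick("((A:1,B:1):1,(C:1,E:1):1);")
        with pytest.raises(ValueError, match="E"):
            rf_normalized(t1, t2)

    def test_agrees_with_dendropy_on_random_pairs(self):
        for seed in range(30):
            t1 = sim_tree(8, seed=100 + seed)
            t2 = sim_tree(8, seed=200 + seed)
            assert rf_normalized(t1, t2) == pytest.approx(_dendropy_rf(t1, t2))

    def test_pseudometric_properties(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            seeds = rng.integers(0, 10_000, size=3)
            ta, tb, tc = (sim_tree(9, seed=int(s)) for s in seeds)
            dab, dba = rf_normalized(ta, tb), rf_normalized(tb, ta)
            assert dab == dba
            assert rf_normalized(ta, ta) == 0.0
            assert rf_normalized(ta, tc) <= dab + rf_normalized(tb, tc) + 1e-12


class TestInducedSubtree:
    def test_full_leafset_is_isomorphic(self):
        tree = sim_tree(10, seed=5)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        sub = induced_subtree(tree, labels)
        assert rf_normalized(tree, sub) == 0.0

    def test_two_leaves_give_path_length(self):
        tree = parse_newick("((A:1,B:2):0.5,C:3);")
        sub = induced_subtree(tree, ["A", "C"])
        leaves = list(sub.leaf_node_iter())
        total = sum(l.edge.length or 0.0 for l in leaves)
        assert total == pytest.approx(1 + 0.5 + 3)

    def test_path_lengths_preserved_on_random_trees(self):
        rng = np.random.default_rng(11)
        tree = sim_tree(20, seed=8)
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        keep = sorted(rng.choice(labels, size=7, replace=False))
        sub = induced_subtree(tree, keep)
        pdm_t = tree.phylogenetic_distance_matrix()
        pdm_s = sub.phylogenetic_distance_matrix()
        tt = {t.label: t for t in tree.taxon_namespace}
        ts = {t.label: t for t in sub.taxon_namespace}
        for i, x in enumerate(keep):
            for y in keep[i + 1 :]:
                assert pdm_s.patristic_distance(ts[x], ts[y]) == pytest.approx(
                    pdm_t.patristic_distance(tt[x], tt[y]), abs=1e-9
                )

    def test_unknown_leaf_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            induced_subtree(sim_tree(6, seed=1), ["nope"])


@pytest.fixture(scope="module")
def sim_ref():
    return make_reference(40, 350, seed=21)


class TestRunSimulation:

    def test_deterministic_per_seed(self, sim_ref):
        cfg = SimConfig(n_reference=25, n_query=5, region_len=250, replicates=4, seed=9)
        v1 = run_simulation(sim_ref, cfg)
        v2 = run_simulation(sim_ref, cfg)
        assert np.array_equal(v1, v2)

    def test_placement_beats_random_baseline(self, sim_ref):
        cfg = SimConfig(n_reference=25, n_query=6, region_len=250, replicates=8, seed=2)
        placed = run_simulation(sim_ref, cfg)
        baseline = random_baseline(sim_ref, cfg)
        assert placed.mean() < baseline.mean()

    def test_self_placement_control_recovers_the_true_tree(self, sim_ref):
        """Queries whose full-length sources stay in the reference place back
        onto their own leaves, so the query tree matches the true subtree."""
        rng = np.random.default_rng(0)
        labels = sorted(sim_ref.msa)
        sources = sorted(rng.choice(labels, size=6, replace=False))
        queries = {f"{s}_q": sim_ref.ungapped(s)[40:290] for s in sources}
        placements = [place_query(q, seq, sim_ref, rng=rng) for q, seq in sorted(queries.items())]
        assert all(pl.target_leaf == pl.query_id[:-2] for pl in placements)
        ext, _ = extend(sim_ref, placements, queries, with_msa=False)
        placed = induced_subtree(ext, sorted(queries))
        truth = induced_subtree(sim_ref.tree, sources)
        for leaf in truth.leaf_node_iter():
            leaf.taxon.label = leaf.taxon.label + "_q"
        assert rf_normalized(placed, truth) == pytest.approx(0.0)

    def test_insufficient_leaves_raise(self, sim_ref):
        cfg = SimConfig(n_reference=38, n_query=5, region_len=250, replicates=1, seed=0)
        with pytest.raises(ValueError, match="leaves"):
            run_simulation(sim_ref, cfg)
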