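"""Reference loading, candidate search, placement, tree/MSA extension."""

import math

import dendropy
import numpy as np
import pytest

from ampliplace.io_formats import parse_newick
from ampliplace.placement import (
    Placement,
    ReferenceSet,
    extend,
    find_candidates,
    jc_distance,
    load_reference,
    place_query,
    prune_to_queries,
    trim_alignment,
)
from ampliplace.synthetic import make_reference


def _write_ref(tmp_path, msa, newick):
    msa_path = tmp_path / "ref.fasta"
    msa_path.write_text("".join(f">{n}\n{s}\n" for n, s in msa.items()))
    tree_path = tmp_path / "ref.nwk"
    tree_path.write_text(newick)
    return msa_path, tree_path


class TestLoadReference:
    def test_matching_names_load(self, tmp_path):
        paths = _write_ref(
            tmp_path,
            {"A": "ACGT", "B": "ACGA", "C": "ACTT", "D": "AGTT"},
            "((A:1,B:1):1,(C:1,D:1):1);",
        )
        ref = load_reference(*paths)
        assert set(ref.msa) == {"A", "B", "C", "D"}

    def test_name_mismatch_lists_offenders(self, tmp_path):
        paths = _write_ref(
            tmp_path, {"A": "ACGT", "B": "ACGA"}, "((A:1,X:1):1,B:0.5);"
        )
        with pytest.raises(ValueError, match="X"):
            load_reference(*paths)

    def test_all_gap_columns_removed(self, tmp_path):
        paths = _write_ref(
            tmp_path,
            {"A": "AC-GT", "B": "AC-GA", "C": "AC-TT", "D": "AG-TT"},
            "((A:1,B:1):1,(C:1,D:1):1);",
        )
        ref = load_reference(*paths)
        assert ref.n_columns == 4


class TestFindCandidates:
    def test_exact_window_scores_one(self, small_reference):
        leaf = sorted(small_reference.msa)[3]
        query = small_reference.ungapped(leaf)[120:370]
        cands = find_candidates(query, small_reference)
        assert len(cands) == 30
        assert cands[0][0] == leaf
        assert cands[0][1] == 1.0
        assert all(0 <= s <= 1 for _, s in cands)

    def test_duplicated_reference_region_ties(self):
        msa = {"X": "AAACGTACGTAC", "Y": "AAACGTACGTAC", "Z": "GGGGTTTTGGGG", "W": "CCCCTTTTCCCC"}
        tree = parse_newick("((X:1,Y:1):1,(Z:1,W:1):1);")
        ref = ReferenceSet(msa=msa, tree=tree)
        cands = find_candidates("ACGTACGT", ref)
        assert cands[0][1] == cands[1][1] == 1.0
        assert {cands[0][0], cands[1][0]} == {"X", "Y"}

    def test_prescreen_restricts_list_but_keeps_best(self, small_reference):
        leaf = sorted(small_reference.msa)[7]
        query = small_reference.ungapped(leaf)[100:350]
        full = find_candidates(query, small_reference)
        screened = find_candidates(query, small_reference, prescreen_top=5)
        assert len(screened) == 5
        assert screened[0] == full[0]


class TestPlaceQuery:
    def test_jc_pendant_values(self):
        assert jc_distance(0.0) == 0.0
        assert jc_distance(0.04) == pytest.approx(-0.75 * math.log(1 - 4 * 0.04 / 3))
        with pytest.warns(UserWarning, match="saturates"):
            assert jc_distance(0.8, maximum=3.0) == 3.0

    def test_identical_query_has_zero_pendant(self, small_reference):
        leaf = sorted(small_reference.msa)[0]
        query = small_reference.ungapped(leaf)[50:300]
        pl = place_query("q", query, small_reference)
        assert pl.target_leaf == leaf
        assert pl.pendant_length == 0.0
        assert not pl.chosen_by_tiebreak

    def test_tied_candidates_resolved_reproducibly(self):
        msa = {"X": "AAACGTACGTAC", "Y": "AAACGTACGTAC", "Z": "GGGGTTTTGGGG", "W": "CCCCTTTTCCCC"}
        ref = ReferenceSet(msa=msa, tree=parse_newick("((X:1,Y:1):1,(Z:1,W:1):1);"))
        choices = {place_query("q", "ACGTACGT", ref, rng=5).target_leaf for _ in range(5)}
        assert len(choices) == 1
        pl = place_query("q", "ACGTACGT", ref, rng=5)
        assert pl.chosen_by_tiebreak
        assert set(pl.candidates) == {"X", "Y"}

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            Placement("q", "X", 0.5, 0.1, candidates=["Y"])
        with pytest.raises(ValueError):
            Placement("q", "X", 1.5, 0.1, candidates=["X"])


class TestExtend:
    def test_sister_attachment_conserves_lengths(self, small_reference):
        leaf = sorted(small_reference.msa)[2]
        query = small_reference.ungapped(leaf)[50:300]
        pl = place_query("q1", query, small_reference)
        before = {l.taxon.label for l in small_reference.tree.leaf_node_iter()}
        ext, _ = extend(small_reference, [pl], {"q1": query}, with_msa=False)
        after = {l.taxon.label for l in ext.leaf_node_iter()}
        assert after == before | {"q1"}
        # the bisected branch keeps its total length
        node = next(l for l in ext.leaf_node_iter() if l.taxon.label == pl.target_leaf)
        orig = next(
            l for l in small_reference.tree.leaf_node_iter() if l.taxon.label == pl.target_leaf
        )
        assert node.edge.length + node.parent_node.edge.length == pytest.approx(
            orig.edge.length
        )

    def test_reference_path_lengths_unchanged(self, small_reference):
        leaves = sorted(small_reference.msa)[:4]
        queries = {f"q{i}": small_reference.ungapped(l)[60:310] for i, l in enumerate(leaves)}
        placements = [place_query(q, s, small_reference) for q, s in sorted(queries.items())]
        ext, _ = extend(small_reference, placements, queries, with_msa=False)
        pdm_b = small_reference.tree.phylogenetic_distance_matrix()
        pdm_a = ext.phylogenetic_distance_matrix()
        tb = {t.label: t for t in small_reference.tree.taxon_namespace}
        ta = {t.label: t for t in ext.taxon_namespace}
        labels = sorted(small_reference.msa)[:10]
        for i, x in enumerate(labels):
            for y in labels[i + 1 :]:
                assert pdm_a.patristic_distance(ta[x], ta[y]) == pytest.approx(
                    pdm_b.patristic_distance(tb[x], tb[y]), abs=1e-9
                )

    def test_insertion_creates_all_gap_reference_columns(self):
        msa = {"A": "ACGTACGTAA", "B": "ACGTACGTCC", "C": "TTGTACGTGG", "D": "TTGTATGTGG"}
        ref = ReferenceSet(msa=msa, tree=parse_newick("((A:1,B:1):1,(C:1,D:1):1);"))
        query = "ACGTTTACGT"  # two-base insertion relative to A's ACGT|ACGT
        pl = place_query("q1", query, ref)
        assert pl.target_leaf in {"A", "B"}
        ext, msa2 = extend(ref, [pl], {"q1": query})
        assert len(msa2["A"]) == 12
        ins_cols = [i for i in range(12) if all(msa2[n][i] == "-" for n in "ABCD")]
        assert len(ins_cols) == 2
        assert all(msa2["q1"][i] != "-" for i in ins_cols)
        assert msa2["q1"].replace("-", "") == query

    def test_no_placements_is_identity(self, small_reference):
        ext, msa = extend(small_reference, [], {})
        assert msa == small_reference.msa
        assert {l.taxon.label for l in ext.leaf_node_iter()} == set(small_reference.msa)


class TestPruneAndTrim:
    def test_single_query_prunes_to_pair(self, small_reference):
        leaf = sorted(small_reference.msa)[5]
        query = small_reference.ungapped(leaf)[50:300]
        pl = place_query("q1", query, small_reference)
        ext, _ = extend(small_reference, [pl], {"q1": query}, with_msa=False)
        pruned = prune_to_queries(ext, ["q1"])
        assert {l.taxon.label for l in pruned.leaf_node_iter()} == {"q1", pl.target_leaf}

    def test_unknown_query_raises(self, small_reference):
        with pytest.raises(ValueError, match="unknown"):
            prune_to_queries(small_reference.tree, ["nope"])

    def test_path_lengths_preserved_by_pruning(self, small_reference):
        leaves = sorted(small_reference.msa)[:5]
        queries = {f"q{i}": small_reference.ungapped(l)[60:310] for i, l in enumerate(leaves)}
        placements = [place_query(q, s, small_reference) for q, s in sorted(queries.items())]
        ext, _ = extend(small_reference, placements, queries, with_msa=False)
        pruned = prune_to_queries(ext, sorted(queries))
        pdm_e = ext.phylogenetic_distance_matrix()
        pdm_p = pruned.phylogenetic_distance_matrix()
        te = {t.label: t for t in ext.taxon_namespace}
        tp = {t.label: t for t in pruned.taxon_namespace}
        qids = sorted(queries)
        for i, x in enumerate(qids):
            for y in qids[i + 1 :]:
                assert pdm_p.patristic_distance(tp[x], tp[y]) == pytest.approx(
                    pdm_e.patristic_distance(te[x], te[y]), abs=1e-9
                )

    def test_trim_keeps_query_window_and_sisters(self, small_reference):
        leaf = sorted(small_reference.msa)[8]
        query = small_reference.ungapped(leaf)[100:350]
        pl = place_query("q1", query, small_reference)
        ext, msa = extend(small_reference, [pl], {"q1": query})
        trimmed = trim_alignment(msa, ["q1"], tree=ext)
        assert set(trimmed) == {"q1", pl.target_leaf}
        assert len(trimmed["q1"]) <= 250
        assert trimmed["q1"].replace("-", "") == query
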