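"""Robinson-Foulds tree comparison and the placement-accuracy simulation.

The normalised Robinson-Foulds (RF) distance between two trees on the same
leaves is the size of the symmetric difference of their non-trivial
bipartition sets divided by the total number of internal edges in both
trees (for two binary trees this is the conventional 2(n-3) denominator;
the sum-of-edges form also handles the multifurcations pruning can create).

The leave-out simulation measures placement accuracy: sample a reference
subset of leaves from a large tree, take queries from the remainder,
extract a fixed-width amplicon-like window from each query's alignment
row, place the queries into the reference with the placement module, and
compare the placement-derived tree restricted to the queries against the
queries' induced subtree in the original (assumed true) tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .hp_align import AlignParams
from .placement import ReferenceSet, extend, place_query, remove_all_gap_columns

__all__ = [
    "SimConfig",
    "bipartitions",
    "rf_normalized",
    "induced_subtree",
    "random_resolved_tree",
    "run_simulation",
]


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions induced by internal edges.

    Each split is canonicalised as the side not containing the
    lexicographically smallest leaf, which also collapses the duplicate
    split a rooted tree's root edge would otherwise contribute.  Trees with
    fewer than 4 leaves have no non-trivial splits.
    """
    labels = _leaf_labels(tree)
    n = len(labels)
    if n < 4:
        return set()
    all_leaves = frozenset(labels)
    ref = min(labels)
    below: dict[dendropy.Node, frozenset[str]] = {}
    splits: set[frozenset[str]] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
            continue
        clade = frozenset().union(*(below[c] for c in node.child_nodes()))
        below[node] = clade
        if node is tree.seed_node:
            continue
        side = all_leaves - clade if ref in clade else clade
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return splits


def rf_normalized(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    """Normalised RF distance in [0, 1]; 0 iff the split sets coincide."""
    l1, l2 = set(_leaf_labels(t1)), set(_leaf_labels(t2))
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ; only in first: {sorted(l1 - l2)}, only in second: {sorted(l2 - l1)}"
        )
    b1, b2 = bipartitions(t1), bipartitions(t2)
    denom = len(b1) + len(b2)
    if denom == 0:
        return 0.0
    return len(b1 ^ b2) / denom


def induced_subtree(tree: dendropy.Tree, leaf_labels) -> dendropy.Tree:
    """Minimal subtree spanning ``leaf_labels``.

    Pass-through (unifurcating) nodes are suppressed with branch lengths
    summed, so pairwise path lengths among retained leaves are preserved.
    """
    want = set(leaf_labels)
    have = set(_leaf_labels(tree))
    unknown = sorted(want - have)
    if unknown:
        raise ValueError(f"unknown leaves: {unknown}")
    tns = dendropy.TaxonNamespace()
    # acc[node] = (new subtree root, pending edge length) or None
    acc: dict[dendropy.Node, tuple[dendropy.Node, float] | None] = {}
    for node in tree.postorder_node_iter():
        elen = node.edge.length or 0.0
        if node.is_leaf():
            if node.taxon.label in want:
                nn = dendropy.Node(taxon=tns.require_taxon(node.taxon.label))
                acc[node] = (nn, elen)
            else:
                acc[node] = None
            continue
        kids = [acc[c] for c in node.child_nodes() if acc[c] is not None]
        if not kids:
            acc[node] = None
        elif len(kids) == 1:
            child, plen = kids[0]
            acc[node] = (child, plen + elen)
        else:
            nn = dendropy.Node()
            for child, plen in kids:
                nn.add_child(child)
                child.edge.length = plen
            acc[node] = (nn, elen)
    entry = acc[tree.seed_node]
    if entry is None:
        raise ValueError("no requested leaves found in tree")
    root, _ = entry  # pending length above the new root is dropped
    root.edge.length = None
    out = dendropy.Tree(taxon_namespace=tns)
    out.seed_node = root
    return out


def random_resolved_tree(leaf_labels, rng: np.random.Generator) -> dendropy.Tree:
    """Uniform random binary tree on the given leaves (random joins)."""
    tns = dendropy.TaxonNamespace()
    nodes = []
    for name in leaf_labels:
        n = dendropy.Node(taxon=tns.require_taxon(name))
        n.edge.length = 1.0
        nodes.append(n)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = dendropy.Node()
        parent.edge.length = 1.0
        parent.add_child(a)
        parent.add_child(b)
        nodes = [n for n in nodes if n is not a and n is not b] + [parent]
    out = dendropy.Tree(taxon_namespace=tns)
    out.seed_node = nodes[0]
    return out


@dataclass
class SimConfig:
    """Leave-out placement simulation settings.

    The field defaults are the full study-scale conditions (750 reference
    sequences, 25-150 queries, 250 bp region, 1000 replicates); tests and
    the shipped acceptance run use smaller, documented values through the
    same code path.
    """

    n_reference: int = 750
    n_query: int = 25
    region_len: int = 250
    region_start: int = 0
    replicates: int = 1000
    seed: int = 0
    prescreen_top: int | None = 10
    align_params: AlignParams = AlignParams()

    def __post_init__(self) -> None:
        if self.n_reference < 4 or self.n_query < 3:
            raise ValueError("need at least 4 reference leaves and 3 queries")
        if self.region_len < 1 or self.replicates < 1:
            raise ValueError("region_len and replicates must be positive")


def _extract_region(row: str, start: int, length: int) -> str:
    return row[start : start + length].replace("-", "")


def run_simulation(ref: ReferenceSet, cfg: SimConfig) -> np.ndarray:
    """Per-replicate normalised RF between placed and true query trees.

    Per replicate: sample ``n_reference`` leaves as the working reference
    (induced subtree + MSA rows), sample ``n_query`` leaves from the
    remainder, cut a ``region_len`` window (alignment columns
    ``region_start:region_start+region_len``) from each query row, place
    the queries, and compute the RF distance between the placement tree
    restricted to the queries and the queries' induced subtree in the
    original tree.  Fully reproducible from ``cfg.seed``.
    """
    labels = sorted(ref.msa)
    if cfg.n_reference + cfg.n_query > len(labels):
        raise ValueError(
            f"need {cfg.n_reference + cfg.n_query} leaves, reference has {len(labels)}"
        )
    rf_values = np.empty(cfg.replicates)
    for rep in range(cfg.replicates):
        rng = np.random.default_rng([cfg.seed, rep])
        perm = rng.permutation(len(labels))
        ref_names = sorted(labels[i] for i in perm[: cfg.n_reference])
        rest = [labels[i] for i in perm[cfg.n_reference :]]
        query_names = sorted(rest[: cfg.n_query])

        sub_msa = remove_all_gap_columns({n: ref.msa[n] for n in ref_names})
        sub_tree = induced_subtree(ref.tree, ref_names)
        working = ReferenceSet(msa=sub_msa, tree=sub_tree)

        queries = {
            q: _extract_region(ref.msa[q], cfg.region_start, cfg.region_len)
            for q in query_names
        }
        placements = [
            place_query(
                q,
                queries[q],
                working,
                cfg.align_params,
                rng=rng,
                prescreen_top=cfg.prescreen_top,
            )
            for q in query_names
        ]
        ext_tree, _ = extend(working, placements, queries, cfg.align_params, with_msa=False)
        placed = induced_subtree(ext_tree, query_names)
        truth = induced_subtree(ref.tree, query_names)
        rf_values[rep] = rf_normalized(placed, truth)
    return rf_values


def random_baseline(ref: ReferenceSet, cfg: SimConfig) -> np.ndarray:
    """RF of random binary query trees against the true induced subtrees.

    Uses the same leaf draws as :func:`run_simulation`, replacing the
    placement tree with a uniformly random resolved tree — the sanity floor
    any real placement should beat.
    """
    labels = sorted(ref.msa)
    out = np.empty(cfg.replicates)
    for rep in range(cfg.replicates):
        rng = np.random.default_rng([cfg.seed, rep])
        perm = rng.permutation(len(labels))
        rest = [labels[i] for i in perm[cfg.n_reference :]]
        query_names = sorted(rest[: cfg.n_query])
        truth = induced_subtree(ref.tree, query_names)
        rand = random_resolved_tree(query_names, rng)
        out[rep] = rf_normalized(rand, truth)
    return out
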