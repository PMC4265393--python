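"""Reference-based phylogenetic placement of OTU centroids.

A fixed full-length marker-gene reference (multiple sequence alignment plus
a congruent phylogeny with branch lengths) is extended with short query
sequences: each query is compared against every extant reference sequence
(glocal alignment: query end-to-end, free end gaps on the reference, since
the amplicon is a subregion of the full gene), attached as a sister of the
best-matching leaf, and inserted into the alignment in reference
coordinates.  Tied candidates are resolved by a seeded uniform random draw,
and the tie is recorded on the Placement.  The final outputs can be pruned
to the queries plus their closest reference leaves and the alignment
trimmed around the amplicon region.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from . import hp_align
from .hp_align import AlignParams
from .io_formats import parse_newick, read_fasta, read_newick, write_newick

__all__ = [
    "ReferenceSet",
    "Placement",
    "load_reference",
    "find_candidates",
    "place_query",
    "jc_distance",
    "extend",
    "prune_to_queries",
    "trim_alignment",
]


@dataclass
class ReferenceSet:
    """Full-gene reference MSA plus a congruent phylogeny.

    Row names and tree leaf names must coincide exactly; all rows share one
    (gapped) length.
    """

    msa: dict[str, str]
    tree: dendropy.Tree
    _ungapped: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.msa.values()}
        if len(lengths) > 1:
            raise ValueError(f"reference MSA rows have differing lengths: {sorted(lengths)}")
        leaf_names = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        msa_names = set(self.msa)
        if leaf_names != msa_names:
            only_tree = sorted(leaf_names - msa_names)
            only_msa = sorted(msa_names - leaf_names)
            raise ValueError(
                f"reference MSA and tree leaf names differ; only in tree: {only_tree}, "
                f"only in MSA: {only_msa}"
            )

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.msa.values()))) if self.msa else 0

    def ungapped(self, name: str) -> str:
        if name not in self._ungapped:
            self._ungapped[name] = self.msa[name].replace("-", "")
        return self._ungapped[name]


@dataclass
class Placement:
    """Chosen attachment of one query at a reference leaf."""

    query_id: str
    target_leaf: str
    similarity: float
    pendant_length: float
    candidates: list[str]
    chosen_by_tiebreak: bool = False

    def __post_init__(self) -> None:
        if self.target_leaf not in self.candidates:
            raise ValueError("target_leaf must be among the candidates")
        if not 0 <= self.similarity <= 1:
            raise ValueError("similarity must lie in [0, 1]")
        if self.pendant_length < 0:
            raise ValueError("pendant_length must be >= 0")


def remove_all_gap_columns(msa: dict[str, str]) -> dict[str, str]:
    if not msa:
        return msa
    arr = np.array([list(s) for s in msa.values()])
    keep = ~np.all((arr == "-") | (arr == "."), axis=0)
    names = list(msa)
    return {n: "".join(row) for n, row in zip(names, arr[:, keep])}


def load_reference(msa_path, tree_path) -> ReferenceSet:
    """Load and validate a reference MSA (FASTA) + tree (newick).

    ``.`` gap characters are normalised to ``-`` and columns containing
    only gaps are removed, mirroring standard curation of database-derived
    alignments.
    """
    msa = {name: seq.upper().replace(".", "-") for name, seq in read_fasta(msa_path)}
    tree = read_newick(tree_path)
    return ReferenceSet(msa=remove_all_gap_columns(msa), tree=tree)


def _edlib_rank(query: str, ref: ReferenceSet, names: list[str], top: int) -> list[str]:
    import edlib

    scored = sorted(
        (edlib.align(query, ref.ungapped(n), mode="HW", task="distance")["editDistance"], n)
        for n in names
    )
    return [n for _, n in scored[:top]]


def find_candidates(
    query: str,
    ref: ReferenceSet,
    params: AlignParams = AlignParams(),
    prescreen_top: int | None = None,
) -> list[tuple[str, float]]:
    """Similarity of ``query`` against every extant reference leaf.

    Returns ``(leaf, similarity)`` sorted by descending similarity (ties by
    name).  By default the scan is exhaustive over all leaves; with
    ``prescreen_top`` set, a fast edit-distance prescreen (edlib, infix
    mode) keeps only the top candidates for the full homopolymer-aware
    alignment and the returned list is restricted to them.
    """
    if not query:
        raise ValueError("query sequence is empty")
    names = sorted(ref.msa)
    if prescreen_top is not None and prescreen_top < len(names):
        names = _edlib_rank(query, ref, names, prescreen_top)
    sims = []
    for name in names:
        res = hp_align.align(ref.ungapped(name), query, params, free_ends_a=True)
        sims.append((name, hp_align.similarity(res)))
    sims.sort(key=lambda t: (-t[1], t[0]))
    return sims


def jc_distance(p: float, maximum: float = 3.0) -> float:
    """Jukes-Cantor distance ``-(3/4) ln(1 - (4/3) p)`` for mismatch fraction p.

    Saturated inputs (p >= 0.75) return ``maximum`` with a warning.
    """
    if p <= 0:
        return 0.0
    if p >= 0.75:
        warnings.warn(f"mismatch fraction {p:.3f} saturates the JC correction; using {maximum}")
        return maximum
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def place_query(
    query_id: str,
    query: str,
    ref: ReferenceSet,
    params: AlignParams = AlignParams(),
    rng: np.random.Generator | int | None = None,
    prescreen_top: int | None = None,
    tie_epsilon: float = 1e-9,
    max_pendant: float = 3.0,
) -> Placement:
    """Choose the attachment leaf for one query and its pendant length.

    The target is the sole best candidate, or a uniform random draw among
    candidates tied within ``tie_epsilon`` of the best (reproducible via
    ``rng``, which may be a seed).  The pendant branch length is the
    Jukes-Cantor distance of the query-vs-target alignment, with mismatch
    fraction computed over counted (non-hp_gap) columns.
    """
    cands = find_candidates(query, ref, params, prescreen_top=prescreen_top)
    best_sim = cands[0][1]
    tied = sorted(n for n, s in cands if s >= best_sim - tie_epsilon)
    if len(tied) == 1:
        target = tied[0]
        tiebreak = False
    else:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        target = tied[int(rng.integers(len(tied)))]
        tiebreak = True
    res = hp_align.align(ref.ungapped(target), query, params, free_ends_a=True)
    p_mis = res.n_mismatch / res.n_counted
    return Placement(
        query_id=query_id,
        target_leaf=target,
        similarity=best_sim,
        pendant_length=jc_distance(p_mis, maximum=max_pendant),
        candidates=tied,
        chosen_by_tiebreak=tiebreak,
    )


def _leaf_map(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}


def extend(
    ref: ReferenceSet,
    placements: list[Placement],
    queries: dict[str, str],
    params: AlignParams = AlignParams(),
    attach_fraction: float = 0.5,
    with_msa: bool = True,
) -> tuple[dendropy.Tree, dict[str, str]]:
    """Insert placed queries into the reference tree and alignment.

    Each query becomes a sister of its target leaf: the target's pendant
    branch is bisected at ``attach_fraction`` of its length (measured from
    the parent) and the query hangs from the new node with its pendant
    length.  The query row is added to the MSA in reference coordinates;
    query insertions relative to the target become new columns that are
    gaps in every other row.  Path lengths among reference leaves are
    unchanged.
    """
    tree = parse_newick(write_newick(ref.tree))
    leaf_of = _leaf_map(tree)
    tns = tree.taxon_namespace
    for pl in placements:
        if pl.query_id in leaf_of:
            raise ValueError(f"query id {pl.query_id!r} collides with an existing leaf")
        target = leaf_of[pl.target_leaf]
        parent = target.parent_node
        e = target.edge.length or 0.0
        new = dendropy.Node()
        if parent is None:  # target is the root (degenerate single-leaf tree)
            tree.seed_node = new
        else:
            parent.remove_child(target)
            parent.add_child(new)
        new.edge.length = e * attach_fraction
        new.add_child(target)
        target.edge.length = e * (1.0 - attach_fraction)
        q = dendropy.Node(taxon=tns.require_taxon(pl.query_id))
        q.edge.length = pl.pendant_length
        new.add_child(q)
        leaf_of[pl.query_id] = q

    if not with_msa:
        return tree, dict(ref.msa)

    ncol = ref.n_columns
    # insertions[anchor] = list of (query_id, inserted bases); anchor -1 = before
    # the first column, anchor c = immediately after base column c.
    insertions: dict[int, list[tuple[str, str]]] = {}
    query_cols: dict[str, dict[int, str]] = {}
    for pl in placements:
        qseq = queries[pl.query_id]
        target_row = ref.msa[pl.target_leaf]
        colmap = [i for i, c in enumerate(target_row) if c != "-"]
        res = hp_align.align(ref.ungapped(pl.target_leaf), qseq, params, free_ends_a=True)
        ti = res.a_start  # next target (ungapped) index to consume
        row: dict[int, str] = {}
        pending_ins: list[str] = []
        anchor = colmap[ti - 1] if ti > 0 else -1
        for ca, cb in zip(res.aligned_a, res.aligned_b):
            if ca != "-" and cb != "-":
                if pending_ins:
                    insertions.setdefault(anchor, []).append((pl.query_id, "".join(pending_ins)))
                    pending_ins = []
                row[colmap[ti]] = cb
                anchor = colmap[ti]
                ti += 1
            elif ca != "-":  # gap in query: target column stays a gap for the query
                if pending_ins:
                    insertions.setdefault(anchor, []).append((pl.query_id, "".join(pending_ins)))
                    pending_ins = []
                anchor = colmap[ti]
                ti += 1
            else:  # insertion in the query relative to the target
                pending_ins.append(cb)
        if pending_ins:
            insertions.setdefault(anchor, []).append((pl.query_id, "".join(pending_ins)))
        query_cols[pl.query_id] = row

    names = list(ref.msa) + [pl.query_id for pl in placements]
    out: dict[str, list[str]] = {n: [] for n in names}

    def emit_insertions(anchor: int) -> None:
        for owner, bases in insertions.get(anchor, []):
            for n in names:
                out[n].append(bases if n == owner else "-" * len(bases))

    emit_insertions(-1)
    for c in range(ncol):
        for n in names:
            if n in ref.msa:
                out[n].append(ref.msa[n][c])
            else:
                out[n].append(query_cols[n].get(c, "-"))
        emit_insertions(c)
    return tree, {n: "".join(parts) for n, parts in out.items()}


def sister_reference_leaf(tree: dendropy.Tree, query_leaf: dendropy.Node,
                          query_ids: set[str]) -> str:
    """Closest (by path length) non-query leaf reachable via the parent."""
    best_name, best_dist = None, math.inf
    node = query_leaf
    base = query_leaf.edge.length or 0.0
    parent = node.parent_node
    while parent is not None and best_name is None:
        for child in parent.child_nodes():
            if child is node:
                continue
            stack = [(child, base + (child.edge.length or 0.0))]
            while stack:
                cur, d = stack.pop()
                if cur.is_leaf():
                    if cur.taxon.label not in query_ids and d < best_dist:
                        best_name, best_dist = cur.taxon.label, d
                else:
                    for grand in cur.child_nodes():
                        stack.append((grand, d + (grand.edge.length or 0.0)))
        base += parent.edge.length or 0.0
        node = parent
        parent = node.parent_node
    if best_name is None:
        raise ValueError(f"no reference leaf found near query {query_leaf.taxon.label!r}")
    return best_name


def prune_to_queries(extended: dendropy.Tree, query_ids: list[str]) -> dendropy.Tree:
    """Minimal induced subtree on the queries plus their sister reference leaves.

    Pass-through nodes are suppressed with branch lengths summed, so path
    lengths between retained leaves equal those in the unpruned tree.
    """
    from .treesim import induced_subtree

    leaf_of = _leaf_map(extended)
    unknown = [q for q in query_ids if q not in leaf_of]
    if unknown:
        raise ValueError(f"unknown query ids: {unknown}")
    qset = set(query_ids)
    keep = set(query_ids)
    for q in query_ids:
        keep.add(sister_reference_leaf(extended, leaf_of[q], qset))
    return induced_subtree(extended, sorted(keep))


def trim_alignment(extended_msa: dict[str, str], query_ids: list[str],
                   sisters: list[str] | None = None,
                   tree: dendropy.Tree | None = None) -> dict[str, str]:
    """Trim the extended MSA around the region covered by the queries.

    Keeps rows for the queries and their sister reference leaves (either
    given explicitly or located in ``tree``), keeps columns from the first
    to the last column where any query has a base, then drops columns that
    became all-gap.
    """
    missing = [q for q in query_ids if q not in extended_msa]
    if missing:
        raise ValueError(f"queries absent from alignment: {missing}")
    if sisters is None:
        if tree is None:
            raise ValueError("provide either sisters or the extended tree")
        leaf_of = _leaf_map(tree)
        qset = set(query_ids)
        sisters = sorted({sister_reference_leaf(tree, leaf_of[q], qset) for q in query_ids})
    rows = {n: extended_msa[n] for n in list(query_ids) + list(sisters)}
    occupied = [
        i
        for i in range(len(next(iter(rows.values()))))
        if any(extended_msa[q][i] != "-" for q in query_ids)
    ]
    lo, hi = occupied[0], occupied[-1] + 1
    trimmed = {n: s[lo:hi] for n, s in rows.items()}
    return remove_all_gap_columns(trimmed)
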