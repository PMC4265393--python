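"""Synthetic fixtures: reference sets, communities and 454-like reads.

Generates everything needed to exercise the pipeline without downloading
data: a random phylogeny, sequences evolved along it under Jukes-Cantor,
per-sample community abundances, and reads carrying barcode + primer +
template with substitution errors and homopolymer-length slips — the error
signature of Roche/454 pyrosequencing.  A truth table maps every read back
to its template and every template to its source tree leaf, so recovery
can be scored exactly.

General indels are deliberately not simulated: after denoising and
truncation to a uniform length the real 454 workflow leaves homopolymer
slips as the dominant length error, and the clustering similarity assumes
equal-length inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io_formats import Read, write_fasta, write_fastq, write_newick_file
from .placement import ReferenceSet

__all__ = [
    "ErrorModel",
    "TruthTable",
    "SimulatedCommunity",
    "sim_tree",
    "evolve_alignment",
    "sim_reads",
    "make_reference",
    "community_fixture",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ErrorModel:
    """454-like per-read error model.

    ``sub_rate`` is the per-base substitution probability.  Homopolymer
    slips are +-1 base per run: a run of length L >= 3 slips with
    probability ``min(hp_slip_base * (L - 2), 0.5)`` — linear growth with
    run length, matching the flow-signal origin of 454 length errors.
    Qualities decline linearly from ``q_start`` to ``q_end`` along the read
    with Gaussian jitter ``q_sd``.
    """

    sub_rate: float = 0.001
    hp_slip_base: float = 0.01
    q_start: float = 37.0
    q_end: float = 30.0
    q_sd: float = 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.sub_rate <= 1 or not 0 <= self.hp_slip_base <= 1:
            raise ValueError("probabilities must lie in [0, 1]")

    def slip_probability(self, run_length: int) -> float:
        if run_length < 3:
            return 0.0
        return min(self.hp_slip_base * (run_length - 2), 0.5)


@dataclass
class TruthTable:
    """read_id -> (template_id, sample_id) and template_id -> source leaf."""

    reads: dict[str, tuple[str, str]] = field(default_factory=dict)
    templates: dict[str, str] = field(default_factory=dict)


def sim_tree(
    n_leaves: int,
    seed: int,
    branch_mean: float = 0.05,
    branch_min: float = 0.01,
) -> dendropy.Tree:
    """Random binary tree via uniform coalescent-style joins.

    Branch lengths are ``branch_min`` plus an exponential of mean
    ``branch_mean`` (expected substitutions per site).  Leaves are named
    ``L0001``.. in order.  Deterministic per seed.
    """
    if n_leaves < 4:
        raise ValueError("need at least 4 leaves")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_leaves):
        n = dendropy.Node(taxon=tns.require_taxon(f"L{i + 1:04d}"))
        nodes.append(n)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = dendropy.Node()
        for child in (a, b):
            parent.add_child(child)
            child.edge.length = branch_min + rng.exponential(branch_mean)
        nodes = [n for n in nodes if n is not a and n is not b] + [parent]
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[0]
    return tree


def _jc_mutate(seq: np.ndarray, distance: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an integer-coded sequence a branch of given length under JC."""
    p_change = 0.75 * (1.0 - math.exp(-4.0 * distance / 3.0))
    hit = rng.random(seq.size) < p_change
    out = seq.copy()
    if hit.any():
        # substitute with a uniformly chosen different base
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def evolve_alignment(tree: dendropy.Tree, root_length: int, seed: int) -> dict[str, str]:
    """Jukes-Cantor evolution of an ungapped alignment along ``tree``.

    Returns leaf name -> sequence (all equal length, no gaps).  Expected
    pairwise identity decays with path length as
    ``1 - (3/4)(1 - exp(-4 d / 3))``.
    """
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=root_length)
    seqs: dict[str, str] = {}
    state = {tree.seed_node: root_seq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            cur = state[node]
        else:
            cur = _jc_mutate(state[node.parent_node], node.edge.length or 0.0, rng)
            state[node] = cur
        if node.is_leaf():
            seqs[node.taxon.label] = "".join(_BASES[cur])
    return seqs


def make_reference(n_leaves: int, n_columns: int, seed: int,
                   branch_mean: float = 0.05, branch_min: float = 0.01) -> ReferenceSet:
    """Synthetic full-length reference: tree + congruent ungapped MSA."""
    tree = sim_tree(n_leaves, seed, branch_mean=branch_mean, branch_min=branch_min)
    msa = evolve_alignment(tree, n_columns, seed + 1)
    return ReferenceSet(msa=msa, tree=tree)


def _apply_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


def _apply_hp_slips(seq: str, error: ErrorModel, rng: np.random.Generator) -> str:
    out = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = j - i
        p = error.slip_probability(run)
        if p > 0 and rng.random() < p:
            run += 1 if rng.random() < 0.5 else -1
        out.append(seq[i] * run)
        i = j
    return "".join(out)


def _qualities(length: int, error: ErrorModel, rng: np.random.Generator) -> list[int]:
    pos = np.arange(length)
    mean = error.q_start + (error.q_end - error.q_start) * pos / max(length - 1, 1)
    q = np.rint(mean + rng.normal(0.0, error.q_sd, size=length))
    return [int(v) for v in np.clip(q, 2, 40)]


def _resolve_iupac(primer: str, rng: np.random.Generator) -> str:
    from .preprocess import IUPAC

    return "".join(
        c if c in "ACGT" else str(rng.choice(sorted(IUPAC[c]))) for c in primer.upper()
    )


def sim_reads(
    templates: dict[str, str],
    community: dict[str, dict[str, int]],
    error: ErrorModel,
    barcodes: dict[str, str],
    primer: str,
    seed: int,
) -> tuple[list[Read], TruthTable]:
    """Emit reads = barcode + primer + noisy template copy, plus the truth.

    ``community[sample][template_id]`` is the exact number of reads to emit;
    read counts match the request exactly and every read has one truth row.
    """
    rng = np.random.default_rng(seed)
    truth = TruthTable()
    reads: list[Read] = []
    counter = 0
    for sample in sorted(community):
        for template_id in sorted(community[sample]):
            count = community[sample][template_id]
            if count < 1:
                raise ValueError("abundances must be positive")
            for _ in range(count):
                counter += 1
                rid = f"r{counter:06d}"
                insert = _apply_substitutions(templates[template_id], error.sub_rate, rng)
                insert = _apply_hp_slips(insert, error, rng)
                seq = barcodes[sample] + _resolve_iupac(primer, rng) + insert
                reads.append(Read(id=rid, seq=seq, qual=_qualities(len(seq), error, rng)))
                truth.reads[rid] = (template_id, sample)
    return reads, truth


@dataclass
class SimulatedCommunity:
    """A complete synthetic study: reference, templates, reads, truth."""

    reference: ReferenceSet
    templates: dict[str, str]
    community: dict[str, dict[str, int]]
    barcodes: dict[str, str]
    primer: str
    reads: list[Read]
    truth: TruthTable

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        write_fastq(self.reads, os.path.join(outdir, "reads.fastq"))
        with open(os.path.join(outdir, "barcodes.tsv"), "w") as fh:
            for sample, bc in sorted(self.barcodes.items()):
                fh.write(f"{sample}\t{bc}\n")
        write_fasta(sorted(self.reference.msa.items()), os.path.join(outdir, "reference.fasta"))
        write_newick_file(self.reference.tree, os.path.join(outdir, "reference.nwk"))
        write_fasta(sorted(self.templates.items()), os.path.join(outdir, "templates.fasta"))
        with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
            fh.write("read_id\ttemplate_id\tsample_id\tsource_leaf\n")
            for rid, (tid, sample) in sorted(self.truth.reads.items()):
                fh.write(f"{rid}\t{tid}\t{sample}\t{self.truth.templates.get(tid, '')}\n")
        with open(os.path.join(outdir, "primer.txt"), "w") as fh:
            fh.write(self.primer + "\n")


def _make_barcodes(n_samples: int, length: int, min_distance: int,
                   rng: np.random.Generator) -> dict[str, str]:
    barcodes: list[str] = []
    while len(barcodes) < n_samples:
        cand = "".join(_BASES[rng.integers(0, 4, size=length)])
        if all(sum(a != b for a, b in zip(cand, bc)) >= min_distance for bc in barcodes):
            barcodes.append(cand)
    return {f"S{i + 1:02d}": bc for i, bc in enumerate(barcodes)}


DEFAULT_PRIMER = "GTGCCAGCMGCCGCGGTAA"


def community_fixture(
    n_templates: int = 20,
    n_samples: int = 4,
    template_len: int = 250,
    mean_depth: int = 25,
    samples_per_template: int = 2,
    error: ErrorModel = ErrorModel(),
    seed: int = 42,
    branch_mean: float = 0.08,
    branch_min: float = 0.03,
    primer: str = DEFAULT_PRIMER,
) -> SimulatedCommunity:
    """A small 454-like study with known ground truth.

    Templates are the leaf sequences of a random tree whose branch lengths
    keep pairwise identity well below typical clustering thresholds, so
    each template should found exactly one OTU.  Each template occurs in
    ``samples_per_template`` samples with a lognormal copy number around
    ``mean_depth``.
    """
    rng = np.random.default_rng(seed)
    tree = sim_tree(n_templates, seed, branch_mean=branch_mean, branch_min=branch_min)
    msa = evolve_alignment(tree, template_len, seed + 1)
    reference = ReferenceSet(msa=msa, tree=tree)
    truth = TruthTable()
    templates: dict[str, str] = {}
    for i, leaf in enumerate(sorted(msa)):
        tid = f"T{i + 1:03d}"
        templates[tid] = msa[leaf]
        truth.templates[tid] = leaf
    barcodes = _make_barcodes(n_samples, length=8, min_distance=5, rng=rng)
    samples = sorted(barcodes)
    community: dict[str, dict[str, int]] = {s: {} for s in samples}
    for tid in sorted(templates):
        chosen = rng.choice(len(samples), size=min(samples_per_template, n_samples),
                            replace=False)
        for k in chosen:
            depth = max(5, int(round(rng.lognormal(math.log(mean_depth), 0.4))))
            community[samples[int(k)]][tid] = depth
    reads, read_truth = sim_reads(templates, community, error, barcodes, primer,
                                  seed=int(rng.integers(0, 2**31 - 1)))
    truth.reads = read_truth.reads
    return SimulatedCommunity(
        reference=reference,
        templates=templates,
        community=community,
        barcodes=barcodes,
        primer=primer,
        reads=reads,
        truth=truth,
    )
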