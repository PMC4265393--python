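"""Greedy abundance-ordered OTU clustering.

Dereplicated sequences are processed in descending order of total copy
number, on the assumption that the most abundant sequences are error-free
and that sequencing artefacts are rare but highly similar to the template
they derived from.  Each sequence is compared to the centroids of existing
OTUs with the homopolymer-aware similarity; if the best similarity reaches
the threshold it joins that OTU (best-fit assignment), otherwise it founds
a new OTU with itself as centroid.  Every input ends up in exactly one OTU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import hp_align
from .hp_align import AlignParams
from .io_formats import AbundanceMatrix
from .preprocess import UniqueSeq

__all__ = [
    "OTU",
    "greedy_cluster",
    "multisample_filter",
    "abundance_matrix",
    "label_otus",
]

_EPS = 1e-12


@dataclass
class OTU:
    id: str
    centroid: UniqueSeq
    members: list[UniqueSeq] = field(default_factory=list)
    abundance: dict[str, int] = field(default_factory=dict)
    label: str | None = None

    @property
    def total(self) -> int:
        return sum(self.abundance.values())

    def _add(self, u: UniqueSeq) -> None:
        self.members.append(u)
        for sample, c in u.counts.items():
            self.abundance[sample] = self.abundance.get(sample, 0) + c


def greedy_cluster(
    uniques: list[UniqueSeq],
    threshold: float,
    params: AlignParams = AlignParams(),
) -> list[OTU]:
    """Cluster UniqueSeqs greedily in descending abundance order.

    ``threshold`` is the minimum similarity (fraction in (0, 1]) for a
    sequence to join an existing OTU.  Assignment is best-fit: the
    highest-similarity centroid at or above the threshold wins; ties go to
    the more abundant (earlier-created) centroid.  Input order does not
    matter: the processing order is (descending total, sequence).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    ordered = sorted(uniques, key=lambda u: (-u.total, u.seq))
    otus: list[OTU] = []
    for u in ordered:
        best_otu = None
        best_sim = -1.0
        for otu in otus:  # creation order == descending centroid abundance
            sim = hp_align.similarity(hp_align.align(otu.centroid.seq, u.seq, params))
            if sim > best_sim + _EPS:
                best_sim = sim
                best_otu = otu
        if best_otu is not None and best_sim >= threshold - _EPS:
            best_otu._add(u)
        else:
            otu = OTU(id=f"OTU_{len(otus) + 1:04d}", centroid=u)
            otu._add(u)
            otus.append(otu)
    return otus


def multisample_filter(otus: list[OTU]) -> list[OTU]:
    """Keep only OTUs observed (nonzero count) in at least two samples.

    An OTU seen in a single sample is often irrelevant when the question is
    about patterns across samples or time points.
    """
    return [o for o in otus if sum(1 for c in o.abundance.values() if c > 0) >= 2]


def abundance_matrix(otus: list[OTU], sample_order: list[str]) -> AbundanceMatrix:
    """Build the OTU x sample count matrix in the given sample order."""
    if len(set(sample_order)) != len(sample_order):
        raise ValueError("duplicate sample ids in sample_order")
    import numpy as np

    counts = np.array(
        [[o.abundance.get(s, 0) for s in sample_order] for o in otus], dtype=int
    ).reshape(len(otus), len(sample_order))
    return AbundanceMatrix(
        otu_ids=[o.id for o in otus],
        sample_ids=list(sample_order),
        counts=counts,
    )


def label_otus(otus: list[OTU], ref, params: AlignParams = AlignParams(),
               tie_epsilon: float = 1e-6) -> list[OTU]:
    """Label each OTU with the name of its most similar reference leaf.

    The centroid is glocally aligned (free end gaps on the full-length
    reference) against every ungapped reference sequence.  Best hits tied
    within ``tie_epsilon`` are joined with ``|`` so that the uncertainty is
    visible in the label.  Returns the same OTU objects, labelled.
    """
    names = sorted(ref.msa)
    for otu in otus:
        sims = []
        for name in names:
            sim = hp_align.similarity(
                hp_align.align(ref.ungapped(name), otu.centroid.seq, params, free_ends_a=True)
            )
            sims.append((sim, name))
        best = max(s for s, _ in sims)
        hits = [n for s, n in sims if s >= best - tie_epsilon]
        otu.label = f"{'|'.join(hits)} ({best:.4f})"
    return otus
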