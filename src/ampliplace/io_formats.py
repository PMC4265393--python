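"""Readers and writers for FASTA, FASTQ (Phred+33), newick and BIOM 1.0 JSON.

This module is the boundary between files on disk and the pipeline's
in-memory types.  Sequence records go through Biopython, trees through
dendropy; BIOM tables use the JSON (1.0) dialect so that round-tripping
needs no HDF5 stack.  All paths may be plain or gzip-compressed (``.gz``).
"""

from __future__ import annotations

import gzip
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Iterator, TextIO

import dendropy
import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "Read",
    "AbundanceMatrix",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "parse_newick",
    "write_newick",
    "read_newick",
    "write_newick_file",
    "write_biom",
    "read_biom",
]

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class Read:
    """One sequencing read with per-base Phred qualities.

    ``sample`` is the originating sample once demultiplexed, or
    ``"unassigned"`` before.
    """

    id: str
    seq: str
    qual: list[int]
    sample: str = UNASSIGNED

    def __post_init__(self) -> None:
        if len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != sequence length {len(self.seq)}"
            )
        if self.qual and (min(self.qual) < 0 or max(self.qual) > 93):
            raise ValueError(f"read {self.id!r}: Phred scores must lie in [0, 93]")

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path, mode: str = "rt") -> TextIO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[Read]:
    """Stream Reads from a 4-line-record FASTQ file (Sanger/Phred+33).

    Malformed records raise ``ValueError`` naming the 1-based record index.
    """
    count = 0
    with _open_text(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                count += 1
                if len(qual) != len(seq):
                    raise ValueError(
                        f"FASTQ record {count} ({title.split()[0]!r}): "
                        f"quality/sequence length mismatch"
                    )
                yield Read(
                    id=title.split()[0],
                    seq=seq.upper(),
                    qual=[ord(c) - 33 for c in qual],
                )
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record near record {count + 1}: {exc}") from exc
    logger.info("read_fastq: %d records from %s", count, path)


def write_fastq(reads: Iterable[Read], path) -> int:
    n = 0
    with _open_text(path, "wt") as handle:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qual)
            handle.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path) -> Iterator[tuple[str, str]]:
    """Stream ``(id, sequence)`` tuples; multi-line sequences concatenated.

    The id is the header token up to the first whitespace.  Empty records
    yield an empty sequence with a warning; sequence data before the first
    header is a parse error.
    """
    count = 0
    with _open_text(path) as handle:
        header: str | None = None
        chunks: list[str] = []
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    seq = "".join(chunks)
                    if not seq:
                        warnings.warn(f"empty FASTA record {header!r}")
                    count += 1
                    yield header, seq
                header = line[1:].split()[0] if line[1:].split() else ""
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"FASTA parse error at line {lineno}: sequence before first header")
                chunks.append(line.upper())
        if header is not None:
            seq = "".join(chunks)
            if not seq:
                warnings.warn(f"empty FASTA record {header!r}")
            count += 1
            yield header, seq
    logger.info("read_fasta: %d records from %s", count, path)


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> int:
    n = 0
    with _open_text(path, "wt") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, max(len(seq), 1), width):
                handle.write(seq[i : i + width] + "\n")
            n += 1
    return n


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string into a dendropy Tree.

    Leaf names must be unique and branch lengths non-negative.  Missing
    branch lengths default to 0.0 when any other branch carries a length;
    a tree with no lengths at all keeps them absent (``None``).
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf names in newick tree: {dupes}")
    lengths = [e.length for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
    if any(l is not None and l < 0 for l in lengths):
        raise ValueError("negative branch length in newick tree")
    if any(l is not None for l in lengths):
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node and edge.length is None:
                edge.length = 0.0
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to newick with 12-significant-digit branch lengths."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".12g",
    )
    return text.strip() + "\n"


def read_newick(path) -> dendropy.Tree:
    with _open_text(path) as handle:
        return parse_newick(handle.read())


def write_newick_file(tree: dendropy.Tree, path) -> None:
    with _open_text(path, "wt") as handle:
        handle.write(write_newick(tree))


@dataclass
class AbundanceMatrix:
    """OTU-by-sample table of non-negative integer counts."""

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), dtype=int))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.otu_ids)}, {len(self.sample_ids)})"
            )
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def write_biom(matrix: AbundanceMatrix, path, table_id: str = "ampliplace OTU table") -> None:
    """Write a BIOM 1.0 JSON sparse OTU table; zero counts are omitted."""
    rows, cols = np.nonzero(matrix.counts)
    data = [[int(r), int(c), int(matrix.counts[r, c])] for r, c in zip(rows, cols)]
    doc = {
        "id": table_id,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "ampliplace",
        "date": datetime.now(timezone.utc).isoformat(),
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [len(matrix.otu_ids), len(matrix.sample_ids)],
        "rows": [{"id": i, "metadata": None} for i in matrix.otu_ids],
        "columns": [{"id": s, "metadata": None} for s in matrix.sample_ids],
        "data": data,
    }
    with _open_text(path, "wt") as handle:
        json.dump(doc, handle, indent=1)
        handle.write("\n")


def read_biom(path) -> AbundanceMatrix:
    with _open_text(path) as handle:
        doc = json.load(handle)
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    counts = np.zeros(tuple(doc["shape"]), dtype=int)
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            counts[r, c] = v
    else:
        counts = np.asarray(doc["data"], dtype=int)
    return AbundanceMatrix(otu_ids=otu_ids, sample_ids=sample_ids, counts=counts)
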