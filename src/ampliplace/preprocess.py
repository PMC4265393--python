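"""Read QC, demultiplexing, trimming, truncation and dereplication.

Everything between raw (already denoised) amplicon FASTQ and the clustering
input.  Reads are laid out 5' barcode + primer + insert; a read is assigned
to the unique sample whose barcode lies within ``max_barcode_errors``
Hamming mismatches, the primer is then matched immediately after the barcode
(IUPAC degeneracies expand to their base sets) and both are trimmed off.
Quality filtering covers minimum, average and windowed quality, ambiguous
base calls and length; reads are truncated to a uniform length so that the
clustering similarity is defined over equal-length sequences.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .io_formats import Read

__all__ = [
    "Reject",
    "BarcodeMap",
    "QCParams",
    "UniqueSeq",
    "demultiplex",
    "quality_filter",
    "truncate",
    "dereplicate",
    "copy_number_filter",
    "run_preprocess",
    "IUPAC",
]

IUPAC = {
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "T": {"T"},
    "R": {"A", "G"},
    "Y": {"C", "T"},
    "S": {"C", "G"},
    "W": {"A", "T"},
    "K": {"G", "T"},
    "M": {"A", "C"},
    "B": {"C", "G", "T"},
    "D": {"A", "G", "T"},
    "H": {"A", "C", "T"},
    "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


class Reject(NamedTuple):
    """A non-exceptional rejection outcome with its reason code."""

    reason: str


@dataclass
class BarcodeMap:
    """sample_id -> barcode; all barcodes must share one length."""

    barcodes: dict[str, str]

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("barcode map is empty")
        lengths = {len(b) for b in self.barcodes.values()}
        if len(lengths) != 1:
            raise ValueError(f"barcodes must all have the same length, got lengths {sorted(lengths)}")
        values = list(self.barcodes.values())
        if len(set(values)) != len(values):
            raise ValueError("barcodes must be pairwise distinct")

    @property
    def length(self) -> int:
        return len(next(iter(self.barcodes.values())))

    def check_separation(self, max_barcode_errors: int) -> None:
        """Warn if two barcodes are close enough for ambiguous assignment."""
        items = sorted(self.barcodes.items())
        for i, (s1, b1) in enumerate(items):
            for s2, b2 in items[i + 1 :]:
                d = sum(x != y for x, y in zip(b1, b2))
                if d <= 2 * max_barcode_errors:
                    warnings.warn(
                        f"barcodes for {s1!r} and {s2!r} differ at only {d} positions; "
                        f"assignment with up to {max_barcode_errors} errors may be ambiguous"
                    )


@dataclass(frozen=True)
class QCParams:
    """Quality-control thresholds.

    Defaults mirror the study conditions: at most one barcode error, at most
    two primer errors, truncation to 250 bp, no ambiguous base calls.  The
    pure quality thresholds default to permissive values (``window_len=0``
    disables the windowed filter).
    """

    min_q: int = 0
    avg_q: float = 0.0
    window_len: int = 0
    window_q: float = 0.0
    min_len: int = 0
    truncate_len: int = 250
    max_barcode_errors: int = 1
    max_primer_errors: int = 2
    allow_ambiguous: bool = False

    def __post_init__(self) -> None:
        for name in ("min_q", "avg_q", "window_len", "window_q", "min_len", "truncate_len",
                     "max_barcode_errors", "max_primer_errors"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.truncate_len and self.truncate_len < self.min_len:
            raise ValueError("truncate_len must be >= min_len")


@dataclass
class UniqueSeq:
    """A dereplicated sequence with per-sample copy numbers."""

    seq: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("per-sample copy numbers must be >= 1")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def max_per_sample(self) -> int:
        return max(self.counts.values()) if self.counts else 0


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _primer_mismatches(primer: str, segment: str) -> int:
    mism = 0
    for p, s in zip(primer, segment):
        if s not in IUPAC.get(p.upper(), {p.upper()}):
            mism += 1
    return mism


def demultiplex(
    read: Read,
    barcodes: BarcodeMap,
    primer: str,
    p: QCParams = QCParams(),
):
    """Assign ``read`` to a sample and trim barcode + primer.

    Returns ``(sample_id, trimmed_read)`` or ``Reject(reason)`` with reason
    in ``{"barcode", "ambiguous_barcode", "primer", "short"}`` (reads too
    short to contain barcode + primer are rejected as ``"short"``).
    """
    blen = barcodes.length
    plen = len(primer)
    if len(read.seq) < blen + plen:
        return Reject("short")
    prefix = read.seq[:blen]
    hits = [
        sample
        for sample, bc in sorted(barcodes.barcodes.items())
        if _hamming(prefix, bc) <= p.max_barcode_errors
    ]
    if not hits:
        return Reject("barcode")
    if len(hits) > 1:
        return Reject("ambiguous_barcode")
    sample = hits[0]
    if _primer_mismatches(primer, read.seq[blen : blen + plen]) > p.max_primer_errors:
        return Reject("primer")
    trimmed = Read(
        id=read.id,
        seq=read.seq[blen + plen :],
        qual=read.qual[blen + plen :],
        sample=sample,
    )
    return sample, trimmed


def quality_filter(read: Read, p: QCParams = QCParams()):
    """Return ``None`` on pass, else ``Reject(reason)``.

    Reasons, checked in order: ``ambiguous`` (contains N), ``short``
    (length < min_len), ``min_quality``, ``avg_quality``, ``window_quality``
    (some window of ``window_len`` consecutive bases has mean < window_q).
    """
    if not p.allow_ambiguous and "N" in read.seq:
        return Reject("ambiguous")
    if len(read) < p.min_len:
        return Reject("short")
    if read.qual:
        if p.min_q and min(read.qual) < p.min_q:
            return Reject("min_quality")
        if p.avg_q and sum(read.qual) / len(read.qual) < p.avg_q:
            return Reject("avg_quality")
        if p.window_len and len(read.qual) >= p.window_len:
            w = p.window_len
            s = sum(read.qual[:w])
            if s / w < p.window_q:
                return Reject("window_quality")
            for i in range(w, len(read.qual)):
                s += read.qual[i] - read.qual[i - w]
                if s / w < p.window_q:
                    return Reject("window_quality")
    return None


def truncate(read: Read, L: int):
    """Keep the first ``L`` bases; shorter reads are rejected.

    Uniform length is required downstream: the clustering similarity is
    defined between equal-length sequences.
    """
    if len(read) < L:
        return Reject("short")
    return Read(id=read.id, seq=read.seq[:L], qual=read.qual[:L], sample=read.sample)


def dereplicate(reads: Iterable[tuple[str, Read | str]]) -> list[UniqueSeq]:
    """Collapse identical sequences into UniqueSeqs with per-sample counts.

    Output is sorted by descending total copy number, ties broken by
    sequence; the sum of totals equals the number of input reads.
    """
    table: dict[str, Counter] = defaultdict(Counter)
    for sample, read in reads:
        seq = read if isinstance(read, str) else read.seq
        table[seq][sample] += 1
    uniques = [UniqueSeq(seq=seq, counts=dict(c)) for seq, c in table.items()]
    uniques.sort(key=lambda u: (-u.total, u.seq))
    return uniques


def copy_number_filter(uniques: list[UniqueSeq], n: int) -> list[UniqueSeq]:
    """Keep a UniqueSeq iff its copy number in some sample is >= ``n``.

    The filter gates entry to clustering only; retained records keep all
    their per-sample counts, including sub-threshold ones.
    """
    if n < 1:
        raise ValueError("copy-number threshold must be >= 1")
    return [u for u in uniques if u.max_per_sample >= n]


def run_preprocess(
    reads: Iterable[Read],
    barcodes: BarcodeMap,
    primer: str,
    params: QCParams = QCParams(),
) -> tuple[list[UniqueSeq], dict[str, int], list[tuple[str, str, str]]]:
    """Full preprocessing: demultiplex, QC, truncate, dereplicate.

    Returns ``(uniques, stage_counts, rejections)`` where ``rejections`` is
    a list of ``(read_id, stage, reason)`` and ``stage_counts`` logs input,
    accepted and per-stage rejection tallies (accepted + rejected == input).
    """
    barcodes.check_separation(params.max_barcode_errors)
    accepted: list[tuple[str, Read]] = []
    rejections: list[tuple[str, str, str]] = []
    stats: Counter = Counter()
    for read in reads:
        stats["input"] += 1
        demux = demultiplex(read, barcodes, primer, params)
        if isinstance(demux, Reject):
            stats[f"reject_demux_{demux.reason}"] += 1
            rejections.append((read.id, "demultiplex", demux.reason))
            continue
        sample, trimmed = demux
        qc = quality_filter(trimmed, params)
        if isinstance(qc, Reject):
            stats[f"reject_qc_{qc.reason}"] += 1
            rejections.append((read.id, "quality", qc.reason))
            continue
        if params.truncate_len:
            trunc = truncate(trimmed, params.truncate_len)
            if isinstance(trunc, Reject):
                stats["reject_truncate_short"] += 1
                rejections.append((read.id, "truncate", trunc.reason))
                continue
            trimmed = trunc
        stats["accepted"] += 1
        accepted.append((sample, trimmed))
    uniques = dereplicate(accepted)
    return uniques, dict(stats), rejections
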