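"""Homopolymer-aware pairwise sequence alignment.

Pyrosequencing platforms such as Roche/454 call the length of a homopolymer
run (e.g. ``AAAA``) from a flow intensity and frequently get it wrong by one
base.  Treating the resulting alignment gap as a true indel distorts the
similarity between a read and the error-free sequence it derived from.  This
module aligns a query against a small sequence *graph* built from its
partner: every maximal homopolymer run of length >= ``min_hp_len`` gains skip
edges that allow up to ``max_hp_skip`` trailing bases of the run to be
omitted at zero cost.  Gap columns produced by those edges are tagged
``hp_gap`` and excluded from the similarity denominator, so two sequences
that differ only in homopolymer run lengths score as identical.

Skips model length uncertainty of a *shared* run, so a skip chain must be
embedded in matched context: it can only start after a match of the run
base and only end into another match (or the end of the alignment).  Even
so, a true single-base indel immediately next to a run is inherently
ambiguous — the model may prefer "substitution + run slip" when that scores
higher, which can lower the similarity by O(1/length) relative to the
plain alignment for such pairs.

The dynamic programme maximises the lexicographic objective
``(score, #match columns, -#counted columns)``.  The secondary terms make the
reported similarity deterministic and direction-independent under symmetric
scoring; with ``hp_model=False`` the result is a classical global
Needleman-Wunsch/Gotoh alignment with affine gaps (a gap of length *g* costs
``gap_open + g * gap_extend``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "AlignParams",
    "HPGraph",
    "AlignmentResult",
    "build_hp_graph",
    "align",
    "similarity",
    "hp_similarity",
    "MATCH",
    "MISMATCH",
    "GAP",
    "HP_GAP",
]

MATCH = "match"
MISMATCH = "mismatch"
GAP = "gap"
HP_GAP = "hp_gap"

# DP states: M=substitution, X=gap in b (consumes a), Y=gap in a (consumes b),
# HX=free homopolymer skip of a, HY=free homopolymer skip of b.
_M, _X, _Y, _HX, _HY = 0, 1, 2, 3, 4
_START = 9
# Preference order on ties: substitution, hp skips, gap-in-a, gap-in-b.
_PREF = (_M, _HX, _HY, _Y, _X)

# Key packing: key = score * _K_SCORE + n_match * _K_MATCH - n_counted.
# Exact in float64 for integer scores and sequences up to ~2000 bases.
_K_SCORE = float(1 << 25)
_K_MATCH = 4096.0
_NEG = -1.0e17


@dataclass(frozen=True)
class AlignParams:
    """Scoring and homopolymer-model parameters.

    The defaults (+1/-2, affine gap -3/-1) are conventional nucleotide
    scores; the paper-scale behaviour depends on the similarity threshold,
    not on these constants.  ``min_hp_len``/``max_hp_skip`` control which
    runs receive skip edges and how many trailing bases may be dropped.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -3.0
    gap_extend: float = -1.0
    min_hp_len: int = 3
    max_hp_skip: int = 1
    hp_model: bool = True

    def __post_init__(self) -> None:
        if not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.min_hp_len < 1 or self.max_hp_skip < 0:
            raise ValueError("min_hp_len >= 1 and max_hp_skip >= 0 required")


@dataclass
class HPGraph:
    """Linear sequence graph with homopolymer skip edges.

    ``skip_mask[i]`` is True when base ``i`` may be omitted for free because
    it is one of the trailing skippable bases of a qualifying run.  The
    linear path through all bases always spells the original sequence.
    """

    seq: str
    skip_mask: np.ndarray
    runs: list[tuple[int, int]] = field(default_factory=list)

    def spellings(self) -> set[str]:
        """All strings spelled by paths through the graph (small inputs)."""
        skippable = [i for i, m in enumerate(self.skip_mask) if m]
        out = set()
        for r in range(len(skippable) + 1):
            for drop in itertools.combinations(skippable, r):
                dropped = set(drop)
                out.add("".join(c for i, c in enumerate(self.seq) if i not in dropped))
        return out


def _maximal_runs(seq: str) -> list[tuple[int, int]]:
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        runs.append((i, j - i))
        i = j
    return runs


def build_hp_graph(seq: str, params: AlignParams = AlignParams()) -> HPGraph:
    """Build the homopolymer skip graph for ``seq``.

    With ``hp_model=False`` the graph is purely linear.  A run is never
    deleted entirely: at most ``run_length - 1`` bases are skippable.
    """
    if not seq:
        raise ValueError("cannot build a sequence graph for an empty sequence")
    mask = np.zeros(len(seq), dtype=np.bool_)
    qualifying = []
    if params.hp_model:
        for start, length in _maximal_runs(seq):
            if length >= params.min_hp_len:
                k = min(params.max_hp_skip, length - 1)
                mask[start + length - k : start + length] = True
                qualifying.append((start, length))
    return HPGraph(seq=seq, skip_mask=mask, runs=qualifying)


@dataclass
class AlignmentResult:
    """A pairwise alignment with per-column tags.

    ``columns[k]`` is one of ``match``/``mismatch``/``gap``/``hp_gap``.
    For free-end ("glocal") alignments ``a_start:a_end`` is the aligned
    window of ``a``; in global mode it spans all of ``a``.
    """

    aligned_a: str
    aligned_b: str
    score: float
    columns: list[str]
    a_start: int = 0
    a_end: int = 0

    @property
    def n_match(self) -> int:
        return self.columns.count(MATCH)

    @property
    def n_mismatch(self) -> int:
        return self.columns.count(MISMATCH)

    @property
    def n_hp_gap(self) -> int:
        return self.columns.count(HP_GAP)

    @property
    def n_counted(self) -> int:
        return len(self.columns) - self.n_hp_gap


@njit(cache=False, fastmath=False)
def _fill(ac, bc, hpa, hpb, sm, sx, go, ge, hp_on, free_a):  # pragma: no cover
    n = ac.size
    m = bc.size
    K = _K_SCORE
    KM = _K_MATCH
    key = np.full((5, n + 1, m + 1), _NEG)
    ptr = np.full((5, n + 1, m + 1), -1, dtype=np.int8)
    k0, k1, k2, k3, k4 = key[0], key[1], key[2], key[3], key[4]
    p0, p1, p2, p3, p4 = ptr[0], ptr[1], ptr[2], ptr[3], ptr[4]
    d_sub_eq = sm * K + KM - 1.0
    d_sub_ne = sx * K - 1.0
    d_open = (go + ge) * K - 1.0
    d_ext = ge * K - 1.0

    k0[0, 0] = 0.0
    p0[0, 0] = 9
    for i in range(1, n + 1):
        if free_a:
            k0[i, 0] = 0.0
            p0[i, 0] = 9
        else:
            if i == 1:
                k1[1, 0] = d_open
                p1[1, 0] = 0
            else:
                k1[i, 0] = k1[i - 1, 0] + d_ext
                p1[i, 0] = 1
    for j in range(1, m + 1):
        if j == 1:
            k2[0, 1] = d_open
            p2[0, 1] = 0
        else:
            k2[0, j] = k2[0, j - 1] + d_ext
            p2[0, j] = 2

    for i in range(1, n + 1):
        ha = hp_on and hpa[i - 1]
        a_i = ac[i - 1]
        for j in range(1, m + 1):
            eq = a_i == bc[j - 1]
            # substitution into M, preference order M, HX, HY, Y, X; a skip
            # chain may only exit into a match (shared-run context)
            bk = k0[i - 1, j - 1]
            bs = 0
            if eq:
                v = k3[i - 1, j - 1]
                if v > bk:
                    bk = v
                    bs = 3
                v = k4[i - 1, j - 1]
                if v > bk:
                    bk = v
                    bs = 4
            v = k2[i - 1, j - 1]
            if v > bk:
                bk = v
                bs = 2
            v = k1[i - 1, j - 1]
            if v > bk:
                bk = v
                bs = 1
            k0[i, j] = bk + (d_sub_eq if eq else d_sub_ne)
            p0[i, j] = bs

            # X: penalised gap in b (consumes a)
            bk = k0[i - 1, j] + d_open
            bs = 0
            v = k2[i - 1, j] + d_open
            if v > bk:
                bk = v
                bs = 2
            v = k1[i - 1, j] + d_ext
            if v > bk:
                bk = v
                bs = 1
            k1[i, j] = bk
            p1[i, j] = bs

            # Y: penalised gap in a (consumes b)
            bk = k0[i, j - 1] + d_open
            bs = 0
            v = k2[i, j - 1] + d_ext
            if v > bk:
                bk = v
                bs = 2
            v = k1[i, j - 1] + d_open
            if v > bk:
                bk = v
                bs = 1
            k2[i, j] = bk
            p2[i, j] = bs

            # A skip models length uncertainty of a *shared* run: the first
            # skipped base must follow a match of that same run base, so a
            # skip chain roots in an M column matching the run; HX/HY only
            # extend an existing chain.
            if ha and eq:
                bk = k0[i - 1, j]
                bs = 0
                v = k3[i - 1, j]
                if v > bk:
                    bk = v
                    bs = 3
                k3[i, j] = bk
                p3[i, j] = bs
            elif ha:
                k3[i, j] = k3[i - 1, j]
                p3[i, j] = 3
            if hp_on and hpb[j - 1] and eq:
                bk = k0[i, j - 1]
                bs = 0
                v = k4[i, j - 1]
                if v > bk:
                    bk = v
                    bs = 4
                k4[i, j] = bk
                p4[i, j] = bs
            elif hp_on and hpb[j - 1]:
                k4[i, j] = k4[i, j - 1]
                p4[i, j] = 4
    return key, ptr


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _recompute_score(aligned_a: str, aligned_b: str, tags: list[str], p: AlignParams) -> float:
    score = 0.0
    prev_gap_in = None  # "a" or "b" when previous column was a penalised gap
    for ca, cb, tag in zip(aligned_a, aligned_b, tags):
        if tag == MATCH:
            score += p.match
            prev_gap_in = None
        elif tag == MISMATCH:
            score += p.mismatch
            prev_gap_in = None
        elif tag == HP_GAP:
            prev_gap_in = None
        else:  # penalised gap
            where = "a" if ca == "-" else "b"
            score += p.gap_extend
            if prev_gap_in != where:
                score += p.gap_open
            prev_gap_in = where
    return score


def align(
    a: str,
    b: str,
    params: AlignParams = AlignParams(),
    free_ends_a: bool = False,
) -> AlignmentResult:
    """Globally align ``b`` against the homopolymer graph of ``a``.

    With ``free_ends_a=True`` leading/trailing bases of ``a`` are skipped for
    free ("glocal": the query ``b`` is aligned end-to-end against a window of
    ``a``, as when a short amplicon is matched to a full-length gene).  The
    free flanks are not emitted as columns.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    ga = build_hp_graph(a, params)
    gb = build_hp_graph(b, params)
    key, ptr = _fill(
        _encode(a),
        _encode(b),
        ga.skip_mask,
        gb.skip_mask,
        float(params.match),
        float(params.mismatch),
        float(params.gap_open),
        float(params.gap_extend),
        params.hp_model,
        free_ends_a,
    )
    n, m = len(a), len(b)
    if free_ends_a:
        best = -np.inf
        ei, es = n, _M
        for i in range(n + 1):
            for s in _PREF:
                if key[s, i, m] > best:
                    best = key[s, i, m]
                    ei, es = i, s
    else:
        best = -np.inf
        ei, es = n, _M
        for s in _PREF:
            if key[s, n, m] > best:
                best = key[s, n, m]
                es = s

    cols_a: list[str] = []
    cols_b: list[str] = []
    tags: list[str] = []
    i, j, s = ei, m, es
    while ptr[s, i, j] != _START:
        prev = int(ptr[s, i, j])
        if s == _M:
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            tags.append(MATCH if a[i - 1] == b[j - 1] else MISMATCH)
            i, j = i - 1, j - 1
        elif s == _X:
            cols_a.append(a[i - 1])
            cols_b.append("-")
            tags.append(GAP)
            i -= 1
        elif s == _HX:
            cols_a.append(a[i - 1])
            cols_b.append("-")
            tags.append(HP_GAP)
            i -= 1
        elif s == _Y:
            cols_a.append("-")
            cols_b.append(b[j - 1])
            tags.append(GAP)
            j -= 1
        else:  # _HY
            cols_a.append("-")
            cols_b.append(b[j - 1])
            tags.append(HP_GAP)
            j -= 1
        s = prev
    cols_a.reverse()
    cols_b.reverse()
    tags.reverse()
    aligned_a = "".join(cols_a)
    aligned_b = "".join(cols_b)
    score = _recompute_score(aligned_a, aligned_b, tags, params)
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        columns=tags,
        a_start=i,
        a_end=ei,
    )


def similarity(result: AlignmentResult) -> float:
    """Fraction of matching columns among counted (non-``hp_gap``) columns."""
    denom = result.n_counted
    if denom == 0:
        raise ValueError("similarity undefined: all alignment columns are hp_gap")
    return result.n_match / denom


def hp_similarity(a: str, b: str, params: AlignParams = AlignParams(), free_ends_a: bool = False) -> float:
    """Convenience wrapper: align then compute similarity."""
    return similarity(align(a, b, params, free_ends_a=free_ends_a))
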