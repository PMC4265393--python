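"""Independent oracles for the test suite.

Deliberately naive implementations, structured differently from the
package code so they can serve as cross-checks: a memoized recursive
Gotoh (affine-gap Needleman-Wunsch) global aligner maximising the
lexicographic objective (score, #matches, -#columns) — the same
similarity tie-break the package guarantees, arrived at independently.
"""

from __future__ import annotations

import functools


def gotoh_oracle(a: str, b: str, match=1.0, mismatch=-2.0, gap_open=-3.0, gap_extend=-1.0):
    """Optimal (score, n_match, n_columns) of a global affine-gap alignment.

    A gap of length g costs ``gap_open + g * gap_extend``.  The recursion
    keys on the last move ("S" start, "M" substitution, "X" gap in b,
    "Y" gap in a) so gap opening is charged exactly once per gap run.
    """

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int, last: str):
        if i == 0 and j == 0:
            return (0.0, 0, 0) if last == "S" else None
        if last == "S":
            return None
        if last == "M":
            if i == 0 or j == 0:
                return None
            prevs = [p for p in (best(i - 1, j - 1, l) for l in "SMXY") if p is not None]
            if not prevs:
                return None
            s, nm, nc = max(prevs)
            hit = a[i - 1] == b[j - 1]
            return (s + (match if hit else mismatch), nm + (1 if hit else 0), nc - 1)
        if last == "X":
            if i == 0:
                return None
            cands = []
            for l in "SMXY":
                p = best(i - 1, j, l)
                if p is not None:
                    cost = gap_extend if l == "X" else gap_open + gap_extend
                    cands.append((p[0] + cost, p[1], p[2] - 1))
            return max(cands) if cands else None
        # last == "Y"
        if j == 0:
            return None
        cands = []
        for l in "SMXY":
            p = best(i, j - 1, l)
            if p is not None:
                cost = gap_extend if l == "Y" else gap_open + gap_extend
                cands.append((p[0] + cost, p[1], p[2] - 1))
        return max(cands) if cands else None

    import sys

    sys.setrecursionlimit(10000)
    finals = [p for p in (best(len(a), len(b), l) for l in "SMXY") if p is not None]
    score, nm, neg_cols = max(finals)
    return score, nm, -neg_cols


def oracle_score_and_similarity(a: str, b: str, **scores):
    score, nm, ncols = gotoh_oracle(a, b, **scores)
    return score, nm / ncols
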