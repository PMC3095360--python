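"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming kernels: the
global oracle enumerates the alignment space recursively with gap-state
tracking, the local oracle maximises the global oracle over all substring
pairs, and the LCS oracle enumerates subsequences.  They are exponential
and only usable on tiny inputs, which is the point.
"""

from __future__ import annotations

import itertools
from functools import lru_cache


def brute_force_global_score(a: str, b: str, match: float = 5.0,
                             mismatch: float = -4.0, gap_open: float = 10.0,
                             gap_extend: float = 0.5) -> float:
    """Optimal global affine-gap score by exhaustive recursion.

    Gap cost is open + (len-1)*extend; N never matches.
    """

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        # state: 0 = no open gap, 1 = gap in b open, 2 = gap in a open
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            s = match if (a[i] == b[j] and a[i] != "N") else mismatch
            best = max(best, s + rec(i + 1, j + 1, 0))
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open
            best = max(best, -cost + rec(i + 1, j, 1))
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open
            best = max(best, -cost + rec(i, j + 1, 2))
        return best

    score = rec(0, 0, 0)
    rec.cache_clear()
    return score


def brute_force_local_score(a: str, b: str, **kw) -> float:
    """Optimal local score: best global score over all substring pairs,
    floored at 0 (the empty alignment)."""
    best = 0.0
    for i0 in range(len(a) + 1):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b) + 1):
                for j1 in range(j0 + 1, len(b) + 1):
                    best = max(best, brute_force_global_score(a[i0:i1], b[j0:j1], **kw))
    return best


def brute_force_lis(seq: list[int]) -> int:
    """Longest strictly increasing subsequence by enumeration (n <= ~12)."""
    best = 0
    for r in range(len(seq), 0, -1):
        for combo in itertools.combinations(seq, r):
            if all(x < y for x, y in zip(combo, combo[1:])):
                return r
    return best


def brute_force_chain(genes_a: list[str], genes_b: list[str]) -> int:
    """Longest order-preserving matching between two labelled gene lists
    (labels must agree), by enumeration over index subsets (<= 6 genes)."""
    best = 0
    n, m = len(genes_a), len(genes_b)
    for r in range(min(n, m), 0, -1):
        for ia in itertools.combinations(range(n), r):
            for ib in itertools.combinations(range(m), r):
                if all(genes_a[i] == genes_b[j] for i, j in zip(ia, ib)):
                    return r
    return best


def base_by_base_coverage(spans: list[tuple[int, int]], lo: int, hi: int) -> int:
    """Bases of [lo, hi] covered by any (clipped) span — counting loop."""
    covered = 0
    for pos in range(lo, hi + 1):
        if any(s <= pos <= e for s, e in spans):
            covered += 1
    return covered
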