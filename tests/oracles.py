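"""Independent oracles used by the test-suite.

These deliberately use different formulations from the package code: the
folding oracle enumerates structures by choosing a partner for the first
position; the alignment oracle maximizes over explicit gap lengths instead
of affine gap states; the sign-test oracle enumerates all 2^n equally
likely down/up outcomes with exact fractions.
"""

from fractions import Fraction
from functools import lru_cache
from math import comb

from mirsort.sequence import can_pair


def max_pairs_enumeration(seq: str, min_loop: int = 3) -> int:
    """Maximum base-pair count by exhaustive (memoized) structure
    enumeration: position i is unpaired, or pairs some k > i + min_loop."""
    n = len(seq)

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        b = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if can_pair(seq[i], seq[k]):
                b = max(b, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return b

    return best(0, n - 1) if n else 0


def _gap_cost(g: int, gap_open: float, gap_extend: float) -> float:
    return gap_open + (g - 1) * gap_extend


def sw_score_oracle(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 15.0,
    gap_extend: float = 2.0,
) -> float:
    """Best local-alignment score, maximizing over explicit gap lengths.

    N[i][j] is the best score of an alignment whose last column aligns
    a[i-1] with b[j-1]; alignments neither start nor end with a gap (such
    variants never score higher under positive gap costs).
    """
    n, m = len(a), len(b)
    N = [[0.0] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            prev = 0.0
            if i > 1 and j > 1:
                prev = max(prev, N[i - 1][j - 1])
                for g in range(1, i - 1):
                    prev = max(prev, N[i - 1 - g][j - 1] - _gap_cost(g, gap_open, gap_extend))
                for g in range(1, j - 1):
                    prev = max(prev, N[i - 1][j - 1 - g] - _gap_cost(g, gap_open, gap_extend))
            N[i][j] = prev + s
            best = max(best, N[i][j])
    return best


def sw_score_exhaustive(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 15.0,
    gap_extend: float = 2.0,
) -> float:
    """Truly exhaustive local-alignment enumeration for tiny strings:
    recursively extends alignments column by column from every start pair."""
    best = [0.0]

    def extend(i: int, j: int, score: float, last: str) -> None:
        # score so far for an alignment ending aligned at (i-1, j-1) or in a gap
        if last == "M":
            best[0] = max(best[0], score)
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            extend(i + 1, j + 1, score + s, "M")
        if i < len(a) and last != "B":  # gap in b
            cost = gap_extend if last == "A" else gap_open
            extend(i + 1, j, score - cost, "A")
        if j < len(b) and last != "A":  # gap in a
            cost = gap_extend if last == "B" else gap_open
            extend(i, j + 1, score - cost, "B")

    for i in range(len(a)):
        for j in range(len(b)):
            extend(i, j, 0.0, "S")
    return best[0]


def binomial_direction_enumeration(
    n_down: int, n_up: int, tail: str = "two_tailed"
) -> float | None:
    """Exact sign-test p by enumeration over all 2^n down/up outcomes."""
    n = n_down + n_up
    if n == 0:
        return None
    k = max(n_down, n_up)
    if tail == "one_tailed":
        hits = sum(comb(n, d) for d in range(n + 1) if d >= k)
    else:
        hits = sum(comb(n, d) for d in range(n + 1) if max(d, n - d) >= k)
    return float(Fraction(hits, 2**n))
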