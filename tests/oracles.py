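"""Independent brute-force oracles used to cross-check the package's
statistics. These deliberately avoid the code paths they validate."""

from __future__ import annotations

import math


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by exhaustive tail summation with exact
    integer weights (all tables sharing the observed margins)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = {
        x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)
    }
    w_obs = weights[a]
    num = sum(w for w in weights.values() if w <= w_obs)
    return num / math.comb(n, c1)


def hypergeom_upper_tail(k: int, universe: int, n_success: int, n_draw: int) -> float:
    """P(X >= k) for a hypergeometric draw, by direct summation."""
    denom = math.comb(universe, n_draw)
    hi = min(n_success, n_draw)
    return sum(
        math.comb(n_success, x) * math.comb(universe - n_success, n_draw - x)
        for x in range(k, hi + 1)
    ) / denom


def gotoh_global_score(
    seq1: str, seq2: str, matrix, gap_open: float = 11.0, gap_extend: float = 1.0
) -> float:
    """Global affine-gap alignment score by dynamic programming.

    A gap of length k costs gap_open + (k-1)*gap_extend; end gaps are
    penalized. Three-state Gotoh recursion with all state transitions
    allowed.
    """
    n, m = len(seq1), len(seq2)
    neg = float("-inf")
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in seq2
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in seq1
    M[0][0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = float(matrix[seq1[i - 1], seq2[j - 1]])
                M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            if i > 0:
                X[i][j] = max(
                    M[i - 1][j] - gap_open,
                    X[i - 1][j] - gap_extend,
                    Y[i - 1][j] - gap_open,
                )
            if j > 0:
                Y[i][j] = max(
                    M[i][j - 1] - gap_open,
                    Y[i][j - 1] - gap_extend,
                    X[i][j - 1] - gap_open,
                )
    return max(M[n][m], X[n][m], Y[n][m])


def chi2_statistic(observed, expected) -> float:
    """Plain chi-square statistic."""
    return sum(
        (o - e) ** 2 / e for o, e in zip(observed, expected) if e > 0
    )


def enumerate_compatible_offsets(left, right) -> list[int]:
    """All offsets of `right` relative to `left` (tuples of residue-class
    frozensets or None for wildcard) with >=1 overlapping position and no
    empty intersection — re-derived independently of the package."""
    out = []
    for offset in range(-len(right) + 1, len(left)):
        overlap = [
            m for m in range(min(0, offset), max(len(left), offset + len(right)))
            if 0 <= m < len(left) and 0 <= m - offset < len(right)
        ]
        if not overlap:
            continue
        ok = True
        for m in overlap:
            lc, rc = left[m], right[m - offset]
            if lc is not None and rc is not None and not (lc & rc):
                ok = False
                break
        if ok:
            out.append(offset)
    return out
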