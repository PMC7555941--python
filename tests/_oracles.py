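"""Independent brute-force oracles used by the test suite.

These are deliberately literal (triple-loop) implementations of the
squared centered and wrap-around L2-discrepancies, written directly from
the double-sum definitions, so they share no code with the package's
vectorized evaluators.
"""

from __future__ import annotations

import itertools
import math


def cd2_direct(points: list[list[float]]) -> float:
    n = len(points)
    s = len(points[0])
    term1 = (13.0 / 12.0) ** s
    term2 = 0.0
    for i in range(n):
        prod = 1.0
        for k in range(s):
            a = abs(points[i][k] - 0.5)
            prod *= 1.0 + 0.5 * a - 0.5 * a * a
        term2 += prod
    term3 = 0.0
    for i in range(n):
        for j in range(n):
            prod = 1.0
            for k in range(s):
                ai = abs(points[i][k] - 0.5)
                aj = abs(points[j][k] - 0.5)
                d = abs(points[i][k] - points[j][k])
                prod *= 1.0 + 0.5 * ai + 0.5 * aj - 0.5 * d
            term3 += prod
    return term1 - (2.0 / n) * term2 + term3 / (n * n)


def wd2_direct(points: list[list[float]]) -> float:
    n = len(points)
    s = len(points[0])
    total = 0.0
    for i in range(n):
        for j in range(n):
            prod = 1.0
            for k in range(s):
                d = abs(points[i][k] - points[j][k])
                prod *= 1.5 - d + d * d
            total += prod
    return -((4.0 / 3.0) ** s) + total / (n * n)


def midpoints(entries) -> list[list[float]]:
    n = len(entries)
    return [[(u - 0.5) / n for u in row] for row in entries]


def exhaustive_min_cd2(n: int) -> float:
    """Global minimum cd2 over all n x 2 U-type tables.

    Row reordering leaves cd2 unchanged, so fixing the first column to
    the identity and enumerating all n! second columns covers every
    table up to a row permutation.
    """
    best = math.inf
    for perm in itertools.permutations(range(1, n + 1)):
        entries = [[i + 1, perm[i]] for i in range(n)]
        best = min(best, cd2_direct(midpoints(entries)))
    return best
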