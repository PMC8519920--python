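"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive (quadratic/cubic, pure Python) and share no
code with the package: an explicit Gotoh dynamic programme for semi-global
affine-gap alignment, a substring enumerator for longest common substrings,
a bisection solver for the two-state duplex equilibrium, the textbook edit
distance, and direct formula evaluations of the classification metrics.
"""

from __future__ import annotations

import itertools
import math

NEG = float("-inf")


def semi_global_score(a: str, b: str, match: float = 5.0,
                      mismatch: float = -4.0, gap_open: float = 5.0,
                      gap_extend: float = 2.0) -> float:
    """Affine-gap semi-global alignment score by explicit 3-state DP.

    End gaps on either sequence are free; an internal gap of length L costs
    ``gap_open + (L - 1) * gap_extend``.
    """
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends in a match/mismatch
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends with a gapped in
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends with b gapped in
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # leading end gap, free
    for j in range(1, m + 1):
        Y[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open,
                          X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open,
                          Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open)
    best = NEG
    for i in range(n + 1):
        best = max(best, M[i][m], X[i][m], Y[i][m])
    for j in range(m + 1):
        best = max(best, M[n][j], X[n][j], Y[n][j])
    return best


def lcs_bruteforce(a: str, b: str) -> int:
    """Longest common substring by enumerating every substring of ``a``."""
    best = 0
    for i in range(len(a)):
        for j in range(i + best + 1, len(a) + 1):
            if a[i:j] in b:
                best = j - i
            else:
                break
    return best


def bisect_duplex(K: float, a0: float, b0: float,
                  tol: float = 1e-16) -> float:
    """Duplex concentration solving K (a0 - x)(b0 - x) = x by bisection."""
    lo, hi = 0.0, min(a0, b0)

    def f(x: float) -> float:
        return K * (a0 - x) * (b0 - x) - x

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def bisect_homodimer(K: float, a0: float, tol: float = 1e-16) -> float:
    """Duplex concentration solving K (a0 - 2x)^2 = x by bisection."""
    lo, hi = 0.0, a0 / 2.0

    def f(x: float) -> float:
        return K * (a0 - 2 * x) ** 2 - x

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance by the standard DP."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def enumerate_run_constrained(length: int, max_run: int = 2):
    """All A/C/G/T strings of ``length`` with no homopolymer run > max_run."""
    for combo in itertools.product("ACGT", repeat=length):
        run = 1
        ok = True
        for x, y in zip(combo, combo[1:]):
            run = run + 1 if x == y else 1
            if run > max_run:
                ok = False
                break
        if ok:
            yield "".join(combo)


def mcc_formula(tp: int, fp: int, fn: int, tn: int) -> float:
    num = tp * tn - fp * fn
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return num / den if den else 0.0


def auroc_pairwise(truth, scores) -> float:
    """AUROC as the tie-corrected probability that a positive outscores a
    negative, by direct O(n^2) pair counting."""
    pos = [s for t, s in zip(truth, scores) if t == 1]
    neg = [s for t, s in zip(truth, scores) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
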