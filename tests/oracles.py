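"""Independent oracles used by the tests.

These are deliberately naive implementations kept separate from the package:
a brute-force global-alignment enumerator, an independently written plain
dynamic program, and a grid-search maximum-likelihood probit fitter. They
share no code with the implementation they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats

from resistkit.align import ScoringScheme, default_scheme
from resistkit.core import ALPHABET

_IDX = {c: i for i, c in enumerate(ALPHABET)}


def score_alignment(a: str, b: str, moves: str, scheme: ScoringScheme) -> int:
    """Score one alignment given as a move string: D=diagonal, A=consume a
    (gap in b), B=consume b (gap in a). Gap runs cost open + extend*(L-1)."""
    i = j = 0
    s = 0
    prev = ""
    for mv in moves:
        if mv == "D":
            s += int(scheme.matrix[_IDX[a[i]], _IDX[b[j]]])
            i += 1
            j += 1
        elif mv == "A":
            s -= scheme.gap_extend if prev == "A" else scheme.gap_open
            i += 1
        else:
            s -= scheme.gap_extend if prev == "B" else scheme.gap_open
            j += 1
        prev = mv
    assert i == len(a) and j == len(b)
    return s


def _enumerate_moves(na: int, nb: int):
    if na == 0 and nb == 0:
        yield ""
        return
    if na > 0:
        for rest in _enumerate_moves(na - 1, nb):
            yield "A" + rest
    if nb > 0:
        for rest in _enumerate_moves(na, nb - 1):
            yield "B" + rest
    if na > 0 and nb > 0:
        for rest in _enumerate_moves(na - 1, nb - 1):
            yield "D" + rest


def brute_force_score(a: str, b: str, scheme: ScoringScheme | None = None) -> int:
    """Exhaustive maximum over every global alignment (small inputs only)."""
    scheme = scheme or default_scheme()
    if not a and not b:
        return 0
    return max(
        score_alignment(a, b, moves, scheme) for moves in _enumerate_moves(len(a), len(b))
    )


def plain_dp_score(a: str, b: str, scheme: ScoringScheme | None = None) -> int:
    """Plain-Python affine-gap DP, written independently of the package's
    aligner (different state layout, no traceback, no numba)."""
    scheme = scheme or default_scheme()
    o, e = scheme.gap_open, scheme.gap_extend
    S = scheme.matrix
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        if n == m == 0:
            return 0
        L = max(n, m)
        return -(o + e * (L - 1))
    NEG = -(10**9)
    ea = [_IDX[c] for c in a]
    eb = [_IDX[c] for c in b]
    # three layers: best ending in match, in gap-in-b, in gap-in-a
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = -(o + e * (i - 1))
    for j in range(1, m + 1):
        Y[0][j] = -(o + e * (j - 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = int(S[ea[i - 1], eb[j - 1]])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sub
            X[i][j] = max(M[i - 1][j] - o, X[i - 1][j] - e, Y[i - 1][j] - o)
            Y[i][j] = max(M[i][j - 1] - o, X[i][j - 1] - o, Y[i][j - 1] - e)
    return max(M[n][m], X[n][m], Y[n][m])


def grid_ml_probit(doses, n, dead, span=16.0, steps=81, rounds=5):
    """Grid-search maximum-likelihood probit fit on log10 dose.

    Coarse-to-fine search over (alpha, beta); returns (alpha, beta).
    ``dead`` may be fractional (Abbott-adjusted counts)."""
    x = np.log10(np.asarray(doses, dtype=float))
    n = np.asarray(n, dtype=float)
    dead = np.asarray(dead, dtype=float)

    def loglik(alpha, beta):
        p = stats.norm.cdf(alpha + beta * x)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(np.sum(dead * np.log(p) + (n - dead) * np.log(1 - p)))

    a0, b0, ra, rb = 0.0, 1.0, span, span
    for _ in range(rounds):
        alphas = np.linspace(a0 - ra, a0 + ra, steps)
        betas = np.linspace(b0 - rb, b0 + rb, steps)
        best = (-math.inf, a0, b0)
        for al in alphas:
            for be in betas:
                ll = loglik(al, be)
                if ll > best[0]:
                    best = (ll, al, be)
        _, a0, b0 = best
        ra /= 10.0
        rb /= 10.0
    return a0, b0


def fieller_bounds_by_grid(check, lo, hi, n=200001):
    """Min/max of a dense grid of points satisfying ``check`` (the Fieller
    defining inequality); returns (None, None) if nothing satisfies it."""
    grid = np.linspace(lo, hi, n)
    mask = check(grid)
    if not mask.any():
        return None, None
    sel = grid[mask]
    return float(sel.min()), float(sel.max())
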