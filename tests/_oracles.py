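"""Independent brute-force oracles used by the tests.

Deliberately naive implementations (explicit template extraction, exhaustive
pair enumeration, hand-written formulas) kept separate from the package so
they cannot share code with the paths they check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps


def sampen_bruteforce(y, m: int, r: float) -> float:
    """Sample entropy by explicit template-pair enumeration.

    Templates i = 1..L-m (those extendable to m+1); unordered pairs i < j;
    strict Chebyshev matches d < r; NaN when either count is zero.
    """
    y = list(map(float, y))
    L = len(y)
    nt = L - m
    B = 0
    A = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            dm = max(abs(y[i + k] - y[j + k]) for k in range(m))
            if dm < r:
                B += 1
            dm1 = max(dm, abs(y[i + m] - y[j + m]))
            if dm1 < r:
                A += 1
    if A == 0 or B == 0:
        return float("nan")
    return -math.log(A / B)


def coarse_bruteforce(x, tau: int) -> list[float]:
    """Block means by explicit slicing."""
    x = list(map(float, x))
    out = []
    j = 0
    while (j + 1) * tau <= len(x):
        block = x[j * tau : (j + 1) * tau]
        out.append(sum(block) / tau)
        j += 1
    return out


def auc_bruteforce(scores0, scores1) -> float:
    """AUC by exhaustive pair counting: wins + half-ties over all pairs."""
    wins = 0.0
    for a in scores0:
        for b in scores1:
            if b > a:
                wins += 1.0
            elif b == a:
                wins += 0.5
    return wins / (len(scores0) * len(scores1))


def welch_bruteforce(a, b) -> tuple[float, float]:
    """Welch t and two-sided p from the textbook formulas.

    Only the t CDF comes from scipy (a distribution function, not a test).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, p
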