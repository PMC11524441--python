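"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a statistic by the most literal route available —
exact rational enumeration, explicit loops, textbook formulas — sharing no
code path with the implementation it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction


def fisher_oracle(a: int, b: int, c: int, d: int, alternative: str = "two-sided") -> float:
    """Fisher exact p by full enumeration in exact rational arithmetic.

    Enumerates every table with the observed margins; point probabilities
    are integer weights C(r1,k)*C(r2,c1-k) over the common denominator
    C(n,c1).  The two-sided rule includes tables whose weight does not
    exceed the observed weight times (1 + 1e-7), evaluated exactly as
    w * 10^7 <= w_obs * (10^7 + 1).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    denom = math.comb(n, c1)
    w_obs = weights[a]
    if alternative == "two-sided":
        total = sum(w for w in weights.values() if w * 10**7 <= w_obs * (10**7 + 1))
    elif alternative == "greater":
        total = sum(w for k, w in weights.items() if k >= a)
    elif alternative == "less":
        total = sum(w for k, w in weights.items() if k <= a)
    else:
        raise ValueError(alternative)
    return float(min(Fraction(total, denom), Fraction(1)))


def cosine_oracle(u: dict, v: dict) -> tuple[float, int]:
    """Cosine similarity by an explicit loop over shared keys."""
    shared = sorted(set(u) & set(v))
    dot = su = sv = 0.0
    for g in shared:
        dot += u[g] * v[g]
        su += u[g] ** 2
        sv += v[g] ** 2
    return dot / math.sqrt(su * sv), len(shared)


def _avg_ranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # 1-based average rank of the tie block
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    """Spearman rho as the Pearson correlation of average ranks."""
    rx, ry = _avg_ranks(list(x)), _avg_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)


def bh_oracle(pvalues) -> list[float]:
    """Benjamini–Hochberg adjusted p-values by the literal step-up recursion."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adj = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * n / rank)
        adj[i] = running
    return adj


def student_t_oracle(x, y) -> tuple[float, float]:
    """Pooled-variance t statistic and df from the textbook closed form."""
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    sx2 = sum((v - mx) ** 2 for v in x) / (nx - 1)
    sy2 = sum((v - my) ** 2 for v in y) / (ny - 1)
    sp2 = ((nx - 1) * sx2 + (ny - 1) * sy2) / (nx + ny - 2)
    t = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    return t, float(nx + ny - 2)


def welch_t_oracle(x, y) -> tuple[float, float]:
    """Welch t statistic and Welch–Satterthwaite df from the closed form."""
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    sx2 = sum((v - mx) ** 2 for v in x) / (nx - 1)
    sy2 = sum((v - my) ** 2 for v in y) / (ny - 1)
    vx, vy = sx2 / nx, sy2 / ny
    t = (mx - my) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (nx - 1) + vy**2 / (ny - 1))
    return t, df
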