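"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the package's own code paths: correlations by a
double loop over the textbook formula, hypergeometric tails by exact
rational PMF summation, Student t from first principles, and BH by the
literal step-up definition.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy import stats


def corr_brute(x: np.ndarray) -> np.ndarray:
    """Product-moment correlation of rows by an explicit double loop."""
    n = x.shape[0]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            a = x[i] - x[i].mean()
            b = x[j] - x[j].mean()
            out[i, j] = (a * b).sum() / math.sqrt((a * a).sum() * (b * b).sum())
    return out


def hypergeom_upper_tail(k: int, M: int, K: int, N: int) -> float:
    """P(X >= k) for drawing N from M with K successes, by exact enumeration."""
    total = Fraction(0)
    denom = math.comb(M, N)
    for x in range(k, min(K, N) + 1):
        total += Fraction(math.comb(K, x) * math.comb(M - K, N - x), denom)
    return float(total)


def student_t_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample t statistic and two-sided p, from scratch."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va = sum((v - a.mean()) ** 2 for v in a) / (na - 1)
    vb = sum((v - b.mean()) ** 2 for v in b) / (nb - 1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    t = (b.mean() - a.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, 2.0 * stats.t.sf(abs(t), df)


def bh_stepup(p: list[float]) -> list[float]:
    """Textbook BH step-up: sort, scale by m/rank, enforce monotonicity."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = min(val, 1.0)
        prev = q[i]
    return q


def ddct_spreadsheet(rows: list[dict], calibrator: str) -> dict[str, float]:
    """Row-by-row delta-delta-Ct as one would compute in a spreadsheet."""
    dct = {r["sample_id"]: r["ct_target"] - r["ct_ref"] for r in rows}
    cal = dct[calibrator]
    return {s: 2.0 ** (-(d - cal)) for s, d in dct.items()}
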