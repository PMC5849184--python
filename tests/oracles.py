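"""Independent oracles used by the test suite.

Deliberately naive implementations — exact rational enumeration, double
loops, literal formula transcriptions — sharing no code with the package
so they can serve as ground truth for the fast implementations.
"""

from __future__ import annotations

import math
from fractions import Fraction

SLACK = Fraction(1, 10**7)  # relative slack for minimum-likelihood ties


def hypergeom_pmf_exact(N: int, K: int, n: int) -> dict[int, Fraction]:
    """Exact hypergeometric pmf over the full support, as Fractions."""
    lo, hi = max(0, n - (N - K)), min(K, n)
    denom = math.comb(N, n)
    return {
        k: Fraction(math.comb(K, k) * math.comb(N - K, n - k), denom)
        for k in range(lo, hi + 1)
    }


def hypergeom_upper_tail_oracle(k: int, K: int, n: int, N: int) -> Fraction:
    pmf = hypergeom_pmf_exact(N, K, n)
    return sum((p for kk, p in pmf.items() if kk >= k), Fraction(0)) if k > 0 \
        else Fraction(1)


import functools


@functools.lru_cache(maxsize=200_000)
def _margin_pmf(N: int, r1: int, c1: int) -> dict[int, Fraction]:
    denom = math.comb(N, c1)
    return {
        k: Fraction(math.comb(r1, k) * math.comb(N - r1, c1 - k), denom)
        for k in range(max(0, c1 - (N - r1)), min(r1, c1) + 1)
    }


def fisher_oracle(a: int, b: int, c: int, d: int, sided: str) -> Fraction:
    """Enumeration over all tables with the observed margins."""
    N = a + b + c + d
    r1, c1 = a + b, a + c
    pmf = _margin_pmf(N, r1, c1)
    obs = pmf[a]
    if sided == "greater":
        total = sum(p for k, p in pmf.items() if k >= a)
    elif sided == "less":
        total = sum(p for k, p in pmf.items() if k <= a)
    else:  # minimum-likelihood two-sided with relative slack
        cut = obs * (1 + SLACK)
        total = sum(p for p in pmf.values() if p <= cut)
    return min(total, Fraction(1))


def binom_sign_oracle(k: int, n: int, p0: float) -> Fraction:
    """Minimum-likelihood two-sided binomial test by full enumeration."""
    q0 = Fraction(p0)
    pmf = [
        math.comb(n, i) * q0**i * (1 - q0) ** (n - i) for i in range(n + 1)
    ]
    cut = pmf[k] * (1 + SLACK)
    return min(sum(p for p in pmf if p <= cut), Fraction(1))


def bh_oracle(pvals) -> list[float]:
    """Definitional BH: q_(i) = min_{j>=i} p_(j)*m/j, via a double loop."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    for pos, idx in enumerate(order):
        best = math.inf
        for j in range(pos, m):
            best = min(best, pvals[order[j]] * m / (j + 1))
        q[idx] = min(best, 1.0)
    return q


def t_tail_by_quadrature(t: float, df: int) -> float:
    """Two-sided Student-t tail via numerical integration of the pdf."""
    from scipy.integrate import quad

    c = math.exp(
        math.lgamma((df + 1) / 2)
        - math.lgamma(df / 2)
        - 0.5 * math.log(df * math.pi)
    )

    def pdf(x):
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    upper, _ = quad(pdf, abs(t), math.inf)
    return 2 * upper


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_scan(weights, seq: str, threshold: float):
    """Score every window on both strands with plain Python loops.

    ``weights`` is a 4xL nested list (rows A,C,G,T).  Returns tuples
    (offset, strand, score) for windows at or above threshold; windows
    containing N are skipped.
    """
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(weights[0])
    hits = []
    for off in range(len(seq) - L + 1):
        window = seq[off : off + L]
        if "N" in window:
            continue
        fwd = sum(weights[idx[base]][j] for j, base in enumerate(window))
        rc = "".join(_COMP[b] for b in reversed(window))
        rev = sum(weights[idx[base]][j] for j, base in enumerate(rc))
        if fwd >= threshold:
            hits.append((off, "+", fwd))
        if rev >= threshold:
            hits.append((off, "-", rev))
    return hits


def kde_brute(values, grid, h: float):
    """Direct double-loop Gaussian KDE."""
    n = len(values)
    out = []
    for g in grid:
        s = 0.0
        for v in values:
            z = (g - v) / h
            s += math.exp(-0.5 * z * z) / math.sqrt(2 * math.pi)
        out.append(s / (n * h))
    return out


def pearson_brute(x, y):
    """Covariance over product of SDs, written out longhand."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def quantile_normalize_brute(columns):
    """Hand order-statistic quantile normalization (no ties expected)."""
    n = len(columns[0])
    ref = [
        sum(sorted(col)[i] for col in columns) / len(columns) for i in range(n)
    ]
    out = []
    for col in columns:
        ranks = sorted(range(n), key=lambda i: col[i])
        new = [0.0] * n
        for r, i in enumerate(ranks):
            new[i] = ref[r]
        out.append(new)
    return out
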