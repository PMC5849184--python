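"""Genome-wide Pearson coexpression screen against a query gene.

The screen computes, for every other gene in the matrix, the sample
Pearson correlation r with the query, a two-sided p-value from the exact
Student-t transform t = r*sqrt((n-2)/(1-r^2)), a Benjamini-Hochberg
adjusted q-value over the whole screen, and a three-way classification:

* ``positive``  — r >  r_min and q < q_max
* ``negative``  — r < -r_min and q < q_max
* ``none``      — everything else, including zero-variance (degenerate)
  genes, whose correlation is undefined and which are excluded from the
  BH family rather than assigned p = 1.

Defaults r_min = 0.2 and q_max = 1e-4 reproduce the published screen
thresholds ("FDR < 0.01% and |r| > 0.2", both strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import ExpressionMatrix

__all__ = [
    "CorrelationRecord",
    "CoexpressionScreen",
    "pearson_with_pvalue",
    "bh_adjust",
    "screen_coexpression",
]

#: p-value reported for |r| == 1, where the t transform diverges.
P_FLOOR = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class CorrelationRecord:
    """One gene's correlation with the query.

    ``degenerate`` marks a zero-variance gene: r, p and q are NaN and the
    class is ``none``.
    """

    gene: str
    r: float
    p: float
    q: float
    klass: str  # "positive" | "negative" | "none"
    degenerate: bool = False


@dataclass
class CoexpressionScreen:
    """Full screen result: one record per non-query gene."""

    query: str
    n_samples: int
    r_min: float
    q_max: float
    records: list[CorrelationRecord]
    m_tested: int  # genes with defined r, the BH family size

    _by_gene: dict[str, CorrelationRecord] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        self._by_gene = {rec.gene: rec for rec in self.records}

    def __getitem__(self, gene: str) -> CorrelationRecord:
        return self._by_gene[gene.upper()]

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self._by_gene

    def genes(self) -> list[str]:
        return [rec.gene for rec in self.records]

    def count(self, klass: str) -> int:
        return sum(1 for rec in self.records if rec.klass == klass)

    def members(self, klass: str) -> list[str]:
        return [rec.gene for rec in self.records if rec.klass == klass]


def _t_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the Student-t transform (n-2 df)."""
    r = np.asarray(r, dtype=float)
    p = np.empty_like(r)
    exact = np.abs(r) >= 1.0 - 1e-15
    p[exact] = P_FLOOR
    rr = r[~exact]
    t = rr * np.sqrt((n - 2) / (1.0 - rr * rr))
    p[~exact] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.minimum(p, 1.0)


def pearson_with_pvalue(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided parametric p-value.

    Returns ``(nan, nan)`` when either vector has zero variance (the
    correlation is undefined, not non-significant).  Perfectly collinear
    input reports ``p`` at the smallest representable positive float.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return (float("nan"), float("nan"))
    r = float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))
    if abs(r) > 1.0 - 1e-14:  # collinear up to rounding
        r = math.copysign(1.0, r)
    p = float(_t_pvalue(np.array([r]), n)[0])
    return r, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q at sorted position i is min over j >= i of p_(j) * m / j, capped at
    1 and mapped back to input order; equal p-values receive equal q.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_coexpression(
    m: ExpressionMatrix,
    query: str,
    r_min: float = 0.2,
    q_max: float = 1e-4,
) -> CoexpressionScreen:
    """Correlate the query gene with every other gene and classify.

    BH adjustment is applied once over all genes with defined r (one
    family); the query is excluded from its own screen.  Records are
    sorted by descending r with the gene symbol as tie-break; degenerate
    genes sort last.
    """
    if r_min < 0:
        raise ValueError("r_min must be non-negative")
    if not 0 < q_max <= 1:
        raise ValueError("q_max must lie in (0, 1]")
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples")
    qi = m.row_index(query)  # KeyError if absent
    n = m.n_samples

    X = np.delete(m.values, qi, axis=0)
    genes = [g for i, g in enumerate(m.gene_ids) if i != qi]
    qv = m.values[qi]

    Xc = X - X.mean(axis=1, keepdims=True)
    qc = qv - qv.mean()
    qnorm = np.sqrt(qc @ qc)
    row_norms = np.sqrt(np.einsum("ij,ij->i", Xc, Xc))
    degenerate = row_norms == 0.0
    if qnorm == 0.0:
        degenerate = np.ones_like(degenerate)

    r = np.full(X.shape[0], np.nan)
    ok = ~degenerate
    if np.any(ok):
        r[ok] = np.clip((Xc[ok] @ qc) / (row_norms[ok] * qnorm), -1.0, 1.0)

    p = np.full_like(r, np.nan)
    q = np.full_like(r, np.nan)
    m_tested = int(ok.sum())
    if m_tested:
        p[ok] = _t_pvalue(r[ok], n)
        q[ok] = bh_adjust(p[ok])

    records = []
    for i, g in enumerate(genes):
        if degenerate[i]:
            records.append(
                CorrelationRecord(g, float("nan"), float("nan"), float("nan"),
                                  "none", degenerate=True)
            )
            continue
        if q[i] < q_max and r[i] > r_min:
            klass = "positive"
        elif q[i] < q_max and r[i] < -r_min:
            klass = "negative"
        else:
            klass = "none"
        records.append(CorrelationRecord(g, float(r[i]), float(p[i]),
                                         float(q[i]), klass))

    records.sort(key=lambda rec: (rec.degenerate, -rec.r if not rec.degenerate
                                  else 0.0, rec.gene))
    return CoexpressionScreen(
        query=m.gene_ids[qi],
        n_samples=n,
        r_min=r_min,
        q_max=q_max,
        records=records,
        m_tested=m_tested,
    )
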