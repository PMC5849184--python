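"""Directional-bias statistics for a curated gene set within a screen.

Given a coexpression screen and a curated set (e.g. immune-response
genes), these tests ask whether the set is skewed toward negative (or
positive) correlation with the query gene:

* a 2x2 Fisher exact test of the set against the negative class,
* an exact binomial sign test on the positive/negative split inside the
  set (p0 = 0.5),
* a two-proportion Fisher comparison against a second set,
* an unpaired two-sample t-test / one-way ANOVA for comparing value
  distributions (e.g. per-gene standard deviations),
* Gaussian kernel density estimation for the density plots.

Two-sided exact tests use the minimum-likelihood definition: the sum of
all outcomes whose point probability does not exceed the observed one
(with 1e-7 relative slack for floating-point ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from fractions import Fraction

import numpy as np
from scipy import stats

from .coexpression import CoexpressionScreen
from .data_io import GeneSet
from .errors import DataError

__all__ = [
    "ContingencyTable2x2",
    "BiasReport",
    "fisher_exact_2x2",
    "binomial_sign_test",
    "bias_analysis",
    "bias_report_from_counts",
    "compare_distributions",
    "gaussian_kde",
    "percent_1dp",
]

_TIE_SLACK = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = in-set / not-in-set, columns = in-class / not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("contingency table must have at least one count")


def fisher_exact_2x2(t: ContingencyTable2x2, sided: str = "two") -> float:
    """Fisher's exact test on a 2x2 table.

    ``sided="greater"`` is the upper hypergeometric tail for cell ``a``
    (over-representation of the class in the set), ``"less"`` the lower
    tail, ``"two"`` the minimum-likelihood two-sided sum.
    """
    if sided not in {"two", "greater", "less"}:
        raise ValueError(f"unknown sidedness {sided!r}")
    a, b, c, d = t.a, t.b, t.c, t.d
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    obs = pmf[a - lo]
    if sided == "greater":
        p = pmf[support >= a].sum()
    elif sided == "less":
        p = pmf[support <= a].sum()
    else:
        p = pmf[pmf <= obs * (1.0 + _TIE_SLACK)].sum()
    return float(min(p, 1.0))


def binomial_sign_test(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial test, minimum-likelihood definition.

    Sums Binomial(n, p0) point probabilities over all outcomes no more
    likely than the observed count ``k``.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    support = np.arange(n + 1)
    pmf = stats.binom.pmf(support, n, p0)
    p = pmf[pmf <= pmf[k] * (1.0 + _TIE_SLACK)].sum()
    return float(min(p, 1.0))


@dataclass
class BiasReport:
    """Directional-bias summary of a gene set against a screen.

    Proportions are percents.  The *paper-style* background proportion
    uses the genome-wide negative count over the full background total
    (the convention of the published contingency figure); the Fisher test
    is computed on the internally consistent table in which set members
    are removed from the background column.
    """

    set_name: str
    n_set: int
    n_background: int
    set_counts: dict[str, int]          # positive / negative / none in the set
    background_counts: dict[str, int]   # same classes over the full background
    proportion_negative_set: float
    proportion_negative_background: float
    fisher_p_negative: float
    sign_test_p: float
    two_proportion_p: float | None = None

    def formatted(self) -> dict[str, str]:
        """Reporting layer: percentages to one decimal, half-to-even."""
        return {
            "proportion_negative_set": percent_1dp(
                self.set_counts["negative"], self.n_set
            ),
            "proportion_negative_background": percent_1dp(
                self.background_counts["negative"], self.n_background
            ),
        }


def percent_1dp(count: int, total: int) -> str:
    """Exact-rational percent rendered to one decimal, round half to even."""
    frac = Fraction(100 * count, total)
    dec = Decimal(frac.numerator) / Decimal(frac.denominator)
    return str(dec.quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))


def bias_report_from_counts(
    set_name: str,
    n_set: int,
    set_negative: int,
    set_positive: int,
    n_background_total: int,
    background_negative_total: int,
    comparison: tuple[int, int] | None = None,
) -> BiasReport:
    """Build a :class:`BiasReport` from raw counts.

    ``n_background_total`` counts every gene in the analysis universe
    (set members included) and ``background_negative_total`` the
    genome-wide negative class, matching how published contingency
    figures quote their denominators.  The Fisher table removes the set
    from the background column so the two rows are disjoint.
    ``comparison`` optionally supplies ``(negative, total)`` of a second
    set for a two-proportion Fisher test.
    """
    if set_negative + set_positive > n_set:
        raise ValueError("set class counts exceed set size")
    if background_negative_total < set_negative:
        raise ValueError("background negative count smaller than the set's")
    if n_background_total < n_set:
        raise ValueError("background total smaller than the set")
    out_set = n_background_total - n_set
    out_neg = background_negative_total - set_negative
    table = ContingencyTable2x2(
        a=set_negative,
        b=n_set - set_negative,
        c=out_neg,
        d=out_set - out_neg,
    )
    n_signed = set_positive + set_negative
    sign_p = binomial_sign_test(set_positive, n_signed) if n_signed else 1.0
    two_prop = None
    if comparison is not None:
        other_neg, other_total = comparison
        two_prop = fisher_exact_2x2(
            ContingencyTable2x2(
                a=set_negative,
                b=n_set - set_negative,
                c=other_neg,
                d=other_total - other_neg,
            ),
            sided="two",
        )
    return BiasReport(
        set_name=set_name,
        n_set=n_set,
        n_background=n_background_total,
        set_counts={
            "positive": set_positive,
            "negative": set_negative,
            "none": n_set - n_signed,
        },
        background_counts={"negative": background_negative_total},
        proportion_negative_set=100.0 * set_negative / n_set,
        proportion_negative_background=(
            100.0 * background_negative_total / n_background_total
        ),
        fisher_p_negative=fisher_exact_2x2(table, sided="greater"),
        sign_test_p=sign_p,
        two_proportion_p=two_prop,
    )


def bias_analysis(
    screen: CoexpressionScreen,
    gene_set: GeneSet,
    comparison_set: GeneSet | None = None,
) -> BiasReport:
    """Quantify the directional bias of ``gene_set`` within ``screen``.

    Set membership is restricted to genes present in the screen.  The
    background total is all screened genes (set members included), so the
    reported background proportion matches the genome-wide convention.
    """
    present = [g for g in gene_set.members if g in screen]
    if not present:
        raise DataError(
            f"gene set {gene_set.name!r} shares no genes with the screen"
        )
    set_neg = sum(1 for g in present if screen[g].klass == "negative")
    set_pos = sum(1 for g in present if screen[g].klass == "positive")
    n_total = len(screen.records)
    neg_total = screen.count("negative")
    comparison = None
    if comparison_set is not None:
        cmp_present = [g for g in comparison_set.members if g in screen]
        if not cmp_present:
            raise DataError(
                f"comparison set {comparison_set.name!r} shares no genes "
                "with the screen"
            )
        cmp_neg = sum(1 for g in cmp_present if screen[g].klass == "negative")
        comparison = (cmp_neg, len(cmp_present))
    report = bias_report_from_counts(
        set_name=gene_set.name,
        n_set=len(present),
        set_negative=set_neg,
        set_positive=set_pos,
        n_background_total=n_total,
        background_negative_total=neg_total,
        comparison=comparison,
    )
    report.background_counts = {
        "positive": screen.count("positive"),
        "negative": neg_total,
        "none": screen.count("none"),
    }
    return report


def compare_distributions(x, y, method: str = "t_test") -> tuple[float, float]:
    """Compare two value distributions.

    ``t_test`` is the classical pooled-variance two-sample t-test
    (two-tailed); ``anova`` the one-way F-test.  For two groups F == t**2.
    Identical constant input in both groups returns (0, 1) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if method not in {"t_test", "anova"}:
        raise ValueError(f"unknown method {method!r}")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("degenerate comparison: all values identical",
                      RuntimeWarning, stacklevel=2)
        return 0.0, 1.0
    if method == "t_test":
        stat, p = stats.ttest_ind(x, y, equal_var=True)
    else:
        stat, p = stats.f_oneway(x, y)
    return float(stat), float(p)


def gaussian_kde(values, grid, bandwidth: float | str = "auto") -> np.ndarray:
    """Gaussian kernel density estimate on a fixed grid.

    density(g) = (1/(n*h)) * sum_i phi((g - v_i)/h) with phi the standard
    normal pdf.  ``bandwidth="auto"`` applies the robust Silverman rule
    h = 0.9 * min(sd, IQR/1.34) * n**(-1/5); a zero scale (constant data)
    falls back to h = 1.
    """
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.size < 1:
        raise ValueError("need at least one value")
    if bandwidth == "auto":
        n = values.size
        sd = values.std(ddof=1) if n > 1 else 0.0
        iqr = np.subtract(*np.percentile(values, [75, 25]))
        scale = min(sd, iqr / 1.34) if min(sd, iqr) > 0 else max(sd, iqr / 1.34)
        h = 0.9 * scale * n ** (-0.2) if scale > 0 else 1.0
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    z = (grid[:, None] - values[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (values.size * h * np.sqrt(2 * np.pi))
    return dens
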