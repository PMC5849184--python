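"""Offline over-representation analysis and TF prioritization.

Replaces a web enrichment call with a local engine: for each term of a
GMT library the overlap with a query gene list is scored by the upper
hypergeometric tail within a declared background universe, adjusted by
Benjamini-Hochberg across the library, and ranked deterministically
(ascending q, ascending p, descending overlap, term name).  Running the
same engine over a TF-target library — set names are transcription
factors, members their targets — yields a master-regulator ranking.

The universe defaults to the genes of the loaded expression matrix; web
tools keep their own (unpublished) backgrounds, so p-values from such
tools are reproduced in order of magnitude, not digit for digit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .coexpression import bh_adjust
from .data_io import GeneSet, GeneSetLibrary
from .errors import DataError

__all__ = [
    "EnrichmentRecord",
    "TFRanking",
    "hypergeom_upper_tail",
    "enrich_sets",
    "prioritize_tfs",
]


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term's over-representation result.

    k = |query ∩ term| within the universe, K = |term| within the
    universe, n = |query| within the universe, N = universe size.
    """

    term: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float
    rank: int


@dataclass
class TFRanking:
    """Deterministically ordered TF-target enrichment results."""

    entries: list[tuple[str, EnrichmentRecord]]

    def rank_of(self, tf_name: str) -> int:
        for name, rec in self.entries:
            if name == tf_name:
                return rec.rank
        raise KeyError(tf_name)

    def top(self, n: int = 10) -> list[tuple[str, EnrichmentRecord]]:
        return self.entries[:n]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def hypergeom_upper_tail(k, K: int, n: int, N: int):
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Evaluated through the survival function (log-space internally) for
    numerical stability; k = 0 gives exactly 1.  ``k`` may be a scalar or
    an integer array.
    """
    k_arr = np.atleast_1d(np.asarray(k, dtype=int))
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    if np.any(k_arr < 0) or np.any(k_arr > np.minimum(K, n)):
        raise ValueError("need 0 <= k <= min(K, n)")
    p = np.minimum(stats.hypergeom.sf(k_arr - 1, N, K, n), 1.0)
    p[k_arr == 0] = 1.0
    return float(p[0]) if np.isscalar(k) or np.asarray(k).ndim == 0 else p


def _sort_key(rec: EnrichmentRecord):
    return (rec.q, rec.p, -rec.k, rec.term)


def enrich_sets(
    query: GeneSet,
    library: GeneSetLibrary,
    universe: set[str],
    q_cut: float = 0.1,
) -> list[EnrichmentRecord]:
    """Score every library term against the query list.

    Terms with no member in the universe are dropped before BH (they
    carry no information and would distort the family size).  When
    ``q_cut < 1`` the returned records are filtered to q < q_cut; ranks
    are assigned over the returned, sorted records.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if len(library) == 0:
        raise ValueError("library must be non-empty")
    universe = {g.upper() for g in universe}
    query_u = query.members & universe
    if not query_u:
        raise DataError(
            f"query {query.name!r} shares no genes with the universe"
        )
    N, n = len(universe), len(query_u)
    terms, ks, Ks = [], [], []
    for s in library:
        term_u = s.members & universe
        if not term_u:
            continue
        terms.append(s.name)
        Ks.append(len(term_u))
        ks.append(len(term_u & query_u))
    if not terms:
        raise DataError(
            f"no term of library {library.name!r} intersects the universe"
        )
    ps = np.array(
        [hypergeom_upper_tail(k, K, n, N) for k, K in zip(ks, Ks)]
    )
    qs = bh_adjust(ps)
    records = [
        EnrichmentRecord(term=t, k=k, K=K, n=n, N=N, p=float(p), q=float(q),
                         rank=0)
        for t, k, K, p, q in zip(terms, ks, Ks, ps, qs)
    ]
    if q_cut < 1.0:
        records = [rec for rec in records if rec.q < q_cut]
    records.sort(key=_sort_key)
    return [
        EnrichmentRecord(**{**rec.__dict__, "rank": i + 1})
        for i, rec in enumerate(records)
    ]


def prioritize_tfs(
    query: GeneSet,
    tf_library: GeneSetLibrary,
    universe: set[str],
) -> TFRanking:
    """Rank candidate master regulators by target-set over-representation.

    The full library ranking is returned (no q cut-off) so the rank of
    any named TF is retrievable.
    """
    records = enrich_sets(query, tf_library, universe, q_cut=1.0)
    return TFRanking(entries=[(rec.term, rec) for rec in records])
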