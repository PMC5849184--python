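"""Position-weight-matrix construction and promoter scanning.

A JASPAR-style count matrix (PFM) is turned into a log2-odds position
weight matrix with a total pseudocount distributed by the background
composition:

    weight[b][j] = log2( (counts[b][j] + pc * bg[b])
                         / ((colsum_j + pc) * bg[b]) )

Every window of the promoter is scored on both strands (the reverse
strand through the reverse complement); windows containing N are
skipped.  Hit coordinates are reported relative to the transcription
start site using the promoter convention without a position 0: base -1
abuts base +1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import PromoterSequence
from .errors import DataError

__all__ = [
    "PositionFrequencyMatrix",
    "PositionWeightMatrix",
    "MotifHit",
    "pwm_from_counts",
    "consensus_of",
    "scan_sequence",
    "offset_to_tss",
    "tss_to_offset",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class PositionFrequencyMatrix:
    """Base counts per motif position; rows A, C, G, T."""

    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix (rows A,C,G,T)")
        if self.counts.shape[1] < 1:
            raise ValueError("matrix needs at least one column")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError("every column must have a positive total")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass
class PositionWeightMatrix:
    """Log2-odds weights derived from a PFM."""

    name: str
    weights: np.ndarray
    pseudocount: float
    background: np.ndarray

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    @property
    def consensus_score(self) -> float:
        """Score of the per-column argmax path (maximum attainable)."""
        return float(self.weights.max(axis=0).sum())


@dataclass(frozen=True)
class MotifHit:
    """One scored window in TSS coordinates (no position 0)."""

    start_tss: int
    end_tss: int
    strand: str  # "+" or "-"
    score: float
    offset: int = field(compare=False, default=-1)  # 0-based genomic start


def offset_to_tss(offset: int, tss_offset: int) -> int:
    """Convert a 0-based sequence index to a TSS coordinate (-1 abuts +1)."""
    rel = offset - tss_offset
    return rel if rel < 0 else rel + 1


def tss_to_offset(pos: int, tss_offset: int) -> int:
    """Inverse of :func:`offset_to_tss`."""
    if pos == 0:
        raise ValueError("TSS coordinates have no position 0")
    return pos + tss_offset if pos < 0 else pos + tss_offset - 1


def pwm_from_counts(
    pfm: PositionFrequencyMatrix,
    pseudocount: float = 1.0,
    background=None,
) -> PositionWeightMatrix:
    """Build the log2-odds PWM from a count matrix.

    ``pseudocount`` is the total pseudo-observation mass per column,
    distributed across bases in proportion to the background (uniform by
    default).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = (
        np.full(4, 0.25)
        if background is None
        else np.asarray(background, dtype=float)
    )
    if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must be 4 positive probabilities summing to 1")
    colsum = pfm.counts.sum(axis=0)
    weights = np.log2(
        (pfm.counts + pseudocount * bg[:, None])
        / ((colsum + pseudocount)[None, :] * bg[:, None])
    )
    return PositionWeightMatrix(
        name=pfm.name, weights=weights, pseudocount=pseudocount, background=bg
    )


def consensus_of(
    pfm: PositionFrequencyMatrix, with_ties: bool = False
):
    """Per-column argmax consensus; ties broken in A<C<G<T order.

    With ``with_ties=True`` also returns a boolean flag per column marking
    tied maxima.
    """
    argmax = pfm.counts.argmax(axis=0)  # first max wins: A<C<G<T order
    consensus = "".join(_BASES[i] for i in argmax)
    if not with_ties:
        return consensus
    colmax = pfm.counts.max(axis=0)
    ties = (pfm.counts == colmax[None, :]).sum(axis=0) > 1
    return consensus, ties.tolist()


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _window_scores(pwm: PositionWeightMatrix, codes: np.ndarray) -> np.ndarray:
    """Score all forward-strand windows; N (code 4) poisons a window."""
    L = pwm.length
    n_win = codes.size - L + 1
    padded = np.vstack([pwm.weights, np.full(L, -np.inf)])  # row 4 = N
    scores = np.zeros(n_win)
    for j in range(L):
        scores += padded[codes[j : j + n_win], j]
    return scores


def scan_sequence(
    pwm: PositionWeightMatrix,
    promoter: PromoterSequence,
    min_score: float | None = None,
    min_fraction: float | None = None,
) -> list[MotifHit]:
    """Score every window of the promoter on both strands.

    The threshold is either an absolute score (``min_score``) or a
    fraction of the consensus score (``min_fraction``); exactly one must
    be given.  Hits are sorted by descending score, then genomic
    position, then strand (+ before -).  Windows containing N never
    qualify.
    """
    if (min_score is None) == (min_fraction is None):
        raise ValueError("give exactly one of min_score / min_fraction")
    threshold = (
        float(min_score)
        if min_score is not None
        else float(min_fraction) * pwm.consensus_score
    )
    L = pwm.length
    if len(promoter) < L:
        raise DataError(
            f"promoter {promoter.id!r} (length {len(promoter)}) shorter than "
            f"motif (length {L})"
        )
    codes = np.fromiter(
        (_CODE.get(b, 4) for b in promoter.sequence), dtype=np.intp,
        count=len(promoter),
    )
    fwd = _window_scores(pwm, codes)
    # reverse strand: score of a window = forward score of the
    # reverse-complemented PWM on the same window
    rc_weights = pwm.weights[::-1, ::-1]
    rc_pwm = PositionWeightMatrix(
        name=pwm.name, weights=rc_weights,
        pseudocount=pwm.pseudocount, background=pwm.background,
    )
    rev = _window_scores(rc_pwm, codes)

    hits: list[MotifHit] = []
    t = promoter.tss_offset
    for strand, scores in (("+", fwd), ("-", rev)):
        for off in np.flatnonzero(scores >= threshold):
            off = int(off)
            hits.append(
                MotifHit(
                    start_tss=offset_to_tss(off, t),
                    end_tss=offset_to_tss(off + L - 1, t),
                    strand=strand,
                    score=float(scores[off]),
                    offset=off,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.offset, h.strand))
    return hits
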