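"""Input containers, readers and pre-correlation summaries.

The analysis consumes five kinds of input: a log2 gene-by-sample
expression matrix (TSV or GCT 1.2), plain-text gene lists, GMT gene-set
libraries, a JASPAR-style position frequency matrix, and a promoter
sequence in FASTA with a declared transcription start site (TSS) offset.
This module loads and validates each of them, collapses duplicate gene
symbols, quantile-normalizes the matrix so every sample shares one
reference distribution, and computes the per-gene expression summaries
(percentile rank across genes, linear fold range, log2 standard
deviation) used to characterise a highly expressed query gene.

Gene symbols are upper-cased everywhere so that list/matrix/library
intersections are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetLibrary",
    "PromoterSequence",
    "ExpressionSummary",
    "read_expression",
    "read_gene_list",
    "read_gmt",
    "read_jaspar_pfm",
    "read_promoter_fasta",
    "quantile_normalize",
    "summarize_gene",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes in rows and samples in columns."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    tissue_of_sample: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        self.gene_ids = [g.upper() for g in self.gene_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids not unique after case normalization")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must all be finite")
        self._row_of = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene: str) -> np.ndarray:
        """Expression vector of one gene across all samples."""
        key = gene.upper()
        if key not in self._row_of:
            raise KeyError(f"gene {gene!r} not in matrix")
        return self.values[self._row_of[key]]

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self._row_of

    def row_index(self, gene: str) -> int:
        key = gene.upper()
        if key not in self._row_of:
            raise KeyError(f"gene {gene!r} not in matrix")
        return self._row_of[key]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (upper-cased)."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "members", frozenset(m.upper() for m in self.members)
        )
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)

    def restricted_to(self, universe: Iterable[str]) -> frozenset[str]:
        return self.members & {g.upper() for g in universe}


@dataclass
class GeneSetLibrary:
    """An ordered collection of uniquely named gene sets (a GMT file)."""

    name: str
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate set names in library {self.name!r}")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class PromoterSequence:
    """A promoter with a declared TSS position.

    ``tss_offset`` is the 0-based index, within ``sequence``, of the +1
    base; every base before it is upstream.  ``tss_offset == len(sequence)``
    means the whole sequence is upstream of the TSS.
    """

    id: str
    sequence: str
    tss_offset: int

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"promoter contains invalid characters {sorted(bad)}")
        if not 0 <= self.tss_offset <= len(self.sequence):
            raise ValueError(
                f"tss_offset {self.tss_offset} outside sequence of length "
                f"{len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ExpressionSummary:
    """Per-gene summary mirroring the highly-expressed-gene claims.

    ``min_percentile_rank`` is the minimum over samples of
    100 * (#genes with value <= query value) / (#genes);
    ``fold_range`` is 2**(max - min) of the gene's log2 values (linear
    scale, >= 1); ``sd_log2`` is the population standard deviation.
    """

    gene: str
    min_percentile_rank: float
    fold_range: float
    sd_log2: float


# ---------------------------------------------------------------------------
# readers


def _collapse_duplicates(
    genes: list[str], values: np.ndarray
) -> tuple[list[str], np.ndarray]:
    """Collapse duplicated (case-normalized) symbols keeping the max-mean row."""
    upper = [g.upper() for g in genes]
    if len(set(upper)) == len(upper):
        return upper, values
    best: dict[str, int] = {}
    means = values.mean(axis=1)
    n_dropped = 0
    for i, g in enumerate(upper):
        if g not in best or means[i] > means[best[g]]:
            if g in best:
                n_dropped += 1
            best[g] = i
        elif g in best:
            n_dropped += 1
    order = sorted(best.values())
    logger.info("collapsed %d duplicate gene rows (kept max-mean row)", n_dropped)
    return [upper[i] for i in order], values[order]


def _parse_numeric_block(
    rows: list[list[str]], genes: list[str], samples: list[str], path: Path
) -> np.ndarray:
    values = np.empty((len(rows), len(samples)), dtype=float)
    for i, fields in enumerate(rows):
        if len(fields) != len(samples):
            raise DataError(
                f"{path}: row {genes[i]!r} has {len(fields)} values, "
                f"expected {len(samples)}"
            )
        for j, cell in enumerate(fields):
            if cell == "" or cell.upper() in {"NA", "NAN", "NULL"}:
                raise DataError(
                    f"{path}: missing value at gene {genes[i]!r}, "
                    f"sample {samples[j]!r}"
                )
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise DataError(
                    f"{path}: non-numeric cell {cell!r} at gene {genes[i]!r}, "
                    f"sample {samples[j]!r}"
                ) from None
            if not np.isfinite(values[i, j]):
                raise DataError(
                    f"{path}: non-finite value at gene {genes[i]!r}, "
                    f"sample {samples[j]!r}"
                )
    return values


def read_expression(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a gene-by-sample expression matrix.

    ``dialect="tsv"``: a header line ``GENE<TAB>sample1<TAB>...`` followed
    by one row per gene.  ``dialect="gct"``: GCT 1.2 — a ``#1.2`` line, a
    dimensions line, then ``Name``/``Description`` columns before the
    samples.  Duplicate symbols are collapsed to the row with the highest
    mean expression.
    """
    path = Path(path)
    if dialect not in {"tsv", "gct"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = [
        ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip() != ""
    ]
    desc_cols = 1
    if dialect == "gct":
        if len(lines) < 3 or not lines[0].startswith("#1.2"):
            raise FormatError(f"{path}: not a GCT 1.2 file (missing '#1.2' line)")
        dims = lines[1].split("\t")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except (ValueError, IndexError):
            raise FormatError(f"{path}: malformed GCT dimensions line") from None
        lines = lines[2:]
        desc_cols = 2
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < desc_cols + 1:
        raise FormatError(f"{path}: header has no sample columns")
    samples = header[desc_cols:]
    if len(set(samples)) != len(samples):
        raise FormatError(f"{path}: duplicate sample ids in header")
    genes, rows = [], []
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) < desc_cols + 1:
            raise FormatError(f"{path}: data line with too few fields: {ln[:50]!r}")
        genes.append(fields[0])
        rows.append(fields[desc_cols:])
    if dialect == "gct" and (len(genes) != n_genes or len(samples) != n_samples):
        raise FormatError(
            f"{path}: GCT declares {n_genes}x{n_samples} but file has "
            f"{len(genes)}x{len(samples)}"
        )
    if not genes:
        raise DataError(f"{path}: matrix has no gene rows")
    values = _parse_numeric_block(rows, genes, samples, path)
    genes, values = _collapse_duplicates(genes, values)
    return ExpressionMatrix(gene_ids=genes, sample_ids=samples, values=values)


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list; ``#`` starts a comment."""
    path = Path(path)
    members = []
    for ln in path.read_text().splitlines():
        sym = ln.split("#", 1)[0].strip()
        if sym:
            members.append(sym.upper())
    if not members:
        raise DataError(f"{path}: gene list is empty")
    return GeneSet(name=name or path.stem, members=frozenset(members))


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetLibrary:
    """Read a GMT library: ``name TAB description TAB member TAB ...``."""
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if ln.strip() == "":
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs name, description and at "
                f"least one member ({len(fields)} fields found)"
            )
        set_name, desc = fields[0], fields[1]
        if set_name in seen:
            raise FormatError(f"{path}:{lineno}: duplicate set name {set_name!r}")
        seen.add(set_name)
        members = frozenset(m.upper() for m in fields[2:] if m.strip())
        if not members:
            raise FormatError(f"{path}:{lineno}: set {set_name!r} has no members")
        sets.append(GeneSet(name=set_name, members=members, description=desc))
    if not sets:
        raise FormatError(f"{path}: GMT file has no sets")
    return GeneSetLibrary(name=name or path.stem, sets=sets)


def read_jaspar_pfm(path: str | Path):
    """Read a JASPAR-style position frequency matrix.

    Accepts an optional ``>`` header line and four base rows in either the
    bracketed (``A [ 4 0 ]``) or plain whitespace-separated dialect.
    Returns a :class:`~coexkit.promoter_scan.PositionFrequencyMatrix`.
    """
    from .promoter_scan import PositionFrequencyMatrix

    path = Path(path)
    name = path.stem
    rows: dict[str, list[float]] = {}
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith(">"):
            name = ln[1:].strip() or name
            continue
        base = ln[0].upper()
        if base not in "ACGT":
            raise FormatError(f"{path}: unexpected row label in line {ln[:30]!r}")
        if base in rows:
            raise FormatError(f"{path}: duplicate row for base {base}")
        body = ln[1:].replace("[", " ").replace("]", " ")
        try:
            counts = [float(tok) for tok in body.split()]
        except ValueError:
            raise FormatError(f"{path}: non-numeric count in row {base}") from None
        if any(c < 0 for c in counts):
            raise DataError(f"{path}: negative count in row {base}")
        rows[base] = counts
    missing = [b for b in "ACGT" if b not in rows]
    if missing:
        raise FormatError(f"{path}: missing base row(s) {missing}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise FormatError(f"{path}: base rows have unequal lengths {sorted(lengths)}")
    if lengths == {0}:
        raise FormatError(f"{path}: matrix has zero columns")
    counts = np.array([rows[b] for b in "ACGT"], dtype=float)
    return PositionFrequencyMatrix(name=name, counts=counts)


def read_promoter_fasta(
    path: str | Path, tss_offset: int | None = None
) -> PromoterSequence:
    """Read a single-record promoter FASTA.

    The TSS offset comes from the argument or, failing that, from a
    ``tss=<int>`` key in the FASTA description line.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise FormatError(f"{path}: expected exactly one FASTA record, "
                          f"found {len(records)}")
    rec = records[0]
    if tss_offset is None:
        for tok in rec.description.split():
            if tok.lower().startswith("tss="):
                try:
                    tss_offset = int(tok.split("=", 1)[1])
                except ValueError:
                    raise FormatError(
                        f"{path}: malformed tss= key in description"
                    ) from None
        if tss_offset is None:
            raise DataError(
                f"{path}: no TSS offset given and no 'tss=' key in description"
            )
    return PromoterSequence(id=rec.id, sequence=str(rec.seq), tss_offset=tss_offset)


# ---------------------------------------------------------------------------
# computations


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to share one reference distribution.

    The reference value at rank ``i`` is the mean across samples of each
    sample's ``i``-th order statistic.  Ties within a sample receive the
    mean of the reference values at the tied ranks, so tied inputs stay
    tied and the transform is idempotent.
    """
    X = m.values
    n_genes, n_samples = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    sorted_cols = np.take_along_axis(X, order, axis=0)
    reference = sorted_cols.mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        sv = sorted_cols[:, j]
        # boundaries of runs of tied values in the sorted column
        starts = np.flatnonzero(np.concatenate(([True], sv[1:] != sv[:-1])))
        sizes = np.diff(np.concatenate((starts, [n_genes])))
        group_means = np.add.reduceat(reference, starts) / sizes
        out[order[:, j], j] = np.repeat(group_means, sizes)
    return ExpressionMatrix(
        gene_ids=list(m.gene_ids),
        sample_ids=list(m.sample_ids),
        values=out,
        tissue_of_sample=dict(m.tissue_of_sample),
    )


def percentile_ranks(m: ExpressionMatrix, gene: str) -> np.ndarray:
    """Per-sample percentile rank of one gene among all genes.

    Defined with a weak inequality: 100 * (#genes <= query) / (#genes).
    Invariant under any strictly monotone per-sample transform.
    """
    v = m.row(gene)
    counts = (m.values <= v[None, :]).sum(axis=0)
    return 100.0 * counts / m.n_genes


def summarize_gene(m: ExpressionMatrix, gene: str) -> ExpressionSummary:
    """Summarize one gene: minimum percentile rank, fold range, log2 SD."""
    v = m.row(gene)
    ranks = percentile_ranks(m, gene)
    return ExpressionSummary(
        gene=gene.upper(),
        min_percentile_rank=float(ranks.min()),
        fold_range=float(2.0 ** (v.max() - v.min())),
        sd_log2=float(v.std(ddof=0)),
    )
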