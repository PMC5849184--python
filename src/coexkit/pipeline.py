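"""End-to-end orchestration of the guilt-by-association analysis.

``run_pipeline`` executes the stages in order — load/normalize the
expression matrix, screen the query gene, bias-test each curated gene
list, enrich each annotation library, prioritize TFs, and scan the
promoter for the top TF's motif — and writes deterministic TSV tables
plus a machine-readable JSON summary.  Optional stages (no promoter, no
TF library) are skipped with a logged notice.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .coexpression import CoexpressionScreen, screen_coexpression
from .data_io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetLibrary,
    PromoterSequence,
    quantile_normalize,
    read_expression,
    read_gene_list,
    read_gmt,
    read_jaspar_pfm,
    read_promoter_fasta,
    summarize_gene,
)
from .enrichment import EnrichmentRecord, TFRanking, enrich_sets, prioritize_tfs
from .errors import ConfigError
from .promoter_scan import MotifHit, pwm_from_counts, scan_sequence
from .set_bias import BiasReport, bias_analysis

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    expression_path: str
    query: str
    expression_dialect: str = "tsv"
    quantile_normalize: bool = False
    r_min: float = 0.2
    q_max: float = 1e-4
    gene_list_paths: list[str] = field(default_factory=list)
    library_paths: list[str] = field(default_factory=list)
    tf_library_path: str | None = None
    enrichment_q_cut: float = 0.1
    enrichment_query: str = "all"  # all | negative | positive
    pfm_path: str | None = None
    promoter_path: str | None = None
    tss_offset: int | None = None
    scan_min_fraction: float = 0.8
    output_dir: str = "coexkit_out"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.q_max <= 1:
            raise ConfigError("q_max must lie in (0, 1]")
        if self.r_min < 0:
            raise ConfigError("r_min must be non-negative")
        if self.enrichment_query not in {"all", "negative", "positive"}:
            raise ConfigError(
                f"enrichment_query must be all/negative/positive, "
                f"got {self.enrichment_query!r}"
            )
        required = [self.expression_path]
        optional = (
            self.gene_list_paths
            + self.library_paths
            + [p for p in (self.tf_library_path, self.pfm_path,
                           self.promoter_path) if p]
        )
        for p in required + optional:
            if not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        cfg = PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from None
    return cfg


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run."""

    screen: CoexpressionScreen
    bias_reports: dict[str, BiasReport]
    enrichment_tables: dict[str, list[EnrichmentRecord]]
    tf_ranking: TFRanking | None
    motif_hits: list[MotifHit]
    metadata: dict


def _sci(x: float) -> str:
    return f"{x:.6g}"


def _write_screen(screen: CoexpressionScreen, path: Path) -> None:
    lines = ["gene\tr\tp\tq\tclass\tdegenerate"]
    for rec in screen.records:
        lines.append(
            f"{rec.gene}\t{_sci(rec.r)}\t{_sci(rec.p)}\t{_sci(rec.q)}"
            f"\t{rec.klass}\t{int(rec.degenerate)}"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_enrichment(records: list[EnrichmentRecord], path: Path) -> None:
    lines = ["rank\tterm\tk\tK\tn\tN\tp\tq"]
    for rec in records:
        lines.append(
            f"{rec.rank}\t{rec.term}\t{rec.k}\t{rec.K}\t{rec.n}\t{rec.N}"
            f"\t{_sci(rec.p)}\t{_sci(rec.q)}"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_hits(hits: list[MotifHit], path: Path) -> None:
    lines = ["start_tss\tend_tss\tstrand\tscore"]
    for h in hits:
        lines.append(f"{h.start_tss}\t{h.end_tss}\t{h.strand}\t{_sci(h.score)}")
    path.write_text("\n".join(lines) + "\n")


def _bias_dict(rep: BiasReport) -> dict:
    fmt = rep.formatted()
    return {
        "set_name": rep.set_name,
        "n_set": rep.n_set,
        "n_background": rep.n_background,
        "set_counts": rep.set_counts,
        "background_counts": rep.background_counts,
        "proportion_negative_set_pct": fmt["proportion_negative_set"],
        "proportion_negative_background_pct": fmt[
            "proportion_negative_background"
        ],
        "fisher_p_negative": rep.fisher_p_negative,
        "sign_test_p": rep.sign_test_p,
        "two_proportion_p": rep.two_proportion_p,
    }


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Run every configured stage and write the report tables."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = read_expression(cfg.expression_path, dialect=cfg.expression_dialect)
    if cfg.quantile_normalize:
        matrix = quantile_normalize(matrix)
    logger.info("loaded %d genes x %d samples", matrix.n_genes, matrix.n_samples)

    summary = summarize_gene(matrix, cfg.query)
    screen = screen_coexpression(matrix, cfg.query, cfg.r_min, cfg.q_max)
    logger.info(
        "screen: m_tested=%d positive=%d negative=%d",
        screen.m_tested, screen.count("positive"), screen.count("negative"),
    )
    _write_screen(screen, out / "screen.tsv")

    bias_reports: dict[str, BiasReport] = {}
    for p in cfg.gene_list_paths:
        gs = read_gene_list(p)
        bias_reports[gs.name] = bias_analysis(screen, gs)

    universe = set(matrix.gene_ids)
    query_members = {
        "all": screen.members("positive") + screen.members("negative"),
        "negative": screen.members("negative"),
        "positive": screen.members("positive"),
    }[cfg.enrichment_query]
    enrichment_tables: dict[str, list[EnrichmentRecord]] = {}
    tf_ranking: TFRanking | None = None
    if query_members:
        query_set = GeneSet(
            name=f"{screen.query}_correlates_{cfg.enrichment_query}",
            members=frozenset(query_members),
        )
        for p in cfg.library_paths:
            lib = read_gmt(p)
            enrichment_tables[lib.name] = enrich_sets(
                query_set, lib, universe, q_cut=cfg.enrichment_q_cut
            )
            _write_enrichment(
                enrichment_tables[lib.name], out / f"enrichment_{lib.name}.tsv"
            )
        if cfg.tf_library_path:
            tf_lib = read_gmt(cfg.tf_library_path)
            tf_ranking = prioritize_tfs(query_set, tf_lib, universe)
            _write_enrichment(
                [rec for _, rec in tf_ranking.entries], out / "tf_ranking.tsv"
            )
    else:
        logger.warning("no correlated genes passed the screen; "
                       "enrichment stages skipped")

    motif_hits: list[MotifHit] = []
    if cfg.pfm_path and cfg.promoter_path:
        pfm = read_jaspar_pfm(cfg.pfm_path)
        promoter = read_promoter_fasta(cfg.promoter_path, cfg.tss_offset)
        pwm = pwm_from_counts(pfm)
        motif_hits = scan_sequence(
            pwm, promoter, min_fraction=cfg.scan_min_fraction
        )
    else:
        logger.info("promoter scan skipped (no PFM/promoter configured)")
    _write_hits(motif_hits, out / "motif_hits.tsv")

    config_hash = hashlib.sha256(
        json.dumps(cfg.__dict__, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    metadata = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": config_hash,
        "query": screen.query,
        "n_genes": matrix.n_genes,
        "n_samples": matrix.n_samples,
        "m_tested": screen.m_tested,
        "universe_size": len(universe),
        "query_summary": {
            "min_percentile_rank": summary.min_percentile_rank,
            "fold_range": summary.fold_range,
            "sd_log2": summary.sd_log2,
        },
        "class_counts": {
            k: screen.count(k) for k in ("positive", "negative", "none")
        },
    }
    bundle = ReportBundle(
        screen=screen,
        bias_reports=bias_reports,
        enrichment_tables=enrichment_tables,
        tf_ranking=tf_ranking,
        motif_hits=motif_hits,
        metadata=metadata,
    )
    summary_json = {
        "metadata": metadata,
        "bias_reports": {k: _bias_dict(v) for k, v in bias_reports.items()},
        "tf_top10": (
            [
                {"tf": name, "rank": rec.rank, "p": rec.p, "q": rec.q,
                 "k": rec.k, "K": rec.K}
                for name, rec in tf_ranking.top(10)
            ]
            if tf_ranking
            else []
        ),
        "n_motif_hits": len(motif_hits),
    }
    (out / "summary.json").write_text(json.dumps(summary_json, indent=2) + "\n")
    return bundle
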