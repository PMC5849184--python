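"""Seeded synthetic datasets with planted guilt-by-association structure.

The generator emulates the statistical shape of a large microarray
panel on the log2 scale with a single latent factor F per sample:

* a *hub* gene (the query of the screen) loaded on F, with a raised
  mean so it sits above the 95th percentile of gene expression in every
  sample, and a small within-gene SD so its linear fold range stays
  below ~2;
* a *TF* gene loaded on F so that corr(hub, TF) equals ``r_hub_tf``
  (default 0.18);
* a *module* of genes loaded negatively on F so that corr(module, hub)
  equals ``r_module_hub`` (default -0.35), with an inflated SD
  (``module_extra_sd``) so SD-comparison tests have a real effect to
  find;
* independent Gaussian background genes with dispersed means.

Alongside the matrix the generator emits the matched curated gene list
(module members plus random distractors — the "immune list" analogue), a
TF-target library whose planted TF targets the module plus the hub with
size-matched random decoy TFs, and a ground-truth record for recovery
tests.  A separate helper plants a motif consensus into a random
promoter.  All outputs are exact functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .data_io import ExpressionMatrix, GeneSet, GeneSetLibrary, PromoterSequence
from .promoter_scan import PositionFrequencyMatrix, consensus_of, tss_to_offset

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_dataset",
    "generate_promoter",
    "export_dataset",
    "demo_pfm",
]

_TISSUES = ("lung", "breast", "cns", "haematopoietic", "skin", "kidney")


@dataclass
class SyntheticConfig:
    """Parameters of the planted-structure generator.

    Effect sizes are population correlations; means and SDs are on the
    log2-intensity scale.  ``module_extra_sd`` multiplies the module
    genes' total SD by (1 + module_extra_sd) without touching their
    correlation with the hub.
    """

    n_genes: int = 2000
    n_samples: int = 400
    hub_name: str = "HUB1"
    tf_name: str = "TF1"
    module_size: int = 50
    r_hub_tf: float = 0.18
    r_module_hub: float = -0.35
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    gene_mean_sd: float = 1.0
    hub_percentile_boost: float = 3.5
    hub_sd_log2: float = 0.15
    module_extra_sd: float = 0.5
    n_distractors: int = 150
    n_decoy_tfs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size + 2 > self.n_genes:
            raise ValueError("n_genes must exceed module_size + 2")
        if not (abs(self.r_hub_tf) < 1 and abs(self.r_module_hub) < 1):
            raise ValueError("planted correlations must lie in (-1, 1)")
        if self.module_extra_sd < 0:
            raise ValueError("module_extra_sd must be non-negative")
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")

    def _hub_loading(self) -> float:
        # hub loading a with module loading r_module_hub/a and TF loading
        # r_hub_tf/a gives the two planted correlations exactly
        return max(np.sqrt(abs(self.r_module_hub)), np.sqrt(abs(self.r_hub_tf)))


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    hub_name: str
    tf_name: str
    module_members: frozenset[str]
    distractor_members: frozenset[str]
    r_hub_tf: float
    r_module_hub: float
    decoy_tf_names: tuple[str, ...]
    seed: int
    config: dict = field(default_factory=dict)


def _correlated_noise(
    rng: np.random.Generator, factor: np.ndarray, loading: float, size: int
) -> np.ndarray:
    """Rows with population correlation ``loading`` to the latent factor."""
    noise = rng.standard_normal((size, factor.size))
    return loading * factor[None, :] + np.sqrt(1.0 - loading**2) * noise


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, GeneSetLibrary, GeneSet, SyntheticTruth]:
    """Generate (expression matrix, TF-target library, curated list, truth)."""
    rng = np.random.default_rng(cfg.seed)
    n_bg = cfg.n_genes - 2 - cfg.module_size
    if cfg.n_distractors > n_bg:
        raise ValueError("n_distractors exceeds available background genes")

    F = rng.standard_normal(cfg.n_samples)
    a = cfg._hub_loading()
    tf_load = cfg.r_hub_tf / a if a > 0 else 0.0
    mod_load = cfg.r_module_hub / a if a > 0 else 0.0

    hub = (
        cfg.baseline_mean
        + cfg.hub_percentile_boost
        + cfg.hub_sd_log2 * _correlated_noise(rng, F, a, 1)[0]
    )
    tf = (
        cfg.baseline_mean
        + 1.0  # the planted regulator is itself well expressed
        + cfg.baseline_sd * _correlated_noise(rng, F, tf_load, 1)[0]
    )
    module_means = cfg.baseline_mean + rng.normal(
        0.0, cfg.gene_mean_sd, cfg.module_size
    )
    module = (
        module_means[:, None]
        + cfg.baseline_sd
        * (1.0 + cfg.module_extra_sd)
        * _correlated_noise(rng, F, mod_load, cfg.module_size)
    )
    bg_means = cfg.baseline_mean + rng.normal(0.0, cfg.gene_mean_sd, n_bg)
    background = bg_means[:, None] + cfg.baseline_sd * rng.standard_normal(
        (n_bg, cfg.n_samples)
    )

    module_names = [f"MOD{i:04d}" for i in range(cfg.module_size)]
    bg_names = [f"G{i:05d}" for i in range(n_bg)]
    gene_ids = [cfg.hub_name, cfg.tf_name] + module_names + bg_names
    values = np.vstack([hub[None, :], tf[None, :], module, background])

    # shuffle gene order so planted structure is not positional
    perm = rng.permutation(cfg.n_genes)
    gene_ids = [gene_ids[i] for i in perm]
    values = values[perm]

    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    tissues = {
        s: _TISSUES[int(t)]
        for s, t in zip(sample_ids, rng.integers(0, len(_TISSUES), cfg.n_samples))
    }
    matrix = ExpressionMatrix(
        gene_ids=gene_ids, sample_ids=sample_ids, values=values,
        tissue_of_sample=tissues,
    )

    distractors = rng.choice(n_bg, size=cfg.n_distractors, replace=False)
    distractor_names = frozenset(bg_names[i] for i in distractors)
    curated = GeneSet(
        name="PLANTED_SET",
        members=frozenset(module_names) | distractor_names,
        description="planted module plus random distractors",
    )

    target_size = cfg.module_size + 1
    planted_targets = frozenset(module_names) | {cfg.hub_name}
    tf_sets = [
        GeneSet(name=cfg.tf_name, members=planted_targets,
                description="planted TF targets")
    ]
    decoy_names = []
    for i in range(cfg.n_decoy_tfs):
        decoy = f"DECOYTF{i:02d}"
        decoy_names.append(decoy)
        targets = rng.choice(cfg.n_genes, size=target_size, replace=False)
        tf_sets.append(
            GeneSet(name=decoy,
                    members=frozenset(gene_ids[j] for j in targets),
                    description="decoy TF targets")
        )
    library = GeneSetLibrary(name="TF_TARGETS", sets=tf_sets)

    truth = SyntheticTruth(
        hub_name=cfg.hub_name,
        tf_name=cfg.tf_name,
        module_members=frozenset(module_names),
        distractor_members=distractor_names,
        r_hub_tf=cfg.r_hub_tf,
        r_module_hub=cfg.r_module_hub,
        decoy_tf_names=tuple(decoy_names),
        seed=cfg.seed,
        config=asdict(cfg),
    )
    return matrix, library, curated, truth


def generate_promoter(
    length: int,
    pfm: PositionFrequencyMatrix,
    plant_at_tss: tuple[int, int],
    gc: float = 0.5,
    seed: int = 0,
    tss_offset: int | None = None,
) -> PromoterSequence:
    """Random promoter with the PFM consensus planted at a TSS interval.

    Background bases are i.i.d. with the given GC content; the consensus
    string overwrites the interval ``plant_at_tss = (start, end)`` given
    in TSS coordinates (inclusive, no position 0).  ``tss_offset``
    defaults to ``length`` (the whole sequence upstream of the TSS).

    The background is redrawn (deterministically, seeded) if the exact
    consensus or its reverse complement occurs by chance outside the
    planted interval, so the planted site is always the unique
    maximal-score match.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must lie in (0, 1)")
    if tss_offset is None:
        tss_offset = length
    if not 0 <= tss_offset <= length:
        raise ValueError("tss_offset outside sequence")
    start, end = plant_at_tss
    s_off = tss_to_offset(start, tss_offset)
    e_off = tss_to_offset(end, tss_offset)
    consensus = consensus_of(pfm)
    if e_off - s_off + 1 != len(consensus):
        raise ValueError(
            f"interval {plant_at_tss} spans {e_off - s_off + 1} bases but the "
            f"motif consensus has {len(consensus)}"
        )
    if s_off < 0 or e_off >= length:
        raise ValueError(f"interval {plant_at_tss} outside the promoter")
    from .promoter_scan import reverse_complement

    rc = reverse_complement(consensus)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    for attempt in range(100):
        rng = np.random.default_rng([seed, attempt])
        bases = rng.choice(list("ACGT"), size=length, p=probs)
        bases[s_off : e_off + 1] = list(consensus)
        seq = "".join(bases)
        spurious = [
            i
            for pat in {consensus, rc}
            for i in range(length - len(consensus) + 1)
            if i != s_off and seq[i : i + len(consensus)] == pat
        ]
        if not spurious:
            return PromoterSequence(
                id=f"synthetic_promoter_seed{seed}",
                sequence=seq,
                tss_offset=tss_offset,
            )
    raise RuntimeError(
        "could not draw a background free of chance consensus matches; "
        "motif too short for this promoter length"
    )


def export_dataset(
    outdir,
    matrix: ExpressionMatrix,
    library: GeneSetLibrary,
    curated: GeneSet,
    truth: SyntheticTruth,
    pfm: PositionFrequencyMatrix | None = None,
    promoter: PromoterSequence | None = None,
) -> dict[str, str]:
    """Write a generated dataset to disk in the standard input formats.

    Emits expression.tsv, the curated gene list, the TF-target GMT,
    optionally a JASPAR-style PFM and promoter FASTA, and truth.json.
    Returns a name → path map usable directly in a pipeline config.
    """
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    expr = outdir / "expression.tsv"
    with expr.open("w") as fh:
        fh.write("GENE\t" + "\t".join(matrix.sample_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            fh.write(g + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    paths["expression"] = str(expr)

    lst = outdir / f"{curated.name}.txt"
    lst.write_text("\n".join(sorted(curated.members)) + "\n")
    paths["gene_list"] = str(lst)

    gmt = outdir / f"{library.name}.gmt"
    with gmt.open("w") as fh:
        for s in library:
            fh.write(
                s.name + "\t" + (s.description or "-") + "\t"
                + "\t".join(sorted(s.members)) + "\n"
            )
    paths["tf_library"] = str(gmt)

    if pfm is not None:
        pfm_path = outdir / f"{pfm.name}.pfm"
        with pfm_path.open("w") as fh:
            fh.write(f">{pfm.name}\n")
            for base, row in zip("ACGT", pfm.counts):
                fh.write(
                    f"{base} [ " + " ".join(f"{c:g}" for c in row) + " ]\n"
                )
        paths["pfm"] = str(pfm_path)

    if promoter is not None:
        fasta = outdir / "promoter.fa"
        fasta.write_text(
            f">{promoter.id} tss={promoter.tss_offset}\n{promoter.sequence}\n"
        )
        paths["promoter"] = str(fasta)

    truth_path = outdir / "truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "hub_name": truth.hub_name,
                "tf_name": truth.tf_name,
                "module_members": sorted(truth.module_members),
                "distractor_members": sorted(truth.distractor_members),
                "r_hub_tf": truth.r_hub_tf,
                "r_module_hub": truth.r_module_hub,
                "decoy_tf_names": list(truth.decoy_tf_names),
                "seed": truth.seed,
                "config": truth.config,
            },
            indent=2,
        )
        + "\n"
    )
    paths["truth"] = str(truth_path)
    return paths


def demo_pfm(name: str = "SYNTF_MOTIF") -> PositionFrequencyMatrix:
    """A small synthetic forkhead-like count matrix (consensus GTAAACAA).

    Synthetic stand-in for a curated database profile; counts are 20
    observations per column with a dominant base and light off-consensus
    counts.
    """
    consensus = "GTAAACAA"
    counts = np.full((4, len(consensus)), 1.0)
    base_index = {b: i for i, b in enumerate("ACGT")}
    for j, b in enumerate(consensus):
        counts[base_index[b], j] = 17.0
    return PositionFrequencyMatrix(name=name, counts=counts)
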