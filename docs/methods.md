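# Methods

## Scope and model

`coexkit` implements a single-query guilt-by-association analysis over a
gene-by-sample log2 expression matrix: a genome-wide Pearson
coexpression screen, directional-bias statistics for curated gene sets
among the correlates, offline gene-set over-representation (including
TF-target prioritization), and PWM promoter scanning.  The package
assumes gene-level, complete (no missing values), approximately
continuous log2 intensities; probe summarization and normalization of
raw arrays are upstream of its scope, except for quantile normalization,
which it provides.

## Coexpression screen

For query *q* and each other gene *g* over *n* samples the screen
computes the sample Pearson correlation and the exact parametric
two-sided p-value through *t = r·√((n−2)/(1−r²))* with *n−2* df.
Conventions, each chosen to keep the screen's contract sharp:

- **One BH family per screen.**  Benjamini–Hochberg is applied once over
  all genes with defined r (`m_tested`); the query is excluded from its
  own screen.
- **Zero-variance genes are undefined, not non-significant.**  They are
  flagged degenerate, classified `none`, and excluded from the BH family
  rather than assigned p = 1, which would deflate every other gene's q.
- **Strict cuts.**  `positive` ⇔ r > r_min and q < q_max; `negative` ⇔
  r < −r_min and q < q_max.  Defaults r_min = 0.2, q_max = 1e-4
  (FDR < 0.01%).  At panel scale (n ≈ 1000, m ≈ 20,000) the p-value at
  |r| = 0.2 is ~8×10⁻¹¹, so the effect-size cut dominates the FDR cut;
  at small n the FDR cut dominates instead, which matters when running
  the pipeline on small matrices.
- **|r| within 1e-14 of 1 is snapped to ±1** and reported with the
  smallest positive float as p (the t transform diverges there).
- Records are sorted by descending r, gene symbol as tie-break,
  degenerate genes last.

## Quantile normalization

The reference distribution is the vector of rank-wise means of the
per-sample order statistics; each sample's value at within-sample rank
*i* becomes reference[i], and tied values within a sample receive the
mean of the reference values over their tied ranks.  On tie-free data
the transform is idempotent and leaves every sample with the identical
sorted vector.  Ties are preserved as ties; when tie patterns differ
between samples, the post-transform columns agree only up to
tie-averaging — an unavoidable property of any tie-respecting rule, and
immaterial for continuous intensity data.

## Expression summaries

Percentile rank of a gene in a sample is 100·(#genes ≤ value)/(#genes)
(weak inequality), and the reported statistic is its minimum over
samples, so "min_percentile_rank ≥ 95" means the gene sits above the
95th percentile in *every* sample.  Fold range is linear-scale,
2^(max−min) of the log2 values.  `sd_log2` is the population SD.

## Exact tests and their two-sided convention

Fisher's exact test, the binomial sign test and the hypergeometric
upper tail are evaluated from the corresponding scipy distributions;
two-sided p-values use the minimum-likelihood definition (sum of all
outcomes with point probability ≤ the observed, with 1e-7 relative
slack for floating-point ties), matching the convention of the common
statistical environments.  The test suite verifies them exhaustively
against exact rational-arithmetic enumeration (every 2×2 table with
total ≤ 40; every sign-test outcome with n ≤ 40; every hypergeometric
configuration with N ≤ 60).

### Bias reports

A set's negative-class contingency removes set members from the
background column (rows must be disjoint for the Fisher test), but the
report additionally carries the *paper-style* background proportion —
genome-wide negative count over the full background total — because
that is how published contingency figures quote their denominators.
The sign test uses only the genes inside the set that passed either
cut: k = positive count, n = positive + negative, p0 = 0.5.  Percents
are rendered at one decimal with round-half-to-even from exact rational
arithmetic.

### KDE

Gaussian KDE is computed directly from its definition.  The automatic
bandwidth is the robust Silverman rule h = 0.9·min(sd, IQR/1.34)·n^(−1/5)
(sample SD, ddof = 1); when one scale estimate is zero the other is
used, and fully constant data falls back to h = 1 so the estimate stays
defined.

## Over-representation and TF prioritization

Per term: k = |query ∩ term ∩ universe|, K = |term ∩ universe|,
n = |query ∩ universe|, N = |universe|, p = P(X ≥ k) with k = 0 pinned
to p = 1.  Terms with K = 0 are dropped *before* BH — they carry no
information and would distort the family size.  Ranking is ascending q,
then ascending p, then descending k, then term name, which makes
rankings fully deterministic.  The universe defaults to the genes of
the loaded expression matrix; web enrichment tools keep their own,
unpublished backgrounds, so their p-values are reproduced here in order
of magnitude rather than digit for digit (the package's consistency
check: the 20/73 overlap among 1,339 query genes in an 18,901-gene
universe gives p ≈ 1.0×10⁻⁷ against a printed 8.1×10⁻⁷, whose printed
adjusted value corresponds to a ~261-term BH family at rank 1).
One-tailed over-representation only; depletion is out of scope, as in
the web tools this replaces.

## Promoter scanning

PWM weights are log2((count + pc·bg)/((colsum + pc)·bg)) with total
pseudocount pc = 1 distributed by the background (uniform by default).
Both strands of every window are scored (reverse strand via the
reverse-complemented matrix); windows containing N are skipped; all
hits above threshold are reported without overlap masking.  The
threshold is given either absolutely or as a fraction of the consensus
score (the sum of column maxima).  TSS coordinates follow the promoter
convention with no position 0: sequence offset minus TSS offset,
incremented by one on the non-negative side.  Published motif scores
from database scanners depend on their (often unstated) pseudocount and
background conventions; identical site geometry, not identical score
values, is the reproducible quantity.

## Synthetic data generator

A single latent factor F ~ N(0,1) per sample induces all planted
correlations: a gene with loading λ is λ·F + √(1−λ²)·ε on a unit scale,
so a pair with loadings λ₁, λ₂ has population correlation λ₁λ₂.  With
hub loading a = max(√|r_module_hub|, √|r_hub_tf|), TF loading
r_hub_tf/a and module loading r_module_hub/a, the generator hits the
two planted correlations exactly for any values in (−1,1).

Defaults are the study conditions the recovery tests assume:

| parameter | default | why |
|---|---|---|
| n_genes | 2,000 | scaled-down genome; keeps 100-seed sweeps fast while leaving the BH family realistically large |
| n_samples | 400 | large-panel regime: at r = −0.35 the screen's strict cuts are passed with wide margin, as in the real panel |
| module_size / n_distractors | 50 / 150 | a curated list in which ~25% of members are true correlates, qualitatively matching the published immune-list split |
| r_hub_tf | 0.18 | the hub–TF coupling the analysis is meant to detect |
| r_module_hub | −0.35 | comfortably past the −0.2 screen threshold at n = 400; the screen publishes thresholds, not true effect sizes, and recovery tests need headroom |
| baseline_mean / baseline_sd | 7.0 / 1.0 log2 units | typical intensity scale of RMA-style microarray data |
| gene_mean_sd | 1.0 | cross-gene mean dispersion, so percentile ranks are non-trivial |
| hub_percentile_boost | 3.5 | places the hub above the 95th percentile in every sample at the defaults |
| hub_sd_log2 | 0.15 | a highly expressed, low-variability hub: linear fold range ≈ 1.9 across 400 samples |
| module_extra_sd | 0.5 | module genes get 1.5× the background SD — a real effect for the SD-comparison test — implemented as a scale factor so the planted correlation is untouched |
| n_decoy_tfs | 20 | decoy TF target sets drawn uniformly, size-matched to the planted TF's, so rank-1 recovery is non-trivial |

Gene order is shuffled so planted structure is never positional.  The
promoter generator redraws its i.i.d. background (seeded sub-streams,
deterministic) if the exact consensus or its reverse complement occurs
by chance away from the planted site, so the planted site is always the
unique maximal-score match.

What the generator does **not** emulate: tissue-driven covariance
blocks, heavy-tailed and heteroskedastic intensity noise, probe
saturation, correlated gene modules other than the planted one, and
overlap between TF target sets.  Passing recovery tests therefore shows
the pipeline's statistics behave correctly under the planted model, not
that the thresholds are optimal for any particular real panel.

## Numerical choices

- BH via the standard step-up implementation; verified against the
  definitional double-loop oracle.
- Hypergeometric tails via the survival function (log-space
  internally); exact-rational oracles in tests.
- Degenerate distribution comparisons (all values identical in both
  groups) return (0, 1) with a warning instead of NaN.
- All generator randomness flows through `numpy.random.default_rng`
  seeded from the config; identical (config, seed, version) gives
  byte-identical outputs, which the pipeline's rerun test asserts.

## Known limitations

- Pearson-only screening: rank-based alternatives (Spearman) are not
  provided, so the screen inherits Pearson's sensitivity to outliers
  and monotone-nonlinear relationships.
- The classification is marginal per gene; no attempt is made to
  deconvolve the correlation structure among correlates (partial
  correlations, network inference).
- Enrichment p-values assume a fixed, correctly specified universe;
  results shift with the universe, which is why the engine logs it.
- The promoter scanner handles only the N ambiguity code and reports
  raw log-odds scores; no p-value calibration of motif scores is
  attempted.
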