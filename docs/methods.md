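# Methods

## Problem and pipeline

`tbgenes` implements a pan-tissue analysis of *tissue-biased genes*: genes
expressed at least two-fold higher in one tissue than in every other
tissue, with statistical significance against every other tissue.  The
pipeline discovers such genes from a multi-tissue normal expression
matrix, summarizes their activity per sample/cell as a signature score,
contrasts tumors against matched adjacent-normal tissue (NAT), screens for
tissue-biased genes coupled to a stemness program at both bulk and
single-cell level, and stratifies survival by the tissue-biased (TB)
score.  A synthetic-data generator with a ground-truth ledger provides
inputs with exactly the structure these analyses assume, so every stage
can be tested as a recovery problem.

## Tissue-biased gene discovery

For gene *g* and tissue *t* the fold-change summary is

    min_log2fc(g, t) = min over u != t of log2((mean_t(g) + pc) / (mean_u(g) + pc))

with group means on the **linear** abundance scale (log2 input is
de-logged first) and pseudocount `pc = 0.01` guarding silent genes.  The
significance summary is the **maximum** p-value over one-sided
(target-greater) two-sample tests of tissue *t* against each other tissue —
the weakest pairwise link.  The default test is the Wilcoxon rank-sum
(Mann–Whitney) test, with a Welch t option.  Worst-case p-values are
Benjamini–Hochberg adjusted across the full (gene, tissue) grid and a gene
is called tissue-biased when `min_log2fc >= log2(2)` and `q < 0.05`.

Both clauses deliberately use the *every-pairwise* reading of "higher than
all other tissues" rather than tissue-vs-pooled-rest: pooling can be
dominated by a few low-expressing tissues and would dilute the claim.
With a fold threshold above 1 the min-over-others construction makes calls
mutually exclusive across tissues (at most one tissue can exceed all
others by more than one-fold); the caller asserts this.

Fold changes are ratios of linear means (not means of logs) because a
"two-fold higher expression level" is a statement about abundances.  The
rank-sum default makes calls invariant to any global rescaling of the
data, up to the (negligible at normal abundances) pseudocount.

## Signature scoring

Two scorers, both self-contained within the scored matrix (no external
reference population):

* **zmean** (default): each member gene is standardized across samples on
  the log2 scale (linear input is `log2(x + 1)`-transformed; sd uses
  ddof = 1); a sample's score is the mean z-value over member genes.
  Scores are in z-units and average to 0 across the matrix.  Zero-variance
  members are dropped with a warning.
* **rank**: a sample's score is the mean normalized rank (in (0, 1]) of the
  member genes among all genes in that sample.  This is invariant to any
  strictly monotone per-cell transform of expression and is the robust
  choice for sparse single-cell counts.

Group comparisons use two-sided rank-sum tests with BH adjustment; score
trends along pseudotime use Spearman correlation, with constant inputs
returned as flagged degenerate results instead of NaN surprises.

## Tumor vs NAT contrast and enrichment

Differential expression reports `log2fc = log2((mean_T + pc)/(mean_N + pc))`
on linear means and a two-tailed independent t-test (Welch by default; a
paired option exists because matched tumor/NAT designs are common) on log2
values.  "Significantly downregulated" means `q < 0.05` with no extra
fold-change gate by default; an optional `|log2fc|` gate is exposed.
Zero-variance degenerate groups resolve to the noise-free limit (p = 0 for
unequal means, p = 1 for equal) rather than NaN.  Over-representation of a
gene set in a pathway is the exact upper-tail hypergeometric probability
P(X >= overlap).  All BH adjustments in the package flow through one shared
routine (`scipy.stats.false_discovery_control`, cross-checked in the test
suite against the step-up formula evaluated by hand).

## Dual-level stemness screen

For each screened gene the Spearman correlation with the stemness
signature score is computed twice: across bulk tumor samples and across
single cells.  Spearman is used (rather than Pearson) because expression
is skewed and single-cell counts are rank-like.  The downregulation axis
is `max(0, -log2fc)` min–max standardized to [0, 1] across the screened
genes.  A candidate must pass, at **both** levels, `rho <= -corr_gate` and
`q < alpha`, plus `down_effect_std >= effect_gate`; defaults are
corr_gate = 0.3, alpha = 0.05, effect_gate = 0.5.  Selected genes are
ranked by the equal-weight composite mean of |bulk rho|, |sc rho| and the
standardized effect, ties broken by gene ID, so the ranking is
deterministic and permutation-invariant.  The composite is a pragmatic
operationalization of "top candidates"; the three components are on
comparable 0–1 scales, and no weighting scheme is claimed optimal.
Strengthening any gate can only shrink the candidate set (tested as a
property).

## Survival stratification

Subjects are split at the score median: high = score > median, low =
score <= median, so median ties deterministically go low.  The
Kaplan–Meier estimator and the two-group log-rank test are implemented
directly from their risk-table definitions (they are the unit under test
for this module; `lifelines` serves as an independent oracle in the test
suite, never as the implementation).  Tied event times use aggregated risk
sets; no Cox model is fitted, so no Efron/Breslow choice arises.  The KM
median is the smallest time with S(t) <= 0.5 (infinity when never
reached).

## Synthetic-data generator

* **Bulk normals**: log-normal expression — gene baselines
  `mu_g ~ N(baseline_log_mean = 3, baseline_log_sd = 1)` in log2 units,
  within-group noise `N(0, noise_sd = 0.5)`.  Each planted TB gene gains
  `planted_log2fc = 2` in its home tissue.  Defaults: 5 tissues x 40 TB
  genes (= 200 planted TB genes), 300 background genes, 50 stemness genes,
  30 samples/tissue — sizes chosen once for test power at desk scale, not
  to mimic any cohort.
* **Tumor/NAT pairs** (default 40): NAT follows the tissue's normal model;
  tumor subtracts the planted downregulation (`tumor_down_log2fc = 1`,
  applied to a random `frac_tb_down = 0.5` of each tissue's TB genes).  A
  per-tumor latent stemness activity `s ~ N(0,1)` adds `+1.0*s` (log2) to
  stemness genes and `stemness_coupling * s` to the candidate genes, so
  candidates anti-correlate with the bulk stemness score.  Candidates
  (default 4, drawn from the focal tissue's down genes) carry
  `candidate_down_multiplier = 2` times the downregulation, making them the
  strongest effects on the screen's y-axis.
* **Single-cell trajectory** (default 2000 cells): pseudotime t ~ U(0, 1);
  Poisson counts with log-normal rates.  The focal tissue's TB program
  decays linearly by `2.5 * |stemness_coupling|` log2 units over the
  trajectory (candidates 1.5x faster); the stemness program rises by 2.0
  log2 units.  Scaling the decay by |coupling| makes the two programs
  exactly decoupled at coupling 0 and strongly anti-correlated at the
  default coupling of -0.8 (the realized program-score Spearman correlation
  at default noise is stronger than -0.8; the parameter sets the sign and
  strength of the planted dependence, not the exact attained rho).
  Cluster labels are equal-occupancy pseudotime bins.
* **Survival**: event times are exponential with hazard
  `baseline_hazard * exp(-survival_coupling * z)` where z is the
  standardized score, i.e. the coupling is the log hazard ratio per score
  SD (standardizing internally keeps the planted effect meaningful across
  scoring methods; the log hazard remains linear in the negative score).
  Censoring is an independent exponential at `censor_rate = 0.02` against
  `baseline_hazard = 0.1` (roughly 15–20% censoring under the null).

One global seed drives numbered substreams (`SeedSequence(seed,
spawn_key=(stage,))`), so identical configs are bit-reproducible and each
stage can be regenerated alone.  The truth ledger records the gene→tissue
map, the down-regulated and candidate sets (candidates ⊆ down ⊆ TB, an
enforced invariant), per-gene planted effects and baselines.

What the generator does **not** emulate: doublets, ambient RNA, library-
size variation, batch effects, raw methylation/CNV data (only categorical
alteration labels are supported downstream), and inferred pseudotime — the
trajectory exports its true ordering, since trajectory inference is out of
scope.  Passing recovery tests therefore demonstrate correctness of the
statistics under the stated generative model, not robustness to those
real-data artifacts.

## Numerical choices and degenerate inputs

* Pseudocounts: 0.01 on linear ratios (fold changes, DE), 1.0 inside
  `log2(x + 1)` when z-scoring linear data.
* BH on empty input returns empty; p-values outside [0, 1] raise.
* Constant genes are excluded from correlation screens (flagged) and from
  zmean scoring (warned); constant scores make trends/splits degenerate
  (flagged result or `DegenerateSplitError`).
* All-equal downregulation effects give 0.5 everywhere with a warning
  (degenerate min–max scale).
* Log-rank with zero variance (e.g. all events in one risk-set pattern)
  returns statistic 0, p 1.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the generator at its
default conditions: 20 seeds for discovery recovery (5 tissues x 30
samples, 550 genes), 20 seeds for the screen (200 TB genes, 40 tumor
pairs, 2000 cells), 1000 null cohorts of n = 100 for log-rank calibration,
and 20 cohorts of n = 300 for the survival-direction check.  These sizes
give Monte-Carlo error comfortably inside the asserted bands while keeping
a full run in the tens of seconds on one CPU.

## Known limitations

* The discovery step's pairwise reading and rank-sum default are one
  defensible convention; tissue-vs-pooled contrasts and the t-test remain
  available as options but are untested against real multi-tissue corpora.
* zmean scoring assumes roughly comparable per-sample depth; use the rank
  scorer when that fails.
* The screen's composite ranking weights its three components equally;
  with very unequal measurement precision between levels a weighted rank
  would be preferable.
* Survival handling is two-group log-rank only — no covariate adjustment,
  no competing risks.
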