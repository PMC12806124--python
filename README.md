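# tbgenes

Analysis pipeline for **tissue-biased genes** in cancer transcriptomics:
genes expressed at least two-fold higher in one tissue than in *every*
other tissue, with statistical significance against every other tissue.
Such genes tend to be silenced in matched tumors, and their loss tracks
stemness gain along tumor-evolution trajectories and worse survival —
`tbgenes` turns that analysis into a tested, reusable library and CLI for
computational biologists working with bulk and single-cell expression
data.

## What it computes

For gene *g* and tissue *t*, with linear-scale group means and pseudocount
*pc*:

```
min_log2fc(g, t) = min_{u != t}  log2( (mean_t(g) + pc) / (mean_u(g) + pc) )
max_p(g, t)      = max_{u != t}  p_one-sided( samples_t(g) > samples_u(g) )
is_tb(g, t)      = [ min_log2fc >= 1 ]  and  [ BH(max_p) < 0.05 ]
```

Around that definition the package provides:

* **discovery** — the caller above (Wilcoxon rank-sum default, Welch t
  option), BH across the full (gene, tissue) grid; mutually exclusive
  calls by construction.
* **scoring** — per-sample/per-cell signature scores for any gene set:
  mean z-value of the members (`zmean`, z-units) or mean normalized rank
  (`rank`, monotone-transform invariant); group summaries and
  score-vs-pseudotime Spearman trends.
* **contrast** — tumor vs NAT differential expression (two-tailed
  independent t-test, BH), tissue-biased-and-downregulated gene
  classification, alteration-group (e.g. methylation category) tests,
  set intersections with Jaccard, and exact hypergeometric pathway
  enrichment.
* **screen** — the dual-level candidate screen: per-gene Spearman
  correlation with the stemness score across bulk samples *and* across
  single cells, downregulation min–max standardized to [0, 1], gates on
  both correlation levels plus effect size, composite ranking.
* **survival** — median-split stratification with a from-scratch
  Kaplan–Meier estimator and two-group log-rank test.
* **synthetic** — a generator that plants all of the above structure
  (tissue-biased effects, tumor downregulation, a stemness-coupled
  single-cell trajectory, score-coupled survival) with a ground-truth
  ledger, so every stage is testable as a recovery problem.

## Worked example

```python
from scipy.stats import spearmanr
from tbgenes import (SimConfig, simulate_study, discover_tb_genes,
                     differential_expression, score_signature,
                     correlate_with_stemness, standardize_effect,
                     select_candidates, stratify_survival)

study = simulate_study(SimConfig(seed=1))     # 5 tissues, 200 planted TB genes

tb = discover_tb_genes(study.bulk, study.design)
print(int(tb["is_tb"].sum()))                 # 200  (all planted genes found)

genes = sorted(study.truth.tb_gene_map)
de = differential_expression(study.tumor_nat.tumor, study.tumor_nat.nat, genes)
print((de["direction"] == "down").sum())      # 20   (focal tissue's down genes)

stem = study.gene_sets["STEMNESS"]
bulk = correlate_with_stemness(
    study.tumor_nat.tumor, score_signature(study.tumor_nat.tumor, stem), genes)
sc = correlate_with_stemness(
    study.sc_counts, score_signature(study.sc_counts, stem), genes)
cand = select_candidates(bulk, sc, standardize_effect(de))
print(cand[cand["selected"]][["gene_id", "bulk_rho", "sc_rho",
                              "down_effect_std", "rank"]])
#      gene_id  bulk_rho    sc_rho  down_effect_std rank
#    TBT01_022 -0.805441 -0.706697         1.000000    1
#    TBT01_021 -0.827017 -0.807725         0.830378    2
#    TBT01_002 -0.744090 -0.781421         0.886816    3
#    TBT01_037 -0.835460 -0.681661         0.749152    4

res = stratify_survival(study.tb_scores, study.survival)
print(res["logrank"].p, res["km_medians"])
# 0.000205  {'high': 23.2, 'low': 2.1}
```

The screen recovers exactly the four planted candidate genes (strong
anti-correlation with the stemness score at both levels, strongest
downregulation), and the cohort with high tissue-biased gene scores
survives an order of magnitude longer at log-rank p = 2e-4 — the
directional effects the pipeline is designed to detect.  On the
single-cell trajectory the TB and stemness program scores anti-correlate
at Spearman rho = -0.98 under the default planted coupling.

The same flow is available from the shell:

```bash
tbgenes simulate --out data --seed 1
tbgenes discover --expr data/bulk_expression.tsv --design data/tissue_design.tsv \
                 --out tb.tsv
tbgenes contrast --tumor data/tumor.tsv --nat data/nat.tsv --out de.tsv
tbgenes survival --scores data/tb_scores.tsv --surv data/survival.tsv --out surv/
```

## Layout

```
src/tbgenes/
  synthetic.py    generator + ground-truth ledger (SimConfig, SimTruth, ...)
  discovery.py    tissue-biased gene calling
  scoring.py      signature scores, group summaries, pseudotime trends
  contrast.py     tumor-vs-NAT DE, alteration tests, enrichment
  screen.py       dual-level stemness candidate screen
  survival.py     median split, Kaplan-Meier, log-rank
  io.py           TSV / MTX / GMT / JSON readers and writers
  cli.py          `tbgenes` command group
docs/methods.md   model, parameters, design choices, limitations
```
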