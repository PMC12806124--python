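"""Tumor vs adjacent-normal contrasts and gene-set enrichment.

Differential expression uses a two-tailed independent t-test (Welch by
default, with a paired option) on log2 values, with log2 fold changes
computed from linear group means and Benjamini-Hochberg adjustment shared
with the rest of the pipeline.  Over-representation of a query set in a
pathway is the upper-tail hypergeometric probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, welch_ttest
from .containers import ExpressionMatrix
from .exceptions import ValidationError


def differential_expression(tumor: ExpressionMatrix, nat: ExpressionMatrix,
                            genes=None, alpha: float = 0.05,
                            pseudocount: float = 0.01,
                            min_abs_log2fc: float = 0.0,
                            paired: bool = False) -> pd.DataFrame:
    """Per-gene tumor vs NAT contrast.

    Returns a DataFrame with ``gene_id, log2fc, t, p, q, direction`` where
    ``log2fc = log2((mean_tumor + pc) / (mean_nat + pc))`` on the linear
    scale and the test runs on log2 values.  ``direction`` is ``down``/
    ``up`` when ``q < alpha`` (and the optional fold-change gate passes),
    otherwise ``ns``.  Genes absent from either matrix are excluded with a
    warning.
    """
    shared = tumor.gene_ids.intersection(nat.gene_ids)
    if genes is None:
        genes = list(shared)
    else:
        genes = [str(g) for g in genes]
        missing = [g for g in genes if g not in set(shared)]
        if missing:
            warnings.warn(f"{len(missing)} genes absent from tumor or NAT "
                          f"matrix were excluded", UserWarning, stacklevel=2)
            genes = [g for g in genes if g not in set(missing)]
    if not genes:
        raise ValidationError("no shared genes to contrast")
    if tumor.n_samples < 2 or nat.n_samples < 2:
        raise ValidationError("each group needs at least 2 samples")
    t_m = tumor.subset(genes=genes)
    n_m = nat.subset(genes=genes)
    lfc = np.log2((t_m.linear_values().mean(axis=1) + pseudocount) /
                  (n_m.linear_values().mean(axis=1) + pseudocount))
    x = t_m.log2_values()
    y = n_m.log2_values()
    if paired:
        if t_m.n_samples != n_m.n_samples:
            raise ValidationError("paired test requires equal sample counts")
        res = stats.ttest_rel(x, y, axis=1)
        tstat = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
        bad = ~np.isfinite(p)
        diff = x.mean(axis=1) - y.mean(axis=1)
        with np.errstate(invalid="ignore"):
            tstat = np.where(bad, np.where(np.isclose(diff, 0), 0.0,
                                           np.sign(diff) * np.inf), tstat)
        p = np.where(bad, np.where(np.isclose(diff, 0), 1.0, 0.0), p)
    else:
        tstat, p = welch_ttest(x, y, axis=1)
    q = bh_adjust(p)
    out = pd.DataFrame({"gene_id": genes, "log2fc": lfc, "t": tstat,
                        "p": p, "q": q})
    sig = (out["q"] < alpha) & (out["log2fc"].abs() >= min_abs_log2fc)
    out["direction"] = np.where(sig & (out["log2fc"] < 0), "down",
                                np.where(sig & (out["log2fc"] > 0), "up", "ns"))
    return out


def classify_cancer_specific(tb_table: pd.DataFrame, de_table: pd.DataFrame,
                             tissue: str) -> set[str]:
    """Genes tissue-biased in ``tissue`` AND significantly down in its tumor."""
    if tissue not in set(tb_table["tissue"]):
        raise ValidationError(f"tissue {tissue!r} not present in TB table")
    tb = set(tb_table.loc[(tb_table["tissue"] == tissue) & tb_table["is_tb"],
                          "gene_id"])
    down = set(de_table.loc[de_table["direction"] == "down", "gene_id"])
    return tb & down


def alteration_group_test(expr: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Pairwise two-tailed t-tests of one gene's expression across alteration groups.

    ``groups`` holds categorical labels (e.g. methylation or CNV classes).
    Groups with n < 2 are excluded with a warning; BH adjustment runs
    within the gene across pairs.
    """
    from ._stats import pairwise_group_tests
    aligned_expr, aligned_groups = pd.Series(expr, dtype=float).align(
        pd.Series(groups), join="inner")
    counts = aligned_groups.value_counts()
    if (counts >= 2).sum() < 2:
        raise ValidationError("need at least two groups with n >= 2")
    return pairwise_group_tests(aligned_expr, aligned_groups, test="ttest",
                                min_n=2)


def intersect_down_genes(bulk_down, sc_down) -> tuple[set[str], float]:
    """Intersection of bulk- and single-cell-downregulated genes, with Jaccard.

    Jaccard is 0 (flagged via a warning) when both sets are empty.
    """
    a, b = set(bulk_down), set(sc_down)
    inter = a & b
    union = a | b
    if not union:
        warnings.warn("both gene sets empty; Jaccard undefined, returning 0",
                      UserWarning, stacklevel=2)
        return inter, 0.0
    return inter, len(inter) / len(union)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of a query set in one pathway."""

    pathway: str
    overlap: int
    query_size: int
    pathway_size: int
    universe_size: int
    p: float


def enrichment_test(query, pathway, universe,
                    pathway_name: str = "pathway") -> EnrichmentResult:
    """Upper-tail hypergeometric test P(X >= overlap).

    Drawing ``|query|`` genes from a universe of ``|universe|`` genes of
    which ``|pathway|`` are annotated, the p-value is the probability of
    seeing at least the observed overlap.
    """
    query, pathway, universe = set(query), set(pathway), set(universe)
    if not query <= universe:
        raise ValidationError("query is not a subset of the universe")
    if not pathway <= universe:
        raise ValidationError("pathway is not a subset of the universe")
    k = len(query & pathway)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(pathway), len(query)))
    return EnrichmentResult(pathway=pathway_name, overlap=k,
                            query_size=len(query), pathway_size=len(pathway),
                            universe_size=len(universe), p=min(p, 1.0))


def enrich_collections(query, pathways: dict, universe) -> pd.DataFrame:
    """Run enrichment_test over a GMT-style pathway collection; adds BH q."""
    rows = []
    for name, members in pathways.items():
        members = getattr(members, "members", members)
        res = enrichment_test(query, set(members) & set(universe), universe,
                              pathway_name=name)
        rows.append(res.__dict__)
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"])
    return out
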