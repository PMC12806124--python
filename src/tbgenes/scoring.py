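"""Gene-signature scoring for samples and cells.

Two scorers are provided.  ``zmean`` standardizes each member gene across
all scored samples (mean 0, sd 1 on the log2 scale) and averages the
z-values per sample; it is the default and puts scores in z-units.
``rank`` averages the per-sample normalized rank (in (0, 1]) of the member
genes among all genes, which is invariant to any strictly monotone
per-cell transform of expression and therefore robust to library-size and
depth effects in sparse single-cell data.

The standardization population is the scored matrix itself (no external
reference): scores compare samples/cells within one dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import pairwise_group_tests
from .containers import ExpressionMatrix, GeneSet, ScoreVector
from .exceptions import GeneSetError, ValidationError


def score_signature(matrix: ExpressionMatrix, gene_set: GeneSet,
                    method: str = "zmean") -> ScoreVector:
    """Score every sample/cell of ``matrix`` for ``gene_set``.

    zmean uses log2 values (linear input is log2(x+1)-transformed);
    member genes with zero variance are dropped with a warning.  rank uses
    average ranks over all genes within each sample.
    """
    members = gene_set.intersect(matrix.gene_ids)
    if not members:
        raise GeneSetError(
            f"gene set {gene_set.name!r} has no members in the matrix")
    midx = matrix.gene_ids.get_indexer(pd.Index(members))
    dropped: tuple[str, ...] = ()
    if method == "zmean":
        X = matrix.log2_values(pseudocount=1.0)[midx]
        mu = X.mean(axis=1)
        sd = X.std(axis=1, ddof=1)
        keep = sd > 0
        if not keep.any():
            raise GeneSetError(
                f"all members of {gene_set.name!r} have zero variance")
        if not keep.all():
            dropped = tuple(np.asarray(members)[~keep])
            warnings.warn(
                f"dropped {len(dropped)} zero-variance genes from "
                f"{gene_set.name!r}", UserWarning, stacklevel=2)
        z = (X[keep] - mu[keep, None]) / sd[keep, None]
        scores = z.mean(axis=0)
        n_used = int(keep.sum())
    elif method == "rank":
        ranks = stats.rankdata(matrix.values, axis=0) / matrix.n_genes
        scores = ranks[midx].mean(axis=0)
        n_used = len(members)
    else:
        raise ValidationError(f"unknown scoring method {method!r}")
    return ScoreVector(pd.Series(scores, index=matrix.sample_ids, name="score"),
                       method=method, gene_set=gene_set.name,
                       n_genes_used=n_used, degenerate_genes=dropped)


def score_by_group(scores: ScoreVector, groups: pd.Series,
                   test: str = "wilcoxon") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group score summaries plus BH-adjusted pairwise comparisons.

    Returns (summary, pairwise): summary has one row per group with
    mean/sd/n; pairwise has two-sided rank-sum (or Welch t) p and q per
    group pair.  Groups with n < 2 are summarized but excluded from
    testing with a warning.
    """
    s = scores.scores
    groups = pd.Series(groups)
    missing = s.index.difference(groups.index)
    if len(missing):
        raise ValidationError(f"unlabeled samples: {list(missing)[:5]}")
    groups = groups.reindex(s.index)
    summary = (
        s.groupby(groups)
        .agg(["mean", "std", "count"])
        .rename(columns={"std": "sd", "count": "n"})
        .rename_axis("group")
        .reset_index()
    )
    pairwise = pairwise_group_tests(s, groups, test=test, min_n=2)
    return summary, pairwise


@dataclass(frozen=True)
class TrendResult:
    """Spearman trend of a score along pseudotime."""

    rho: float
    p: float
    n: int
    degenerate: bool = False


def score_trend(scores: ScoreVector, pseudotime: pd.Series) -> TrendResult:
    """Spearman correlation of a score vector against pseudotime.

    Constant scores (or constant pseudotime) make the rank correlation
    undefined; the result is returned flagged rather than raising.
    """
    s = scores.scores
    pt = pd.Series(pseudotime).reindex(s.index)
    if pt.isna().any() or not np.all(np.isfinite(pt.to_numpy(dtype=float))):
        raise ValidationError("pseudotime must be finite for every scored cell")
    x = s.to_numpy(dtype=float)
    y = pt.to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TrendResult(rho=float("nan"), p=float("nan"), n=len(x),
                           degenerate=True)
    rho, p = stats.spearmanr(x, y)
    return TrendResult(rho=float(rho), p=float(p), n=len(x))
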