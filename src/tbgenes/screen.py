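"""Dual-level stemness screen for candidate tissue-biased genes.

A candidate gene must (i) anti-correlate with the stemness score across
bulk tumor samples, (ii) anti-correlate with the stemness score across
single cells, and (iii) be strongly downregulated in tumor.  The
downregulation axis is min-max standardized to [0, 1] across the screened
genes.  Candidates are ranked by the equal-weight mean of |bulk rho|,
|single-cell rho| and the standardized effect.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .containers import ExpressionMatrix, ScoreVector
from .exceptions import ScreenError, ValidationError


def correlate_with_stemness(matrix: ExpressionMatrix, stemness: ScoreVector,
                            genes=None) -> pd.DataFrame:
    """Spearman correlation of each gene's expression with the stemness score.

    Returns ``gene_id, rho, p, q, degenerate``.  Constant genes are
    flagged degenerate (rho, p, q = NaN) and excluded from the BH
    adjustment over the remaining genes.
    """
    s = stemness.scores
    shared = matrix.sample_ids.intersection(s.index)
    if len(shared) < 5:
        raise ValidationError("need at least 5 shared samples/cells")
    sub = matrix.subset(genes=genes, samples=shared)
    y = s.reindex(shared).to_numpy(dtype=float)
    X = sub.values
    degenerate = np.ptp(X, axis=1) == 0
    rho = np.full(sub.n_genes, np.nan)
    p = np.full(sub.n_genes, np.nan)
    ok = ~degenerate
    if ok.sum() == 1:
        r, pv = stats.spearmanr(X[ok][0], y)
        rho[ok] = r
        p[ok] = pv
    elif ok.any():
        res = stats.spearmanr(X[ok].T, y)
        # spearmanr on (n, k) + y returns a (k+1, k+1) matrix; take last column
        rho[ok] = np.asarray(res.statistic)[:-1, -1]
        p[ok] = np.asarray(res.pvalue)[:-1, -1]
    q = np.full(sub.n_genes, np.nan)
    if ok.any():
        q[ok] = bh_adjust(p[ok])
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} constant genes excluded from "
                      "correlation screen", UserWarning, stacklevel=2)
    return pd.DataFrame({"gene_id": sub.gene_ids, "rho": rho, "p": p, "q": q,
                         "degenerate": degenerate}).reset_index(drop=True)


def standardize_effect(de_table: pd.DataFrame) -> pd.Series:
    """Min-max standardized downregulation magnitude in [0, 1].

    The raw effect is ``max(0, -log2fc)`` (upregulated genes clamp to
    zero); the largest downregulation maps to 1 and no downregulation to
    0.  If every screened gene has the same effect the scale is
    degenerate and all genes get 0.5 with a warning.
    """
    lfc = pd.Series(de_table["log2fc"].to_numpy(dtype=float),
                    index=de_table["gene_id"])
    finite = lfc[np.isfinite(lfc)]
    if len(finite) < 2:
        raise ValidationError("need >= 2 genes with finite log2fc")
    mag = np.maximum(0.0, -finite)
    lo, hi = float(mag.min()), float(mag.max())
    if hi == lo:
        warnings.warn("all downregulation effects identical; degenerate "
                      "scale, returning 0.5", UserWarning, stacklevel=2)
        return pd.Series(0.5, index=finite.index, name="down_effect_std")
    return ((mag - lo) / (hi - lo)).rename("down_effect_std")


def select_candidates(bulk_corr: pd.DataFrame, sc_corr: pd.DataFrame,
                      effects: pd.Series, corr_gate: float = 0.3,
                      alpha: float = 0.05, effect_gate: float = 0.5,
                      direction: str = "negative") -> pd.DataFrame:
    """Gate and rank candidate genes from the dual-level screen.

    A gene is selected when its correlation passes the magnitude and
    significance gates at BOTH levels and its standardized downregulation
    reaches ``effect_gate``.  Selected genes are ranked (1 = best) by the
    equal-weight composite mean of |bulk rho|, |sc rho| and the effect;
    ties break lexicographically by gene ID.  ``direction="negative"``
    screens for anti-correlation (loss of tissue identity with stemness
    gain); ``"positive"`` flips the sign.
    """
    if direction not in ("negative", "positive"):
        raise ValidationError("direction must be 'negative' or 'positive'")
    b = bulk_corr.set_index("gene_id")[["rho", "q"]].rename(
        columns={"rho": "bulk_rho", "q": "bulk_q"})
    s = sc_corr.set_index("gene_id")[["rho", "q"]].rename(
        columns={"rho": "sc_rho", "q": "sc_q"})
    e = pd.Series(effects, name="down_effect_std")
    table = b.join(s, how="inner").join(e, how="inner")
    if table.empty:
        raise ScreenError("no genes shared between bulk, single-cell and "
                          "effect tables")
    sign = -1.0 if direction == "negative" else 1.0

    def _passes(rho, q):
        return (sign * rho >= corr_gate) & (q < alpha)

    with np.errstate(invalid="ignore"):
        selected = (
            _passes(table["bulk_rho"], table["bulk_q"])
            & _passes(table["sc_rho"], table["sc_q"])
            & (table["down_effect_std"] >= effect_gate)
        )
    selected &= table[["bulk_rho", "sc_rho", "bulk_q", "sc_q"]].notna().all(axis=1)
    table["selected"] = selected.to_numpy()
    table["composite"] = (table["bulk_rho"].abs() + table["sc_rho"].abs()
                          + table["down_effect_std"]) / 3.0
    table = table.rename_axis("gene_id").reset_index()
    table["rank"] = pd.NA
    sel = table[table["selected"]].sort_values(
        ["composite", "gene_id"], ascending=[False, True])
    table.loc[sel.index, "rank"] = np.arange(1, len(sel) + 1)
    return table.sort_values(["selected", "composite"],
                             ascending=[False, False]).reset_index(drop=True)


def plot_screen(candidates: pd.DataFrame, path, corr_gate: float = 0.3,
                effect_gate: float = 0.5, top_n: int = 5) -> None:
    """Volcano-style screen plot: x = bulk rho, y = standardized effect."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    bg = candidates[~candidates["selected"]]
    fg = candidates[candidates["selected"]].nsmallest(top_n, "rank")
    ax.scatter(bg["bulk_rho"], bg["down_effect_std"], s=10, c="0.7", label="other")
    if len(fg):
        ax.scatter(fg["bulk_rho"], fg["down_effect_std"], s=30, c="crimson",
                   label="candidate")
        for _, row in fg.iterrows():
            ax.annotate(row["gene_id"], (row["bulk_rho"], row["down_effect_std"]),
                        fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.axvline(-corr_gate, ls="--", c="k", lw=0.8)
    ax.axhline(effect_gate, ls="--", c="k", lw=0.8)
    ax.set_xlabel("Spearman rho vs stemness score (bulk)")
    ax.set_ylabel("standardized downregulation (0-1)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
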