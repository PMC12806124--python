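"""Shared statistical helpers.

Every module that reports adjusted p-values goes through :func:`bh_adjust`
so Benjamini-Hochberg behaviour is bit-identical across the pipeline.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Accepts any array-like of raw p-values in [0, 1]; returns adjusted
    values in the original order.  NaNs are not allowed - callers exclude
    degenerate tests before adjustment.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p
    if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def welch_ttest(x: np.ndarray, y: np.ndarray, axis: int = -1,
                alternative: str = "two-sided") -> tuple[np.ndarray, np.ndarray]:
    """Welch two-sample t-test with a zero-variance guard.

    When both groups are constant the t statistic is undefined; we report
    p=1 (and t=0) if the means agree and p=0 (t=+/-inf) otherwise, which is
    the noise-free limit of the test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant groups trip scipy's precision-loss warning; we guard the
        # degenerate outputs explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(x, y, axis=axis, equal_var=False,
                              alternative=alternative)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if np.any(bad):
        mx = np.mean(x, axis=axis)
        my = np.mean(y, axis=axis)
        diff = np.broadcast_to(mx - my, p.shape)
        equal = np.isclose(diff, 0.0)
        with np.errstate(invalid="ignore"):
            t = np.where(bad, np.where(equal, 0.0, np.sign(diff) * np.inf), t)
        if alternative == "two-sided":
            p_bad = np.where(equal, 1.0, 0.0)
        elif alternative == "greater":
            p_bad = np.where(equal, 1.0, np.where(diff > 0, 0.0, 1.0))
        else:
            p_bad = np.where(equal, 1.0, np.where(diff < 0, 0.0, 1.0))
        p = np.where(bad, p_bad, p)
    return t, p


def pairwise_group_tests(values: pd.Series, groups: pd.Series,
                         test: str = "wilcoxon", min_n: int = 2) -> pd.DataFrame:
    """All pairwise two-sided comparisons between groups, BH-adjusted.

    Groups with fewer than ``min_n`` observations are excluded with a
    warning.  ``test`` is ``"wilcoxon"`` (Mann-Whitney rank-sum) or
    ``"ttest"`` (Welch).
    """
    values, groups = values.align(groups, join="inner")
    counts = groups.value_counts()
    small = counts[counts < min_n]
    if len(small):
        warnings.warn(
            f"groups excluded from testing (n < {min_n}): {sorted(small.index)}",
            UserWarning, stacklevel=2)
    usable = sorted(counts[counts >= min_n].index)
    rows = []
    for g1, g2 in itertools.combinations(usable, 2):
        a = values[groups == g1].to_numpy(dtype=float)
        b = values[groups == g2].to_numpy(dtype=float)
        if test == "wilcoxon":
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        elif test == "ttest":
            _, p = welch_ttest(a, b)
            p = float(p)
        else:
            raise ValidationError(f"unknown test {test!r}")
        rows.append({"group1": g1, "group2": g2, "p": p})
    out = pd.DataFrame(rows, columns=["group1", "group2", "p"])
    out["q"] = bh_adjust(out["p"]) if len(out) else out["p"]
    return out
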