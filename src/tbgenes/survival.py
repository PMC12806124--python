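"""Median-split survival stratification, Kaplan-Meier curves, log-rank test.

The estimator and test are implemented directly from their defining
risk-table arithmetic rather than delegated, because they are the unit
under test for the stratification contract: the product-limit estimator
S(t) = prod_{t_i <= t} (1 - d_i / n_i) and the two-group log-rank
statistic (sum of observed-minus-expected events over distinct event
times, squared over the summed hypergeometric variance, chi-square with
1 df).  Tied event times are handled with aggregated risk sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ScoreVector
from .exceptions import DegenerateSplitError, ValidationError


def median_split(scores: ScoreVector | pd.Series) -> pd.Series:
    """Assign "high" (score > median) / "low" (score <= median) labels.

    Subjects tied at the median go to the low group, so the split is
    deterministic; the label assignment does not depend on input order.
    """
    s = scores.scores if isinstance(scores, ScoreVector) else pd.Series(scores)
    x = s.to_numpy(dtype=float)
    if len(x) < 4:
        raise ValidationError("median split needs at least 4 subjects")
    if np.ptp(x) == 0:
        raise DegenerateSplitError("all scores identical; cannot split")
    med = float(np.median(x))
    return pd.Series(np.where(x > med, "high", "low"), index=s.index,
                     name="group")


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    need = {"time", "event"}
    if not need.issubset(table.columns):
        raise ValidationError(f"survival table must have columns {sorted(need)}")
    t = table["time"].to_numpy(dtype=float)
    e = table["event"].to_numpy()
    if not np.all(np.isfinite(t)) or (t <= 0).any():
        raise ValidationError("times must be finite and positive")
    if not np.isin(e, [0, 1]).all():
        raise ValidationError("event must be 0 (censored) or 1 (event)")
    return table


def km_estimate(table: pd.DataFrame, group: str | None = None) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve for one (sub)cohort.

    Returns a step function as a DataFrame ``time, n_at_risk, n_events,
    survival`` including the t=0 anchor (S=1).  With no events the curve
    stays flat at 1 (warned).
    """
    table = _check_table(table)
    if group is not None:
        table = table[table["group"] == group]
        if table.empty:
            raise ValidationError(f"group {group!r} is empty")
    t = table["time"].to_numpy(dtype=float)
    e = table["event"].to_numpy(dtype=int)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    rows = [{"time": 0.0, "n_at_risk": len(t), "n_events": 0, "survival": 1.0}]
    surv = 1.0
    for et in event_times:
        n_at_risk = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        surv *= 1.0 - d / n_at_risk
        rows.append({"time": float(et), "n_at_risk": n_at_risk,
                     "n_events": d, "survival": surv})
    if len(rows) == 1:
        import warnings
        warnings.warn("no events; survival curve is flat at 1", UserWarning,
                      stacklevel=2)
    return pd.DataFrame(rows)


def km_median(curve: pd.DataFrame) -> float:
    """Smallest time with S(t) <= 0.5, or inf if the curve never reaches it."""
    below = curve[curve["survival"] <= 0.5]
    return float(below["time"].iloc[0]) if len(below) else float("inf")


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p: float


def logrank_test(table: pd.DataFrame) -> LogrankResult:
    """Two-group log-rank test on a survival table with a ``group`` column.

    At each distinct event time the observed events in group 1 are
    compared with the hypergeometric expectation given the pooled risk
    set; the squared summed difference over the summed variance is
    chi-square with 1 df.
    """
    table = _check_table(table)
    if "group" not in table.columns:
        raise ValidationError("survival table needs a 'group' column")
    labels = sorted(table["group"].unique())
    if len(labels) != 2:
        raise ValidationError(f"log-rank needs exactly two groups, got {labels}")
    t = table["time"].to_numpy(dtype=float)
    e = table["event"].to_numpy(dtype=int)
    g1 = (table["group"] == labels[0]).to_numpy()
    if e.sum() == 0:
        raise ValidationError("log-rank needs at least one event")
    o_minus_e = 0.0
    var = 0.0
    for et in np.unique(t[e == 1]):
        at_risk = t >= et
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((t == et) & (e == 1)).sum())
        d1 = int(((t == et) & (e == 1) & g1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return LogrankResult(statistic=0.0, p=1.0)
    stat = o_minus_e ** 2 / var
    return LogrankResult(statistic=float(stat),
                         p=float(stats.chi2.sf(stat, df=1)))


def stratify_survival(scores: ScoreVector | pd.Series,
                      table: pd.DataFrame) -> dict:
    """Median-split the cohort by score and compare survival between groups.

    ``table`` must carry ``subject_id, time, event``; subjects are matched
    to scores by ID.  Returns the labeled table, both KM curves, per-group
    KM medians, and the log-rank result.
    """
    s = scores.scores if isinstance(scores, ScoreVector) else pd.Series(scores)
    table = _check_table(table).copy()
    ids = table["subject_id"].astype(str)
    missing = ids[~ids.isin(s.index.astype(str))]
    if len(missing):
        raise ValidationError(f"subjects without scores: {list(missing)[:5]}")
    groups = median_split(s)
    table["group"] = groups.reindex(ids).to_numpy()
    curves = {g: km_estimate(table, group=g) for g in ("high", "low")}
    medians = {g: km_median(c) for g, c in curves.items()}
    return {"table": table, "curves": curves, "km_medians": medians,
            "logrank": logrank_test(table)}
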