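"""Independent straight-line oracles used by the test suite.

Each function re-derives a quantity from its definition (enumeration,
step-up formula, risk-table counting) without touching the package
implementations it checks.
"""

import itertools
import math

import numpy as np


def bh_stepup(pvalues):
    """Benjamini-Hochberg adjusted values straight from the step-up formula."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


def hypergeom_sf_enumeration(universe_size, pathway_size, query_size, k):
    """P(overlap >= k) by enumerating every possible query draw."""
    universe = list(range(universe_size))
    pathway = set(universe[:pathway_size])
    hits = total = 0
    for draw in itertools.combinations(universe, query_size):
        total += 1
        if len(pathway.intersection(draw)) >= k:
            hits += 1
    return hits / total


def ranksum_greater_exact(x, y):
    """One-sided (x greater) exact rank-sum p by enumerating label assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires ties-free data"
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    observed = sum(ranks[v] for v in x)
    n = len(x)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        total += 1
        stat = sum(ranks[pooled[i]] for i in combo)
        if stat >= observed:
            count += 1
    return count / total


def km_curve_bruteforce(times, events):
    """Product-limit curve by explicit risk-set counting at each event time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    surv = 1.0
    out = [(0.0, 1.0)]
    for t in sorted(set(times[events == 1])):
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        surv *= 1 - d / n_at_risk
        out.append((t, surv))
    return out


def logrank_bruteforce(times, events, in_group1):
    """Two-group log-rank chi-square from the risk-table definition."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    g1 = np.asarray(in_group1, dtype=bool)
    num = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        num += d1 - d * n1 / n
        if n > 1:
            var += d * n1 * (n - n1) * (n - d) / (n * n * (n - 1))
    return num ** 2 / var if var > 0 else 0.0


def tb_calls_bruteforce(values, gene_ids, tissue_of_sample, pseudocount=0.01,
                        fc_threshold=2.0, alpha=0.05):
    """Straight-line tissue-bias caller: loops over every gene/tissue pair,
    exact rank-sum p by enumeration, BH by the step-up formula.

    ``values`` is linear-scale genes x samples; returns
    {(gene, tissue): (min_log2fc, max_p, q, is_tb)}.
    """
    tissues = sorted(set(tissue_of_sample))
    cols = {t: [j for j, lab in enumerate(tissue_of_sample) if lab == t]
            for t in tissues}
    fc = {}
    pv = {}
    for gi, g in enumerate(gene_ids):
        for t in tissues:
            mt = sum(values[gi][j] for j in cols[t]) / len(cols[t])
            worst_fc = math.inf
            worst_p = 0.0
            for u in tissues:
                if u == t:
                    continue
                mu = sum(values[gi][j] for j in cols[u]) / len(cols[u])
                worst_fc = min(worst_fc,
                               math.log2((mt + pseudocount) / (mu + pseudocount)))
                x = [values[gi][j] for j in cols[t]]
                y = [values[gi][j] for j in cols[u]]
                worst_p = max(worst_p, ranksum_greater_exact(x, y))
            fc[(g, t)] = worst_fc
            pv[(g, t)] = worst_p
    keys = [(g, t) for g in gene_ids for t in tissues]
    q = bh_stepup([pv[k] for k in keys])
    out = {}
    for k, qv in zip(keys, q):
        is_tb = fc[k] >= math.log2(fc_threshold) and qv < alpha
        out[k] = (fc[k], pv[k], qv, is_tb)
    return out
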