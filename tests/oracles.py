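"""Independent brute-force oracles used to pin the optimized implementations.

Everything here is written as plain loops over the defining formulas, kept
deliberately separate from the package's code paths: the running-sum
enrichment score, BH step-up, exact rank-sum enumeration, Nelson-Aalen
log-rank scores and the exhaustive maximally-selected-statistic search.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def rank_average(values):
    """Ascending average ranks, by direct counting."""
    values = list(values)
    out = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        out.append(less + (equal + 1) / 2)
    return out


def enrichment_score_bruteforce(gene_ids, expression, in_set, alpha):
    """Running-sum ES by position-by-position accumulation.

    Genes traversed in decreasing rank order, rank ties broken by
    lexicographic gene id.
    """
    ranks = rank_average(expression)
    order = sorted(range(len(gene_ids)), key=lambda i: (-ranks[i], gene_ids[i]))
    n = len(gene_ids)
    n_in = sum(1 for g in gene_ids if g in in_set)
    denom_in = sum(ranks[i] ** alpha for i in range(n) if gene_ids[i] in in_set)
    p_in = 0.0
    n_out_seen = 0
    es = 0.0
    for i in order:
        if gene_ids[i] in in_set:
            p_in += ranks[i] ** alpha / denom_in
        else:
            n_out_seen += 1
        es += p_in - n_out_seen / (n - n_in)
    return es


def ssgsea_bruteforce(gene_ids, matrix, sets, alpha, normalize):
    """Sets x samples score table from the per-position oracle."""
    matrix = np.asarray(matrix, dtype=float)
    scores = np.array(
        [
            [
                enrichment_score_bruteforce(gene_ids, matrix[:, j], set(genes), alpha)
                for j in range(matrix.shape[1])
            ]
            for genes in sets
        ]
    )
    if normalize:
        scores = scores / (scores.max() - scores.min())
    return scores


def bh_stepup_bruteforce(pvals):
    """BH adjusted p-values straight from the step-up definition."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank_pos in range(m, 0, -1):
        i = indexed[rank_pos - 1]
        running_min = min(running_min, pvals[i] * m / rank_pos)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def ranksum_exact_p(a, b):
    """Two-sided exact rank-sum p by full enumeration of group assignments."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = rank_average(pooled)
    observed = sum(ranks[:n_a])
    mean = n_a * (len(pooled) + 1) / 2
    obs_dev = abs(observed - mean)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        stat = sum(ranks[i] for i in combo)
        if abs(stat - mean) >= obs_dev - 1e-12:
            count += 1
        total += 1
    return count / total


def kruskal_h(groups):
    """Kruskal-Wallis H directly from the rank formula (no tie correction)."""
    pooled = [v for g in groups for v in g]
    ranks = rank_average(pooled)
    n = len(pooled)
    h = 0.0
    pos = 0
    for g in groups:
        r_sum = sum(ranks[pos:pos + len(g)])
        h += r_sum**2 / len(g)
        pos += len(g)
    return 12 / (n * (n + 1)) * h - 3 * (n + 1)


def nelson_aalen_scores(time, event):
    """Log-rank scores a_i = event_i - H(t_i), by direct risk-set counting."""
    n = len(time)
    out = []
    for i in range(n):
        h = 0.0
        for t in sorted(set(time)):
            if t > time[i]:
                break
            d = sum(1 for j in range(n) if time[j] == t and event[j] == 1)
            at_risk = sum(1 for j in range(n) if time[j] >= t)
            if d:
                h += d / at_risk
        out.append(event[i] - h)
    return out


def maxstat_bruteforce(time, event, score, minprop):
    """Exhaustive search over admissible cutpoints, per-split statistics.

    Returns (cutpoint, standardized statistic); ties on |statistic| go to
    the smallest cutpoint value.
    """
    n = len(score)
    a = nelson_aalen_scores(time, event)
    a_mean = sum(a) / n
    ss = sum((x - a_mean) ** 2 for x in a)
    min_size = math.ceil(minprop * n)
    best = None
    for mu in sorted(set(score)):
        low = [i for i in range(n) if score[i] <= mu]
        m = len(low)
        if m < min_size or n - m < min_size:
            continue
        t_stat = sum(a[i] for i in low)
        expected = m * a_mean
        variance = m * (n - m) * ss / (n * (n - 1))
        std = (t_stat - expected) / math.sqrt(variance)
        if best is None or abs(std) > abs(best[1]) + 1e-12:
            best = (mu, std)
    return best


def km_product_limit(time, event):
    """{event time: S(t)} by the product-limit formula."""
    out = {}
    s = 1.0
    for t in sorted(set(time)):
        d = sum(1 for j in range(len(time)) if time[j] == t and event[j] == 1)
        at_risk = sum(1 for j in range(len(time)) if time[j] >= t)
        if d:
            s *= 1 - d / at_risk
        out[t] = s
    return out
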