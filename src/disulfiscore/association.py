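"""Statistical layer: fold change, rank tests, Spearman correlation, BH-FDR.

These are the association tools applied throughout the workflow:
tumour/normal fold change on linear-scale means, Wilcoxon
rank-sum (exact enumeration on small tie-free inputs, tie-corrected normal
approximation otherwise), Kruskal-Wallis for three or more groups, Spearman
correlation with a t-approximation p-value, and Benjamini-Hochberg step-up
adjustment.  ``hallmark_correlation_profile`` strings them together to
correlate an activity score against a pathway-score table (e.g. ssGSEA over
the 50 cancer hallmark sets) with FDR control across the profile.

Significance conventions (p < 0.05 or FDR < 0.05) are reporting flags for
callers; nothing here filters data on significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "DifferentialResult",
    "fold_change",
    "rank_sum_test",
    "kruskal_test",
    "spearman_assoc",
    "bh_adjust",
    "hallmark_correlation_profile",
    "differential_expression",
]

DEFAULT_EXACT_THRESHOLD = 10


@dataclass(frozen=True)
class AssociationResult:
    """Spearman association of one feature with the activity score."""

    feature_id: str
    rho: float
    p: float
    fdr: float
    n: int


@dataclass(frozen=True)
class DifferentialResult:
    """Tumour-vs-normal differential summary for one gene."""

    gene_id: str
    fold_change: float
    p: float
    fdr: float
    flagged: bool = False  # True when the normal-group mean is zero


def fold_change(tumor, normal) -> tuple[float, bool]:
    """mean(tumor) / mean(normal); a zero normal mean is flagged infinite.

    Returns ``(ratio, flagged)``.  Fold change is defined on linear-scale
    expression; callers holding log2 values must unlog first.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.size == 0 or normal.size == 0:
        raise ValueError("fold_change requires non-empty groups")
    mn = normal.mean()
    mt = tumor.mean()
    if mn == 0:
        warnings.warn("normal-group mean is zero; fold change flagged infinite",
                      stacklevel=2)
        return float(np.sign(mt) * np.inf) if mt != 0 else float("nan"), True
    return float(mt / mn), False


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def rank_sum_test(
    a, b, exact_threshold: int = DEFAULT_EXACT_THRESHOLD
) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of the U null distribution when the pooled sample is
    tie-free and no larger than ``exact_threshold``; otherwise the normal
    approximation with tie correction (no continuity correction, so the
    statistic is symmetric in the group labels).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("rank_sum_test requires >=2 observations per group")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:  # degenerate: no rank information at all
        return {"statistic": float(a.size * b.size / 2), "p": 1.0,
                "exact": False}
    exact = pooled.size <= exact_threshold and not _has_ties(pooled)
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "exact": exact}


def kruskal_test(groups) -> dict[str, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square (k-1 df) p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("kruskal_test requires >=3 groups; use rank_sum_test")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs >=2 observations")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:  # degenerate: every value identical
        return {"H": 0.0, "p": 1.0}
    h, p = stats.kruskal(*groups)
    return {"H": float(h), "p": float(p)}


def spearman_assoc(x, y) -> dict[str, float]:
    """Spearman rho (Pearson on average ranks) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman_assoc requires >=3 paired observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero variance in a ranked vector")
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p)}


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    q_(i) = min_{j >= i} ( m * p_(j) / j ) clipped at 1, where (i) indexes
    the ascending sort of p.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("bh_adjust expects a non-empty 1-d vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def hallmark_correlation_profile(
    scores, pathway_scores: pd.DataFrame, score_column: str = "activity_score"
) -> pd.DataFrame:
    """Spearman profile of per-sample pathway scores against the activity score.

    Parameters
    ----------
    scores
        A ``ScoreTable`` (anything with a ``.table`` DataFrame indexed by
        sample) or a DataFrame indexed by sample id containing
        ``score_column``.
    pathway_scores
        Pathways x samples table, typically ``ssgsea_matrix`` output scores
        over a user-supplied collection (e.g. the 50 cancer hallmark sets).

    Returns a DataFrame (feature_id, rho, p, fdr, n) sorted by rho
    descending, with BH-FDR applied across this profile.
    """
    table = getattr(scores, "table", scores)
    shared = [s for s in pathway_scores.columns if s in table.index]
    if len(shared) < 3:
        raise ValueError("need >=3 shared samples between scores and pathways")
    activity = table.loc[shared, score_column].to_numpy(dtype=float)
    rows = []
    for feature in pathway_scores.index:
        vals = pathway_scores.loc[feature, shared].to_numpy(dtype=float)
        res = spearman_assoc(activity, vals)
        rows.append((feature, res["rho"], res["p"], len(shared)))
    out = pd.DataFrame(rows, columns=["feature_id", "rho", "p", "n"])
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out = out[["feature_id", "rho", "p", "fdr", "n"]]
    return out.sort_values("rho", ascending=False, kind="stable").reset_index(
        drop=True
    )


def differential_expression(
    expr_tumor: pd.DataFrame, expr_normal: pd.DataFrame, log2: bool = False
) -> pd.DataFrame:
    """Gene-wise fold change + Wilcoxon p + BH-FDR between two sample groups.

    ``log2=True`` unlogs values (2**x) before the fold-change means; the
    rank-sum test is scale-free so it runs on the values as given.
    """
    genes = expr_tumor.index.intersection(expr_normal.index)
    if genes.empty:
        raise ValueError("no shared genes between groups")
    rows = []
    for g in genes:
        t = expr_tumor.loc[g].to_numpy(dtype=float)
        n = expr_normal.loc[g].to_numpy(dtype=float)
        tl, nl = (2.0**t, 2.0**n) if log2 else (t, n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fc, flagged = fold_change(tl, nl)
        p = rank_sum_test(t, n)["p"]
        rows.append((g, fc, p, flagged))
    out = pd.DataFrame(rows, columns=["gene_id", "fold_change", "p", "flagged"])
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out[["gene_id", "fold_change", "p", "fdr", "flagged"]]
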