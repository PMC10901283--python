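"""Single-sample gene-set enrichment (ssGSEA) from scratch.

For each sample, genes are ranked by expression (average ranks at ties).
Walking the gene list in decreasing rank order, two running fractions are
accumulated: the in-set fraction weighted by rank**alpha and the uniform
out-of-set fraction.  The enrichment score is the SUM of their deviations
over all positions (the single-sample variant), not the maximum deviation
used by the classic two-class GSEA statistic:

    ES(S, j) = sum_i [ P_in(i) - P_out(i) ]
    P_in(i)  = sum_{k in S, pos(k) <= i} r_k^alpha / sum_{k in S} r_k^alpha
    P_out(i) = #{k not in S : pos(k) <= i} / (N - |S|)

Ranks are scale-free, so the score is invariant under any strictly
increasing per-sample transform of the expression values (log or linear
input give identical scores).  Ties in the decreasing-rank ordering are
broken by lexicographic gene id so results are deterministic across
platforms.  With ``normalize=True`` every score in the table is divided by
the global (all sets, all samples) max-minus-min range, the conventional
"ssgsea.norm" behaviour; sets whose scores will be differenced must
therefore be scored in the same call so the shared range cancels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genesets import GeneSetCollection

__all__ = [
    "ExpressionMatrix",
    "EnrichmentTable",
    "rank_transform",
    "enrichment_score",
    "ssgsea_matrix",
    "read_expression",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.25


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with per-sample annotations.

    ``values`` is a DataFrame indexed by gene symbol with sample ids as
    columns.  ``sample_annotations`` (optional) is indexed by sample id and
    carries condition/cohort/covariate columns.  Missing values are an
    error: imputation is out of scope.
    """

    values: pd.DataFrame
    sample_annotations: pd.DataFrame | None = None
    log2: bool = False  # records the declared scale; ranks never transform

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] < 2:
            raise ValueError("expression matrix needs >=2 genes")
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = v.to_numpy(dtype=float, copy=False)
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains missing/non-finite values")
        if self.sample_annotations is not None:
            missing = v.columns.difference(self.sample_annotations.index)
            if len(missing):
                raise ValueError(
                    f"samples missing from annotations: {list(missing)[:5]}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class EnrichmentTable:
    """Sets x samples enrichment scores with the parameters that made them."""

    scores: pd.DataFrame
    alpha: float = DEFAULT_ALPHA
    normalized: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValueError("enrichment table contains non-finite scores")


def rank_transform(column: np.ndarray) -> np.ndarray:
    """Ascending ranks 1..N (highest expression gets rank N), average at ties."""
    column = np.asarray(column, dtype=float)
    if column.ndim != 1 or column.size < 2:
        raise ValueError("rank_transform expects a 1-d vector of length >=2")
    if not np.isfinite(column).all():
        raise ValueError("non-finite values in expression column")
    return rankdata(column, method="average")


def enrichment_score(
    column_ranks: np.ndarray,
    set_mask: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    order: np.ndarray | None = None,
) -> float:
    """Running-sum enrichment score for one sample and one gene set.

    Parameters
    ----------
    column_ranks
        Per-gene ranks for the sample (ascending with expression).
    set_mask
        Boolean membership vector aligned with ``column_ranks``.
    alpha
        Rank-weight exponent.
    order
        Optional precomputed traversal order (indices in decreasing rank,
        ties broken lexicographically by gene id).  When omitted the order
        is derived from the ranks alone (stable sort on input order).
    """
    r = np.asarray(column_ranks, dtype=float)
    m = np.asarray(set_mask, dtype=bool)
    if r.shape != m.shape:
        raise ValueError("ranks and membership mask differ in length")
    n_in = int(m.sum())
    n = r.size
    if n_in == 0:
        raise ValueError("gene set has no genes in the matrix")
    if n_in == n:
        raise ValueError("gene set covers every gene in the matrix")
    if order is None:
        order = np.argsort(-r, kind="stable")
    r_ord = r[order]
    m_ord = m[order]
    w = np.where(m_ord, r_ord**alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~m_ord) / (n - n_in)
    return float(np.sum(p_in - p_out))


def _traversal_orders(
    expr: ExpressionMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample traversal orders with the lexicographic tie-break.

    Genes are first sorted lexicographically; a stable descending-rank sort
    within that order then breaks rank ties by gene id.  Returns the ranks
    (genes x samples, in lexicographic gene order) and an (samples x genes)
    array of traversal index vectors into that lexicographic order.
    """
    lex = np.argsort(np.asarray(expr.gene_ids, dtype=object), kind="stable")
    arr = expr.values.to_numpy(dtype=float)[lex, :]
    n_genes, n_samples = arr.shape
    ranks = np.empty_like(arr)
    orders = np.empty((n_samples, n_genes), dtype=np.intp)
    for j in range(n_samples):
        ranks[:, j] = rankdata(arr[:, j], method="average")
        orders[j] = np.argsort(-ranks[:, j], kind="stable")
    return ranks, orders, lex


def ssgsea_matrix(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = True,
) -> EnrichmentTable:
    """Score every set in ``collection`` for every sample of ``expr``.

    Genes of a set absent from the matrix are dropped with a logged warning;
    a set with no genes present (or covering the whole matrix) is an error.
    With ``normalize=True`` all scores are divided by the joint max-min
    range of the whole table.
    """
    ranks, orders, lex = _traversal_orders(expr)
    lex_genes = [expr.gene_ids[i] for i in lex]
    gene_pos = {g: i for i, g in enumerate(lex_genes)}
    n_genes, n_samples = ranks.shape

    masks: list[np.ndarray] = []
    for s in collection:
        mask = np.zeros(n_genes, dtype=bool)
        present = [g for g in s.genes if g in gene_pos]
        missing = [g for g in s.genes if g not in gene_pos]
        if missing:
            logger.warning(
                "set %r: %d gene(s) absent from matrix and dropped: %s",
                s.name, len(missing), ", ".join(missing),
            )
        if not present:
            raise ValueError(f"set {s.name!r} has no genes in the matrix")
        if len(present) == n_genes:
            raise ValueError(f"set {s.name!r} covers every gene in the matrix")
        mask[[gene_pos[g] for g in present]] = True
        masks.append(mask)

    scores = np.empty((len(masks), n_samples))
    for j in range(n_samples):
        r = ranks[:, j]
        order = orders[j]
        r_ord = r[order]
        for si, mask in enumerate(masks):
            m_ord = mask[order]
            w = np.where(m_ord, r_ord**alpha, 0.0)
            p_in = np.cumsum(w) / w.sum()
            p_out = np.cumsum(~m_ord) / (n_genes - int(mask.sum()))
            scores[si, j] = np.sum(p_in - p_out)

    if normalize:
        rng = scores.max() - scores.min()
        if rng == 0:
            raise ValueError(
                "cannot normalize: global score range is zero (degenerate matrix)"
            )
        scores = scores / rng

    table = pd.DataFrame(scores, index=collection.names, columns=expr.sample_ids)
    return EnrichmentTable(table, alpha=alpha, normalized=normalize)


def read_expression(
    path: str | Path,
    sep: str | None = None,
    annotations: pd.DataFrame | None = None,
    log2: bool = False,
) -> ExpressionMatrix:
    """Load a genes x samples TSV/CSV (first column gene symbols, header row).

    ``sep=None`` infers the delimiter from the file extension (.csv -> comma,
    otherwise tab).
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, sample_annotations=annotations, log2=log2)
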