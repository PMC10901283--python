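"""Per-cell activity scoring with binned-control-gene module scores.

The module score of a gene set in a cell is the mean expression of the
set's genes minus the mean expression of expression-matched control genes:
all genes are ranked by their mean expression across cells and cut into
``nbin`` equal-frequency bins, and for every module gene ``n_ctrl`` control
genes are drawn without replacement from its bin (module genes excluded,
draw capped at bin size).  Subtracting bin-matched controls removes the
depth/abundance component a raw mean would carry.  The per-cell activity
score is the positive-set module score minus the negative-set module
score; malignant (or any) cell subsets are then split at the median
activity into "activated" (strictly above) and "suppressive" (at or below)
cells.

All control draws are seeded and reproducible: the same inputs and seed
give bit-identical scores.  Input is expected log-normalized; a helper
applies counts-per-10k + log1p for raw counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .genesets import Direction, GeneSet, GeneSetCollection

__all__ = [
    "CellMatrix",
    "CellScoreTable",
    "bin_genes_by_mean",
    "module_score",
    "activity_score_cells",
    "split_by_median",
    "normalize_counts",
    "read_mtx",
]

logger = logging.getLogger(__name__)

DEFAULT_NBIN = 24
DEFAULT_N_CTRL = 100

ACTIVATED = "activated"
SUPPRESSIVE = "suppressive"


@dataclass
class CellMatrix:
    """Genes x cells sparse (or dense) expression with cell annotations."""

    values: sparse.spmatrix | np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n_genes, n_cells = self.values.shape
        if n_genes != len(self.gene_ids) or n_cells != len(self.cell_ids):
            raise ValueError("matrix shape does not match id lists")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")
        if sparse.issparse(self.values):
            if self.values.count_nonzero() and self.values.min() < 0:
                raise ValueError("negative values in cell matrix")
            self.values = sparse.csr_matrix(self.values)
        else:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.size and self.values.min() < 0:
                raise ValueError("negative values in cell matrix")
        if self.cell_annotations is not None:
            missing = pd.Index(self.cell_ids).difference(
                self.cell_annotations.index
            )
            if len(missing):
                raise ValueError(f"cells missing annotations: {list(missing)[:5]}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sparse.issparse(self.values):
            return self.values.toarray()
        return self.values

    def gene_means(self) -> np.ndarray:
        """Mean expression of each gene across cells."""
        if sparse.issparse(self.values):
            return np.asarray(self.values.mean(axis=1)).ravel()
        return self.values.mean(axis=1)


@dataclass
class CellScoreTable:
    """Per-cell module/activity scores; labels appear after the median split."""

    table: pd.DataFrame  # indexed by cell id; column "activity_score"
    seed: int | None = None

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table.index)


def normalize_counts(matrix: CellMatrix, target_sum: float = 1e4) -> CellMatrix:
    """Counts-per-``target_sum`` followed by log1p (standard log-normalization)."""
    vals = matrix.values
    if sparse.issparse(vals):
        totals = np.asarray(vals.sum(axis=0)).ravel()
        totals[totals == 0] = 1.0
        scaled = vals @ sparse.diags(target_sum / totals)
        out = scaled.log1p()
    else:
        totals = vals.sum(axis=0)
        totals = np.where(totals == 0, 1.0, totals)
        out = np.log1p(vals * (target_sum / totals))
    return CellMatrix(out, list(matrix.gene_ids), list(matrix.cell_ids),
                      matrix.cell_annotations)


def bin_genes_by_mean(matrix: CellMatrix, nbin: int = DEFAULT_NBIN) -> pd.Series:
    """Assign every gene to one of ``nbin`` equal-frequency mean-expression bins.

    Genes are ordered by (mean expression, gene id) — the lexicographic
    tie-break makes the cut deterministic — and split into ``nbin``
    near-equal contiguous chunks.  Returns a Series gene id -> bin index.
    """
    n_genes = matrix.n_genes
    if nbin < 1:
        raise ValueError("nbin must be >=1")
    if nbin > n_genes:
        raise ValueError(f"nbin ({nbin}) exceeds number of genes ({n_genes})")
    means = matrix.gene_means()
    order = sorted(range(n_genes), key=lambda i: (means[i], matrix.gene_ids[i]))
    bins = np.array_split(order, nbin)
    assignment = np.empty(n_genes, dtype=int)
    for b, idx in enumerate(bins):
        assignment[np.asarray(idx, dtype=int)] = b
    return pd.Series(assignment, index=pd.Index(matrix.gene_ids, name="gene_id"),
                     name="bin")


def module_score(
    matrix: CellMatrix,
    module: GeneSet,
    nbin: int = DEFAULT_NBIN,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
    bins: pd.Series | None = None,
) -> np.ndarray:
    """Binned-control module score per cell for one gene set.

    For each module gene present in the matrix, ``n_ctrl`` control genes
    are drawn uniformly without replacement from that gene's bin (module
    genes excluded; capped at the bin's available size with a warning).
    score(cell) = mean expression of module genes - mean expression of the
    pooled control draws (pooled as a multiset, so a control gene drawn for
    two module genes counts twice).
    """
    if seed is None:
        raise ValueError("seed is mandatory for the control-gene draws")
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    present = [g for g in module.genes if g in gene_pos]
    absent = [g for g in module.genes if g not in gene_pos]
    if absent:
        logger.warning("module %r: dropping %d absent gene(s): %s",
                       module.name, len(absent), ", ".join(absent))
    if not present:
        raise ValueError(f"module {module.name!r} has no genes in the matrix")
    if bins is None:
        bins = bin_genes_by_mean(matrix, nbin=nbin)
    module_set = set(present)
    rng = np.random.default_rng(seed)
    bin_members: dict[int, list[str]] = {}
    for b in sorted(bins.unique()):
        members = bins.index[bins.to_numpy() == b].tolist()
        bin_members[b] = [g for g in members if g not in module_set]
    control_idx: list[int] = []
    capped: list[str] = []
    for g in sorted(present):  # sorted: draw order independent of input order
        b = int(bins.loc[g])
        pool = bin_members[b]
        k = min(n_ctrl, len(pool))
        if k < n_ctrl:
            capped.append(g)
        if k == 0:
            continue
        draw = rng.choice(len(pool), size=k, replace=False)
        control_idx.extend(gene_pos[pool[i]] for i in draw)
    if capped:
        warnings.warn(
            f"module {module.name!r}: control draw capped at bin size for "
            f"{len(capped)} gene(s) (requested {n_ctrl} controls each): "
            f"{', '.join(capped)}",
            stacklevel=2,
        )
    if not control_idx:
        raise ValueError("no control genes available for the module")
    dense = matrix.dense()
    module_mean = dense[[gene_pos[g] for g in present], :].mean(axis=0)
    control_mean = dense[control_idx, :].mean(axis=0)
    return np.asarray(module_mean - control_mean, dtype=float)


def activity_score_cells(
    matrix: CellMatrix,
    regulators: GeneSetCollection,
    nbin: int = DEFAULT_NBIN,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> CellScoreTable:
    """Per-cell activity = module score(positive set) - module score(negative set).

    The two control draws are seeded independently with ``seed`` and
    ``seed + 1``, assigned to the two sets in lexicographic set-name order
    so each set's draw is independent of which direction tag it carries;
    swapping the direction tags therefore exactly negates every cell's
    score.
    """
    positive = regulators.by_direction(Direction.POSITIVE)
    negative = regulators.by_direction(Direction.NEGATIVE)
    if len(positive) != 1 or len(negative) != 1:
        raise ValueError("need exactly one positive and one negative set")
    bins = bin_genes_by_mean(matrix, nbin=nbin)
    first, second = sorted((positive[0], negative[0]), key=lambda s: s.name)
    seeds = {first.name: seed, second.name: seed + 1}
    pos = module_score(matrix, positive[0], nbin, n_ctrl,
                       seed=seeds[positive[0].name], bins=bins)
    neg = module_score(matrix, negative[0], nbin, n_ctrl,
                       seed=seeds[negative[0].name], bins=bins)
    table = pd.DataFrame(
        {"positive_score": pos, "negative_score": neg, "activity_score": pos - neg},
        index=pd.Index(matrix.cell_ids, name="cell_id"),
    )
    if matrix.cell_annotations is not None:
        table = table.join(matrix.cell_annotations, how="left")
    return CellScoreTable(table, seed=seed)


def split_by_median(
    table: CellScoreTable,
    within: list[str] | np.ndarray | None = None,
    score_column: str = "activity_score",
) -> CellScoreTable:
    """Label cells activated (> median) or suppressive (<= median).

    ``within`` restricts both the median and the labelling to a cell subset
    (e.g. malignant cells); other cells keep a missing label.  Ties at the
    median are assigned to "suppressive" so "activated" is strictly above
    the median.
    """
    df = table.table.copy()
    if within is None:
        subset = df.index
    else:
        subset = pd.Index(within)
        missing = subset.difference(df.index)
        if len(missing):
            raise ValueError(f"unknown cells in subset: {list(missing)[:5]}")
    if len(subset) == 0:
        raise ValueError("median split requires a non-empty cell subset")
    if len(subset) < 2:
        raise ValueError("median split requires >=2 cells")
    scores = df.loc[subset, score_column].to_numpy(dtype=float)
    med = float(np.median(scores))
    labels = np.where(scores > med, ACTIVATED, SUPPRESSIVE)
    if (labels == SUPPRESSIVE).all():
        warnings.warn("all cells at or below the median; no activated cells",
                      stacklevel=2)
    if "activity_label" not in df.columns:
        df["activity_label"] = pd.Series(pd.NA, index=df.index, dtype="object")
    df.loc[subset, "activity_label"] = labels
    return CellScoreTable(df, seed=table.seed)


def read_mtx(
    mtx_path, genes_path, barcodes_path, annotations: pd.DataFrame | None = None
) -> CellMatrix:
    """Read a MatrixMarket genes x cells matrix with gene/barcode TSVs.

    The gene file may have one column (symbol) or two (id, symbol; the
    second column is used, the 10x convention).  Barcodes are one per line.
    """
    from scipy.io import mmread

    mat = sparse.csr_matrix(mmread(str(mtx_path)))
    genes_df = pd.read_csv(genes_path, sep="\t", header=None)
    gene_ids = genes_df.iloc[:, 1 if genes_df.shape[1] > 1 else 0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    return CellMatrix(mat, gene_ids, barcodes, cell_annotations=annotations)
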