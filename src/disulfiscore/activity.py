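"""The headline statistic: the per-sample disulfidptosis activity score.

Each sample receives an ssGSEA enrichment score for the positive regulator
set and one for the negative regulator set; the activity score is their
difference.  Both sets are scored in a single ssGSEA call so the joint
normalization range cancels in the difference.  Scores are not
re-standardized per cohort by default; an optional z-scaling of each score
column (across samples, before differencing) is exposed for users who want
cohort-standardized scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import kruskal_test, rank_sum_test
from .genesets import Direction, GeneSetCollection
from .ssgsea import DEFAULT_ALPHA, ExpressionMatrix, ssgsea_matrix

__all__ = ["ScoreTable", "disulfidptosis_scores", "compare_score_by_condition"]


@dataclass
class ScoreTable:
    """Per-sample positive, negative and activity (= pos - neg) scores.

    ``table`` is indexed by sample id with columns ``positive_score``,
    ``negative_score``, ``activity_score`` plus any annotation columns
    carried over from the expression matrix.
    """

    table: pd.DataFrame
    alpha: float = DEFAULT_ALPHA
    normalized: bool = True
    zscaled: bool = False

    def __post_init__(self) -> None:
        required = {"positive_score", "negative_score", "activity_score"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"score table missing columns: {sorted(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def activity_score(self) -> pd.Series:
        return self.table["activity_score"]


def disulfidptosis_scores(
    expr: ExpressionMatrix,
    regulators: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = True,
    zscale: bool = False,
) -> ScoreTable:
    """Score samples for the positive and negative regulator sets.

    ``regulators`` must contain exactly one positive-direction and one
    negative-direction set (the bundled collection by default).  Both are
    scored in one ``ssgsea_matrix`` call; the activity score is the exact
    per-sample difference positive - negative.
    """
    positive = regulators.by_direction(Direction.POSITIVE)
    negative = regulators.by_direction(Direction.NEGATIVE)
    if len(positive) != 1 or len(negative) != 1:
        raise ValueError(
            "regulator collection must contain exactly one positive and one "
            f"negative set (got {len(positive)} positive, {len(negative)} negative)"
        )
    pos, neg = positive[0], negative[0]
    scored = GeneSetCollection([pos, neg], source=regulators.source)
    enr = ssgsea_matrix(expr, scored, alpha=alpha, normalize=normalize)
    pos_scores = enr.scores.loc[pos.name]
    neg_scores = enr.scores.loc[neg.name]
    if zscale:
        pos_scores = (pos_scores - pos_scores.mean()) / pos_scores.std(ddof=1)
        neg_scores = (neg_scores - neg_scores.mean()) / neg_scores.std(ddof=1)
    table = pd.DataFrame(
        {
            "positive_score": pos_scores,
            "negative_score": neg_scores,
            "activity_score": pos_scores - neg_scores,
        }
    )
    table.index.name = "sample_id"
    if expr.sample_annotations is not None:
        table = table.join(expr.sample_annotations, how="left")
    return ScoreTable(table, alpha=alpha, normalized=normalize, zscaled=zscale)


def compare_score_by_condition(
    scores: ScoreTable,
    condition_key: str = "condition",
    score_column: str = "activity_score",
) -> dict:
    """Rank-test the activity score across condition levels.

    Two levels -> two-sided Wilcoxon rank-sum; three or more ->
    Kruskal-Wallis.  The report carries per-level n and medians alongside
    the statistic and p-value.
    """
    table = scores.table
    if condition_key not in table.columns:
        raise ValueError(f"no annotation column {condition_key!r} in score table")
    values = table[score_column]
    levels = table[condition_key]
    groups: dict[str, np.ndarray] = {}
    for level, sub in values.groupby(levels, sort=True):
        if len(sub) < 2:
            raise ValueError(f"condition level {level!r} has <2 samples")
        groups[str(level)] = sub.to_numpy(dtype=float)
    if len(groups) < 2:
        raise ValueError("need >=2 condition levels to compare")
    report: dict = {
        "levels": {
            name: {"n": int(g.size), "median": float(np.median(g))}
            for name, g in groups.items()
        },
        "score_column": score_column,
    }
    vecs = list(groups.values())
    if len(vecs) == 2:
        res = rank_sum_test(vecs[0], vecs[1])
        report.update(test="wilcoxon_rank_sum", statistic=res["statistic"],
                      p=res["p"])
    else:
        res = kruskal_test(vecs)
        report.update(test="kruskal_wallis", statistic=res["H"], p=res["p"])
    return report
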