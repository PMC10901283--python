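"""Survival layer: maxstat cutpoint, Kaplan-Meier, log-rank, univariate Cox.

The central operation dichotomizes a continuous per-sample score (the
activity score, or a single gene's expression) by the maximally selected
rank statistic: every observed score value whose low/high split keeps at
least ``ceil(minprop * n)`` samples on each side is a candidate cutpoint;
each candidate is scored with a standardized log-rank statistic and the
cutpoint maximizing its absolute value is selected ("low" = score <=
cutpoint).  Because the maximum over many candidates is not chi-square
distributed, significance is assessed by a seeded permutation test (score
labels permuted against survival) rather than an asymptotic correction.

Per-candidate statistics use log-rank (Nelson-Aalen) scores
``a_i = event_i - H(t_i)`` with the permutational mean/variance of their
low-group sum — the standard maximally-selected-rank-statistics
formulation, equivalent in ordering to per-split log-rank tests.

Kaplan-Meier estimation and Cox proportional-hazards fitting delegate to
lifelines; this module pins their contracts (product-limit values, HR with
asymptotic CI) behind a stable interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "SurvivalTable",
    "CutpointResult",
    "km_estimate",
    "logrank_statistic",
    "logrank_scores",
    "maxstat_cutpoint",
    "cox_univariate",
    "median_cutpoint",
]

DEFAULT_MINPROP = 0.1
DEFAULT_N_PERM = 1000


@dataclass
class SurvivalTable:
    """Per-sample time-to-event data joined with an optional score covariate."""

    table: pd.DataFrame  # index: sample id; columns: time, event[, score, ...]
    time_unit: str = "days"

    def __post_init__(self) -> None:
        df = self.table
        for col in ("time", "event"):
            if col not in df.columns:
                raise ValueError(f"survival table missing column {col!r}")
        if (df["time"] < 0).any():
            raise ValueError("negative survival times")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (event)")
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids")

    @property
    def time(self) -> np.ndarray:
        return self.table["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    @property
    def score(self) -> np.ndarray:
        if "score" not in self.table.columns:
            raise ValueError("survival table has no score column")
        return self.table["score"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CutpointResult:
    """Selected cutpoint with its statistic, the induced groups, permutation p."""

    cutpoint: float
    statistic: float  # standardized log-rank statistic at the cutpoint
    groups: pd.Series  # sample id -> "low" (score <= cutpoint) / "high"
    p_perm: float | None = None
    n_perm: int = 0
    candidates: pd.DataFrame | None = None  # per-candidate cutpoint/statistic


def km_estimate(
    table: SurvivalTable, group: pd.Series | None = None
) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve(s), one per group level.

    Returns ``{level: DataFrame(time, survival)}``; the single-curve case
    uses the level ``"all"``.  S(0) = 1; right-continuous non-increasing
    steps at event times.  An all-censored table yields a flat curve at 1
    with a warning.
    """
    if table.event.sum() == 0:
        warnings.warn("no events observed; survival estimate is flat at 1",
                      stacklevel=2)
    if group is None:
        levels = {"all": table.table.index}
    else:
        group = group.reindex(table.table.index)
        levels = {str(v): idx for v, idx in table.table.groupby(group).groups.items()}
    out: dict[str, pd.DataFrame] = {}
    for level, idx in levels.items():
        sub = table.table.loc[idx]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        sf = kmf.survival_function_
        df = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
        out[level] = df.reset_index(drop=True)
    return out


def logrank_statistic(table: SurvivalTable, groups: pd.Series) -> dict[str, float]:
    """Two-group log-rank chi-square statistic and p-value."""
    groups = groups.reindex(table.table.index)
    counts = groups.value_counts()
    if len(counts) != 2 or (counts < 1).any():
        raise ValueError("logrank_statistic needs two non-empty groups")
    if table.event.sum() == 0:
        raise ValueError("log-rank test requires >=1 event")
    res = multivariate_logrank_test(table.time, groups.to_numpy(), table.event)
    return {"statistic": float(res.test_statistic), "p": float(res.p_value)}


def logrank_scores(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Log-rank (Nelson-Aalen) scores a_i = event_i - H(t_i).

    H is the Nelson-Aalen cumulative hazard evaluated at each subject's
    observed time (events and censorings at the same time both receive the
    hazard accumulated through that time; deaths at t are counted in the
    risk set at t).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = time.size
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    uniq, start = np.unique(t_sorted, return_index=True)
    cumhaz_at = np.empty(uniq.size)
    at_risk = n
    cumhaz = 0.0
    for k, t in enumerate(uniq):
        stop = start[k + 1] if k + 1 < uniq.size else n
        d = int(e_sorted[start[k]:stop].sum())
        tied = stop - start[k]
        if d:
            cumhaz += d / at_risk
        cumhaz_at[k] = cumhaz
        at_risk -= tied
    h = cumhaz_at[np.searchsorted(uniq, time)]
    return event - h


def _candidate_splits(
    score: np.ndarray, minprop: float
) -> tuple[np.ndarray, np.ndarray]:
    """Admissible cutpoint values and low-group sizes for the sorted score."""
    n = score.size
    min_size = int(np.ceil(minprop * n))
    uniq = np.unique(score)
    sizes = np.searchsorted(np.sort(score), uniq, side="right")
    keep = (sizes >= min_size) & (n - sizes >= min_size)
    return uniq[keep], sizes[keep]


def _max_standardized(
    a_sorted_cumsum: np.ndarray,
    sizes: np.ndarray,
    a_mean: float,
    a_var_factor: float,
) -> np.ndarray:
    """Standardized low-group score sums at the admissible split sizes."""
    t = a_sorted_cumsum[sizes - 1]
    expected = sizes * a_mean
    variance = sizes * (a_sorted_cumsum.size - sizes) * a_var_factor
    return (t - expected) / np.sqrt(variance)


def maxstat_cutpoint(
    table: SurvivalTable,
    minprop: float = DEFAULT_MINPROP,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> CutpointResult:
    """Maximally selected rank statistic cutpoint on the score column.

    Candidates are the observed score values whose "low" (score <= value)
    and "high" groups each hold at least ``ceil(minprop * n)`` samples.
    The returned cutpoint maximizes the absolute standardized log-rank
    statistic (ties broken toward the smallest score value).  With
    ``n_perm > 0`` a permutation p-value is computed by permuting the score
    against (time, event) and recording how often the permuted maximal
    statistic reaches the observed one.
    """
    if not 0 < minprop < 0.5:
        raise ValueError("minprop must lie in (0, 0.5)")
    score = table.score
    n = score.size
    if np.unique(score).size < 3:
        raise ValueError("need >=3 distinct score values for cutpoint selection")
    a = logrank_scores(table.time, table.event)
    a_mean = a.mean()
    ss = np.sum((a - a_mean) ** 2)
    if ss == 0:
        raise ValueError("degenerate survival data: zero log-rank score variance")
    var_factor = ss / (n * (n - 1))

    cutpoints, sizes = _candidate_splits(score, minprop)
    if cutpoints.size == 0:
        raise ValueError(
            f"no admissible cutpoint under minprop={minprop} with n={n}"
        )
    order = np.argsort(score, kind="stable")
    cum = np.cumsum(a[order])
    stats = _max_standardized(cum, sizes, a_mean, var_factor)
    best = int(np.argmax(np.abs(stats)))  # argmax takes first -> smallest score
    cutpoint = float(cutpoints[best])
    statistic = float(stats[best])
    observed_max = abs(statistic)

    groups = pd.Series(
        np.where(score <= cutpoint, "low", "high"), index=table.table.index,
        name="group",
    )

    p_perm: float | None = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            cum_p = np.cumsum(a[perm][order])
            stats_p = _max_standardized(cum_p, sizes, a_mean, var_factor)
            if np.abs(stats_p).max() >= observed_max:
                count += 1
        p_perm = count / n_perm

    cand = pd.DataFrame({"cutpoint": cutpoints, "statistic": stats,
                         "n_low": sizes})
    return CutpointResult(cutpoint, statistic, groups, p_perm=p_perm,
                          n_perm=n_perm, candidates=cand)


def median_cutpoint(table: SurvivalTable) -> CutpointResult:
    """Median split of the score (low = score <= median), no test statistic."""
    score = table.score
    med = float(np.median(score))
    groups = pd.Series(np.where(score <= med, "low", "high"),
                       index=table.table.index, name="group")
    if groups.nunique() < 2:
        raise ValueError("median split produced a single group")
    return CutpointResult(med, float("nan"), groups)


def cox_univariate(
    table: SurvivalTable, covariate: pd.Series | np.ndarray | str = "score"
) -> dict[str, float]:
    """Univariate Cox proportional-hazards fit by partial likelihood.

    Returns hazard ratio per covariate unit with its asymptotic 95% CI and
    Wald p-value.
    """
    if isinstance(covariate, str):
        cov = table.table[covariate].to_numpy(dtype=float)
        name = covariate
    else:
        cov = np.asarray(covariate, dtype=float)
        name = "covariate"
    if np.unique(cov).size < 2:
        raise ValueError("covariate has zero variance")
    if table.event.sum() == 0:
        raise ValueError("Cox fit requires >=1 event")
    df = pd.DataFrame({"time": table.time, "event": table.event, name: cov})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    coef = float(cph.params_[name])
    se = float(cph.standard_errors_[name])
    z = 1.959963984540054
    return {
        "coef": coef,
        "hr": float(np.exp(coef)),
        "ci_low": float(np.exp(coef - z * se)),
        "ci_high": float(np.exp(coef + z * se)),
        "p": float(cph.summary.loc[name, "p"]),
        "n_events": int(table.event.sum()),
    }
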