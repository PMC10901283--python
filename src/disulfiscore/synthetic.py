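"""Synthetic fixtures: bulk contrasts, survival cohorts, sparse single cells.

These generators stand in for the cohort data the workflow is normally run
on.  They are statistical stand-ins, not mimics of any particular dataset:

* ``simulate_bulk_contrast`` emulates a two-condition experiment (e.g.
  control vs glucose starvation) as log2-scale expression with gene-wise
  Gaussian baselines and noise; condition B shifts the positive regulator
  genes up and/or the negative regulator genes down by ``effect_size``
  log2 units, planting a higher activity score in condition B.
* ``simulate_survival`` draws exponential event times whose hazard depends
  on a standard-normal score, either proportionally (log-HR ``beta`` per
  score unit) or as a step at a score threshold, with independent
  exponential censoring calibrated to a target censoring fraction.
* ``simulate_sc`` draws negative-binomial counts with a malignant cell
  subpopulation whose negative-regulator genes are scaled by
  ``module_shift`` (>1 plants a LOWER activity score in malignant cells),
  plus optional Bernoulli dropout.

Every generator is a pure function of its configuration: all randomness
flows through numpy's PCG64 ``default_rng`` seeded from the mandatory
``seed``, so the same configuration reproduces bit-identical output on any
platform.  Regulator genes are embedded by symbol in the synthetic gene
universe so the bundled gene sets apply unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, optimize

from .genesets import Direction, GeneSetCollection, bundled_regulators
from .sc_score import CellMatrix
from .ssgsea import ExpressionMatrix
from .survival import SurvivalTable

__all__ = [
    "SimulationConfig",
    "simulate_bulk_contrast",
    "simulate_survival",
    "simulate_sc",
]


@dataclass
class SimulationConfig:
    """Configuration of the two-condition bulk contrast generator.

    Defaults encode the scaled-down validation contrast: 2000 genes, 20
    samples per condition, a +1 log2 shift on the positive regulator set in
    condition B, log-scale noise SD 1.0, gene baselines ~ Normal(5, 2) on
    the log2 scale.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 20
    effect_size: float = 1.0
    target_sets: tuple[str, ...] = ("positive",)  # which sets shift in B
    noise_sd: float = 1.0
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    seed: int = 0
    regulators: GeneSetCollection | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for t in self.target_sets:
            if t not in ("positive", "negative"):
                raise ValueError(f"unknown target set {t!r}")


def _gene_universe(n_genes: int, regulators: GeneSetCollection) -> list[str]:
    reg_genes = regulators.all_genes()
    if n_genes < len(reg_genes):
        raise ValueError(
            f"n_genes={n_genes} smaller than the {len(reg_genes)} regulator genes"
        )
    width = len(str(n_genes))
    fillers = [f"GENE{i:0{width}d}" for i in range(n_genes - len(reg_genes))]
    return reg_genes + fillers


def simulate_bulk_contrast(config: SimulationConfig) -> ExpressionMatrix:
    """Two-condition bulk cohort with a planted regulator-set shift.

    Condition A is the baseline; condition B adds ``effect_size`` log2
    units to the positive-set genes and/or subtracts it from the
    negative-set genes, per ``target_sets``.  Values are log2-scale
    (ssGSEA ranks are scale-free, so no unlogging is needed downstream).
    """
    regulators = config.regulators or bundled_regulators()
    genes = _gene_universe(config.n_genes, regulators)
    rng = np.random.default_rng(config.seed)
    n_per = config.n_samples_per_group
    n_samples = 2 * n_per
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, (config.n_genes, n_samples)
    )
    gene_pos = {g: i for i, g in enumerate(genes)}
    b_cols = np.arange(n_per, n_samples)
    for tag in config.target_sets:
        direction = Direction.POSITIVE if tag == "positive" else Direction.NEGATIVE
        (geneset,) = regulators.by_direction(direction)
        idx = [gene_pos[g] for g in geneset.genes if g in gene_pos]
        if not idx:
            raise ValueError(f"{tag} set genes missing from synthetic universe")
        sign = 1.0 if tag == "positive" else -1.0
        values[np.ix_(idx, b_cols)] += sign * config.effect_size
    sample_ids = [f"A{i:03d}" for i in range(n_per)] + [
        f"B{i:03d}" for i in range(n_per)
    ]
    annotations = pd.DataFrame(
        {"condition": ["A"] * n_per + ["B"] * n_per},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    df = pd.DataFrame(values, index=genes, columns=sample_ids)
    return ExpressionMatrix(df, sample_annotations=annotations, log2=True)


def _calibrate_censoring(hazards: np.ndarray, censor_rate: float) -> float:
    """Censoring rate lam s.t. mean_i lam / (lam + h_i) == censor_rate.

    For independent exponentials T ~ Exp(h) and C ~ Exp(lam),
    P(C < T) = lam / (lam + h); the overall censored fraction is the mean
    over subjects.  Solved by bisection (monotone in lam).
    """
    if censor_rate == 0:
        return 0.0

    def frac(lam: float) -> float:
        return float(np.mean(lam / (lam + hazards)))

    hi = hazards.max()
    while frac(hi) < censor_rate:
        hi *= 2
    return float(optimize.brentq(lambda lam: frac(lam) - censor_rate,
                                 1e-12, hi, xtol=1e-12))


def simulate_survival(
    n: int,
    beta: float = 0.7,
    censor_rate: float = 0.3,
    seed: int = 0,
    baseline_hazard: float = 0.05,
    step_threshold: float | None = None,
) -> SurvivalTable:
    """Survival cohort whose hazard depends on a standard-normal score.

    With ``step_threshold=None`` the hazard is proportional,
    ``h0 * exp(beta * score)``; with a threshold it is a step,
    ``h0`` below and ``h0 * exp(beta)`` strictly above the threshold.
    Censoring is an independent exponential calibrated so the expected
    censored fraction equals ``censor_rate``.
    """
    if n < 10:
        raise ValueError("simulate_survival requires n >= 10")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    score = rng.normal(0.0, 1.0, n)
    if step_threshold is None:
        hazards = baseline_hazard * np.exp(beta * score)
    else:
        hazards = np.where(score > step_threshold,
                           baseline_hazard * np.exp(beta), baseline_hazard)
    event_time = rng.exponential(1.0 / hazards)
    if censor_rate > 0:
        lam = _calibrate_censoring(hazards, censor_rate)
        censor_time = rng.exponential(1.0 / lam, n)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time, event = event_time, np.ones(n, dtype=int)
    ids = [f"S{i:04d}" for i in range(n)]
    df = pd.DataFrame({"time": time, "event": event, "score": score},
                      index=pd.Index(ids, name="sample_id"))
    return SurvivalTable(df)


def simulate_sc(
    n_genes: int = 1500,
    n_cells: int = 500,
    frac_malignant: float = 0.4,
    module_shift: float = 2.0,
    dropout: float = 0.0,
    seed: int = 0,
    mean_log_mu: float = 0.0,
    mean_log_sd: float = 1.0,
    nb_dispersion: float = 2.0,
    regulators: GeneSetCollection | None = None,
) -> CellMatrix:
    """Sparse single-cell counts with a planted malignant module shift.

    Gene means are log-normal; counts are negative-binomial with shape
    ``nb_dispersion`` (variance mu + mu^2/dispersion).  In malignant cells
    the negative-regulator gene means are multiplied by ``module_shift``,
    so a shift > 1 raises the negative (suppressor) module and LOWERS the
    activity score of malignant cells.  ``dropout`` zeroes entries
    independently with the given probability.
    """
    if not 0 < frac_malignant < 1:
        raise ValueError("frac_malignant must lie in (0, 1)")
    if not 0 <= dropout < 1:
        raise ValueError("dropout must lie in [0, 1)")
    if module_shift <= 0:
        raise ValueError("module_shift must be positive")
    regulators = regulators or bundled_regulators()
    genes = _gene_universe(n_genes, regulators)
    rng = np.random.default_rng(seed)
    n_mal = int(round(frac_malignant * n_cells))
    if n_mal == 0 or n_mal == n_cells:
        raise ValueError("frac_malignant leaves an empty subpopulation")
    malignant = np.zeros(n_cells, dtype=bool)
    malignant[:n_mal] = True
    mu = np.exp(rng.normal(mean_log_mu, mean_log_sd, n_genes))
    mu_mat = np.tile(mu[:, None], (1, n_cells))
    (neg_set,) = regulators.by_direction(Direction.NEGATIVE)
    gene_pos = {g: i for i, g in enumerate(genes)}
    neg_idx = [gene_pos[g] for g in neg_set.genes if g in gene_pos]
    mu_mat[np.ix_(neg_idx, np.where(malignant)[0])] *= module_shift
    # NB as Gamma-Poisson mixture: shape r, mean mu -> Poisson(Gamma(r, mu/r))
    lam = rng.gamma(nb_dispersion, mu_mat / nb_dispersion)
    counts = rng.poisson(lam).astype(np.int64)
    if dropout > 0:
        keep = rng.random(counts.shape) >= dropout
        counts = counts * keep
    cell_ids = [f"C{i:04d}" for i in range(n_cells)]
    annotations = pd.DataFrame(
        {
            "malignant": malignant,
            "cell_type": np.where(malignant, "malignant", "stromal"),
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return CellMatrix(sparse.csr_matrix(counts), genes, cell_ids,
                      cell_annotations=annotations)
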