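"""Single-study spike-in simulation and ROC/AUC benchmarking.

The benchmark generates a genes x samples matrix of i.i.d. standard
normal values, adds a constant spike ``m`` to the first ``k`` disease
samples of one designated true-positive gene, scores every gene with
each method, and summarizes detection of the true positive over
replicates as a ROC curve (true positive rate against a false-positive
threshold grid) with a trapezoidal AUC.

The per-replicate p-value is the bespoke rank statistic: the proportion
of genes whose score strictly exceeds the true positive's, divided by
the TOTAL gene count (it can be exactly 0).  A conventional
(r+1)/(n+1) variant exists behind a flag but is not used for the
benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .stats_core import (
    METHODS,
    ExpressionMatrix,
    GroupAssignment,
    copa_score,
    gti_score,
    ort_score,
    os_score,
    t_statistic,
)

__all__ = [
    "SimulationConfig",
    "RocExperimentResult",
    "simulate_single_study",
    "simulation_pvalue",
    "roc_experiment",
    "auc",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Spike-in simulation parameters.

    Defaults follow the benchmark protocol: 1000 genes, 30 normal and
    30 disease samples, spike magnitude m = 2, k spiked disease samples
    (k in {1, 10, 20, 30} in the study design), 50 replicates.
    """

    n_genes: int = 1000
    n1: int = 30
    n2: int = 30
    k: int = 10
    m: float = 2.0
    n_reps: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if not (0 <= self.k <= self.n2):
            raise ValueError(f"k must lie in [0, n2]; got k={self.k}, n2={self.n2}")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need at least 2 samples per group")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class RocExperimentResult:
    """Per-method ROC points, AUC and the per-replicate p-values."""

    fp_grid: np.ndarray
    tpr: dict[str, np.ndarray]
    auc: dict[str, float]
    pvalues: dict[str, np.ndarray]  # shape (n_reps,) each
    config: SimulationConfig | None = None
    methods: list[str] = field(default_factory=list)

    def points(self, method: str) -> list[tuple[float, float]]:
        return list(zip(self.fp_grid.tolist(), self.tpr[method].tolist()))


def simulate_single_study(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> tuple[ExpressionMatrix, GroupAssignment, int]:
    """Draw one replicate: N(0,1) background plus one spiked gene.

    All cells are i.i.d. standard normal; then ``m`` is added to the
    first ``k`` disease-group cells of gene 0, the designated true
    positive.  Samples are ordered normal first, then disease.  Returns
    (matrix, groups, index of the true-positive gene).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    n = config.n1 + config.n2
    values = rng.standard_normal((config.n_genes, n))
    tp = 0
    values[tp, config.n1 : config.n1 + config.k] += config.m
    labels = np.concatenate(
        [np.ones(config.n1, dtype=int), np.full(config.n2, 2, dtype=int)]
    )
    width = len(str(config.n_genes))
    matrix = ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i:0{width}d}" for i in range(config.n_genes)],
        sample_ids=[f"normal_{i}" for i in range(config.n1)]
        + [f"cancer_{i}" for i in range(config.n2)],
    )
    return matrix, GroupAssignment(labels), tp


def simulation_pvalue(
    scores: np.ndarray, tp_index: int, conventional: bool = False
) -> float:
    """Rank p-value of the true-positive gene.

    Default: the proportion of genes whose score STRICTLY exceeds the
    true positive's, out of the total gene count (ties do not count;
    can be 0).  ``conventional=True`` uses (r+1)/(n+1) instead.  NaN if
    the true positive's score is undefined.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need scores for at least 2 genes")
    tp_score = scores[tp_index]
    if np.isnan(tp_score):
        return float("nan")
    with np.errstate(invalid="ignore"):
        r = int(np.sum(scores > tp_score))  # NaN comparisons are False
    if conventional:
        return (r + 1.0) / (scores.size + 1.0)
    return r / scores.size


_SCORERS = {
    "t": t_statistic,
    "copa": copa_score,
    "os": os_score,
    "ort": ort_score,
    "gti": gti_score,
}


def roc_experiment(
    config: SimulationConfig,
    methods: Sequence[str] = METHODS,
    fp_grid: np.ndarray | None = None,
) -> RocExperimentResult:
    """Run the replicated spike-in benchmark for several methods.

    For each false-positive threshold on the grid, TPR is the
    proportion of replicates whose bespoke p-value is <= the threshold.
    Per-replicate seeds are spawned deterministically from the master
    seed, so identical configs reproduce the full ROC table exactly.
    """
    methods = list(methods)
    if not methods:
        raise ValueError("at least one method required")
    unknown = set(methods) - set(_SCORERS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if fp_grid is None:
        fp_grid = np.linspace(0.0, 1.0, 101)
    fp_grid = np.asarray(fp_grid, dtype=float)

    pvals = {m: np.empty(config.n_reps) for m in methods}
    children = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    for rep, ss in enumerate(children):
        matrix, groups, tp = simulate_single_study(
            config, np.random.default_rng(ss)
        )
        for m in methods:
            pvals[m][rep] = simulation_pvalue(_SCORERS[m](matrix, groups), tp)

    tpr = {
        m: np.array([np.mean(pvals[m] <= f) for f in fp_grid]) for m in methods
    }
    aucs = {m: auc(list(zip(fp_grid, tpr[m]))) for m in methods}
    return RocExperimentResult(
        fp_grid=fp_grid,
        tpr=tpr,
        auc=aucs,
        pvalues=pvals,
        config=config,
        methods=methods,
    )


def auc(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under a ROC curve on [0, 1].

    Points must be sorted by false-positive threshold with all
    coordinates in [0, 1].  Missing endpoints at 0 or 1 are added by
    constant extrapolation of the nearest TPR (so a curve at TPR = 1
    everywhere above 0 integrates to exactly 1).
    """
    pts = [(float(f), float(t)) for f, t in points]
    if not pts:
        raise ValueError("empty ROC curve")
    fp = np.array([p[0] for p in pts])
    tp = np.array([p[1] for p in pts])
    if np.any(np.diff(fp) < 0):
        raise ValueError("ROC points must be sorted by fp threshold")
    if fp.min() < 0 or fp.max() > 1 or tp.min() < 0 or tp.max() > 1:
        raise ValueError("ROC coordinates must lie in [0, 1]")
    if fp[0] > 0:
        fp = np.concatenate([[0.0], fp])
        tp = np.concatenate([[tp[0]], tp])
    if fp[-1] < 1:
        fp = np.concatenate([fp, [1.0]])
        tp = np.concatenate([tp, [tp[-1]]])
    return float(np.trapezoid(tp, fp))
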