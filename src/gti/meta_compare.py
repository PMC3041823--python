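"""Method-comparison diagnostics.

Two diagnostics for comparing outlier statistics on the same matrix:
the overlap structure of the per-method top-N gene lists (every region
of the intersection lattice, e.g. the 7 regions of a 3-set Venn
diagram), and the Spearman rank correlation of each method's scores
with the per-gene informative-sample counts.  The latter exposes
sample-count bias: on integrated multi-study data with varying samples
per gene, a score that grows with the number of informative samples
will rank well-covered genes ahead of sparsely covered ones regardless
of biology.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sp_stats

from .stats_core import ExpressionMatrix, GroupAssignment, ScoreTable

__all__ = [
    "OverlapReport",
    "top_n_overlap",
    "informative_counts",
    "score_vs_samplecount_correlation",
]


@dataclass
class OverlapReport:
    """Intersection-lattice decomposition of per-method top-N sets.

    ``regions`` maps a sorted tuple of method names to the list of
    genes belonging to exactly those methods' top-N sets (2^M - 1
    regions for M methods, possibly empty).  ``unique`` holds, per
    method, the genes in no other method's set.
    """

    methods: list[str]
    n_top: int
    top_sets: dict[str, list[str]]
    regions: dict[tuple[str, ...], list[str]]
    unique: dict[str, list[str]]

    def region_counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}

    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())


def top_n_overlap(
    score_table: ScoreTable,
    methods: Sequence[str] | None = None,
    n_top: int = 100,
) -> OverlapReport:
    """Decompose the per-method top-``n_top`` gene sets into Venn regions."""
    methods = list(methods) if methods is not None else list(score_table.methods)
    missing = [m for m in methods if f"score_{m}" not in score_table.table]
    if missing:
        raise ValueError(f"methods not present in score table: {missing}")

    top: dict[str, list[str]] = {}
    for m in methods:
        try:
            top[m] = score_table.top_genes(m, n_top)
        except ValueError as exc:
            raise ValueError(f"top_n_overlap: {exc}") from None

    sets = {m: set(top[m]) for m in methods}
    union = sorted(set().union(*sets.values()))
    regions: dict[tuple[str, ...], list[str]] = {}
    for size in range(1, len(methods) + 1):
        for combo in combinations(methods, size):
            regions[tuple(sorted(combo))] = []
    for gene in union:
        members = tuple(sorted(m for m in methods if gene in sets[m]))
        regions[members].append(gene)
    unique = {m: regions[(m,)] for m in methods}
    return OverlapReport(
        methods=methods, n_top=n_top, top_sets=top, regions=regions,
        unique=unique,
    )


def informative_counts(
    matrix: ExpressionMatrix,
    groups: GroupAssignment,
    which: str = "all",
) -> np.ndarray:
    """Per-gene informative-sample counts (``all``, ``normal`` or ``disease``)."""
    informative = ~matrix.missing
    if which == "all":
        return informative.sum(axis=1)
    if which == "normal":
        return informative[:, groups.normal_mask].sum(axis=1)
    if which == "disease":
        return informative[:, groups.disease_mask].sum(axis=1)
    raise ValueError(f"which must be all/normal/disease, got {which!r}")


def score_vs_samplecount_correlation(
    score_table: ScoreTable,
    counts: np.ndarray,
    methods: Sequence[str] | None = None,
) -> dict[str, float]:
    """Spearman rho between each method's scores and per-gene counts.

    Scores are rank-correlated (average ranks for ties) against the
    count vector; Spearman on the raw scores equals Spearman on their
    ascending ranks, so larger rho means higher scores go to genes with
    more informative samples.  Genes with an undefined score are
    dropped per method.  A constant count vector (over the genes used)
    is an error: rank correlation is undefined there.
    """
    methods = list(methods) if methods is not None else list(score_table.methods)
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] != len(score_table.table):
        raise ValueError("counts length does not match score table")
    out: dict[str, float] = {}
    for m in methods:
        s = score_table.scores(m).to_numpy(dtype=float)
        ok = ~np.isnan(s) & ~np.isnan(counts)
        if ok.sum() < 3:
            raise ValueError(
                f"method {m!r}: need >=3 genes with defined scores and counts"
            )
        if np.ptp(counts[ok]) == 0:
            raise ValueError(
                f"method {m!r}: count vector is constant; "
                "Spearman correlation undefined"
            )
        rho = sp_stats.spearmanr(s[ok], counts[ok]).statistic
        out[m] = float(rho)
    return out
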