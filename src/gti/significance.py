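"""Permutation null distributions and empirical p-values.

Group labels are permuted uniformly at random, preserving the group
sizes; the chosen statistic is recomputed under each relabelling.  The
one-sided upper-tail p-value uses the add-one estimator

    p = (1 + #{null >= observed}) / (1 + n_perm)

so p lies in [1/(n_perm+1), 1] and is never zero.  Nulls are per-gene by
default; a pooled-across-genes mode is provided, with the caveat that in
multi-study matrices per-gene missingness makes genes non-exchangeable,
so pooled nulls can be miscalibrated there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

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

__all__ = ["PermutationResult", "permute_labels", "permutation_pvalues"]


@dataclass
class PermutationResult:
    """Observed scores, empirical p-values and the null provenance."""

    method: str
    n_perm: int
    seed: int
    pooling: str
    observed: np.ndarray
    pvalues: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    null_scores: np.ndarray | None = None  # (n_perm, n_genes), optional


def permute_labels(
    groups: GroupAssignment, rng: np.random.Generator
) -> GroupAssignment:
    """Uniformly random relabelling preserving n1 and n2."""
    return GroupAssignment(rng.permutation(groups.labels))


def _score_fn(method: str, copa_r: int):
    if method == "copa":
        return lambda m, g: copa_score(m, g, r=copa_r)
    fns = {"t": t_statistic, "os": os_score, "ort": ort_score, "gti": gti_score}
    if method not in fns:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return fns[method]


def permutation_pvalues(
    matrix: ExpressionMatrix,
    groups: GroupAssignment,
    method: str = "gti",
    n_perm: int = 1000,
    seed: int = 0,
    pooling: str = "per-gene",
    copa_r: int = 90,
    two_sided: bool = False,
    keep_null: bool = False,
) -> PermutationResult:
    """Empirical permutation p-values for one statistic.

    Parameters
    ----------
    pooling
        ``"per-gene"`` compares each gene's observed score against its
        own null draws; ``"pooled"`` pools all defined null scores
        across genes into one reference distribution.
    two_sided
        Use |score| for both observed and null values; the default
        upper tail targets outlier over-expression (a score's sign
        encodes direction).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if pooling not in ("per-gene", "pooled"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    fn = _score_fn(method, copa_r)
    raw_observed = np.asarray(fn(matrix, groups), dtype=float)
    observed = np.abs(raw_observed) if two_sided else raw_observed

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, matrix.n_genes), dtype=float)
    for i in range(n_perm):
        null[i] = fn(matrix, permute_labels(groups, rng))
    if two_sided:
        null = np.abs(null)

    p = np.full(matrix.n_genes, np.nan)
    if pooling == "per-gene":
        n_def = np.sum(~np.isnan(null), axis=0)
        with np.errstate(invalid="ignore"):
            ge = np.nansum(null >= observed[None, :], axis=0)
        ok = ~np.isnan(observed) & (n_def > 0)
        p[ok] = (1.0 + ge[ok]) / (1.0 + n_def[ok])
    else:
        pool = np.sort(null[~np.isnan(null)])
        if pool.size == 0:
            raise ValueError(
                "all permuted scores undefined; cannot build a pooled null"
            )
        ok = ~np.isnan(observed)
        # #{pool >= obs} via a right-open search on the sorted pool
        ge = pool.size - np.searchsorted(pool, observed[ok], side="left")
        p[ok] = (1.0 + ge) / (1.0 + pool.size)

    return PermutationResult(
        method=method,
        n_perm=n_perm,
        seed=seed,
        pooling=pooling,
        observed=raw_observed,
        pvalues=p,
        gene_ids=list(matrix.gene_ids),
        null_scores=null if keep_null else None,
    )
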