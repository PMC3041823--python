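"""Per-gene outlier statistics for two-group expression matrices.

Implements five scores over a genes x samples matrix of log-scale
expression values with optional per-cell missingness:

``t``
    standard unpaired two-sample t-statistic with pooled variance.
``copa``
    r-th percentile of the disease samples' standardized expression,
    centred by the all-sample median and scaled by the all-sample MAD.
``os``
    sum of standardized disease values exceeding the q75 + IQR cutoff
    computed on all informative samples.
``ort``
    sum of normal-median-centred disease outliers (cutoff from normal
    samples only), scaled by a pooled group-centred MAD.
``gti``
    per-group score = 100 x (outlier proportion) x (relative mean
    exceedance above the cutoff); the gene's index is the disease-group
    score minus the normal-group score.

Conventions pinned throughout the package:

* quantiles use linear interpolation between order statistics
  (numpy ``method="linear"``, i.e. the classical "type 7" rule);
* the MAD carries the 1.4826 normal-consistency factor;
* cutoff comparisons are strict -- values equal to the cutoff are
  never outliers;
* group label 1 is the normal/reference group, label 2 the disease
  group; positive scores mean disease over-expression;
* undefined scores are returned as NaN and sort after all defined
  scores in rank tables.

Missing cells are represented as NaN; every centre, scale, quantile and
group count is taken over the per-gene informative (non-missing)
samples, which is the regime of integrated multi-study matrices with
varying numbers of samples per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MAD_SCALE",
    "QUANTILE_METHOD",
    "METHODS",
    "ExpressionMatrix",
    "GroupAssignment",
    "RobustSummary",
    "OutlierCutoff",
    "ScoreTable",
    "robust_center_scale",
    "outlier_cutoff",
    "t_statistic",
    "copa_score",
    "os_score",
    "ort_score",
    "gti_group_score",
    "gti_score",
    "score_all",
]

#: Normal-consistency factor: MAD * 1.4826 estimates the standard
#: deviation for Gaussian data.
MAD_SCALE = 1.4826

#: Quantile convention used everywhere (q25, q75, COPA percentile).
QUANTILE_METHOD = "linear"  # classical type 7

#: Canonical method order.
METHODS = ("gti", "copa", "os", "ort", "t")

NORMAL = 1
DISEASE = 2


class UndefinedInputError(ValueError):
    """Raised when an operation receives an empty / all-missing input."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a missingness mask.

    Parameters
    ----------
    values
        Real matrix, shape ``(n_genes, n_samples)``.  Cells may be NaN,
        in which case they are treated as missing regardless of `missing`.
    gene_ids, sample_ids
        Row / column identifiers.  Gene identifiers must be unique.
    missing
        Optional boolean mask, same shape; True marks a missing cell.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_genes, n_samples = self.values.shape
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} rows"
            )
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samples} columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene identifiers")
        if self.missing is None:
            self.missing = np.isnan(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.values.shape:
                raise ValueError("missing mask shape mismatch")
            self.missing = self.missing | np.isnan(self.values)
        if not np.isfinite(self.values[~self.missing]).all():
            raise ValueError("non-finite value in a non-missing cell")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def masked(self) -> np.ndarray:
        """Values with missing cells replaced by NaN (copy)."""
        out = self.values.copy()
        out[self.missing] = np.nan
        return out


@dataclass
class GroupAssignment:
    """Per-sample group labels: 1 = normal/reference, 2 = disease."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        bad = set(np.unique(self.labels)) - {NORMAL, DISEASE}
        if bad:
            raise ValueError(f"group labels must be 1 or 2, got {sorted(bad)}")

    @property
    def n1(self) -> int:
        return int(np.sum(self.labels == NORMAL))

    @property
    def n2(self) -> int:
        return int(np.sum(self.labels == DISEASE))

    @property
    def normal_mask(self) -> np.ndarray:
        return self.labels == NORMAL

    @property
    def disease_mask(self) -> np.ndarray:
        return self.labels == DISEASE

    def swapped(self) -> "GroupAssignment":
        """Assignment with the two group labels exchanged."""
        return GroupAssignment(np.where(self.labels == NORMAL, DISEASE, NORMAL))


@dataclass(frozen=True)
class RobustSummary:
    """Median and 1.4826-scaled median absolute deviation."""

    med: float
    mad: float


@dataclass(frozen=True)
class OutlierCutoff:
    """The q75 + IQR upper outlier fence.

    ``source`` records which samples defined it (``"all"`` or
    ``"normal"``).
    """

    b: float
    source: str = "all"


@dataclass
class ScoreTable:
    """Per-gene scores and descending ranks for one or more methods.

    ``table`` is indexed by gene id with columns ``score_<m>`` and
    ``rank_<m>`` per method plus a ``flags`` column.  Ranks 1..d (d =
    number of genes with a defined score) go to the defined genes in
    descending score order, ties broken by gene identifier; undefined
    genes take ranks d+1.. in identifier order.
    """

    table: pd.DataFrame
    methods: list[str]
    config: dict = field(default_factory=dict)

    def scores(self, method: str) -> pd.Series:
        return self.table[f"score_{method}"]

    def ranks(self, method: str) -> pd.Series:
        return self.table[f"rank_{method}"]

    def top_genes(self, method: str, n_top: int) -> list[str]:
        """The ``n_top`` gene ids with the highest defined scores."""
        defined = self.table[f"score_{method}"].notna()
        if int(defined.sum()) < n_top:
            raise ValueError(
                f"method {method!r} has only {int(defined.sum())} defined "
                f"genes, fewer than n_top={n_top}"
            )
        r = self.table.loc[defined, f"rank_{method}"]
        return list(r[r <= n_top].sort_values().index)


# ---------------------------------------------------------------------------
# scalar building blocks
# ---------------------------------------------------------------------------


def _clean(values: Sequence[float] | np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float).ravel()
    return v[~np.isnan(v)]


def robust_center_scale(values: Sequence[float] | np.ndarray) -> RobustSummary:
    """Median and scaled MAD of the non-missing values.

    ``mad = 1.4826 * median(|v - med|)``, which estimates the standard
    deviation under normality.
    """
    v = _clean(values)
    if v.size == 0:
        raise UndefinedInputError("robust_center_scale of an empty input")
    med = float(np.median(v))
    mad = MAD_SCALE * float(np.median(np.abs(v - med)))
    return RobustSummary(med=med, mad=mad)


def outlier_cutoff(
    values: Sequence[float] | np.ndarray, source: str = "all"
) -> OutlierCutoff:
    """Upper outlier fence b = q75 + (q75 - q25), type-7 quantiles."""
    v = _clean(values)
    if v.size == 0:
        raise UndefinedInputError("outlier_cutoff of an empty input")
    q25, q75 = np.quantile(v, [0.25, 0.75], method=QUANTILE_METHOD)
    return OutlierCutoff(b=float(q75 + (q75 - q25)), source=source)


def gti_group_score(
    group_values: Sequence[float] | np.ndarray, cutoff: OutlierCutoff | float
) -> float:
    """Single-group score: outlier proportion x relative exceedance, x100.

    With ``A = {v : v > b}`` (strict) the score is

        100 * (|A| / n_group) * (mean(A) - b) / b

    and 0 when A is empty.  Returns NaN when ``b <= 0``: the relative
    gap presumes a positive (log-intensity) expression scale -- shift
    the data rather than trusting a clamped score.
    """
    b = cutoff.b if isinstance(cutoff, OutlierCutoff) else float(cutoff)
    v = _clean(group_values)
    if v.size == 0:
        raise UndefinedInputError("gti_group_score of an empty group")
    if b <= 0:
        return float("nan")
    above = v[v > b]
    if above.size == 0:
        return 0.0
    return 100.0 * (above.size / v.size) * ((float(np.mean(above)) - b) / b)


# ---------------------------------------------------------------------------
# vectorized per-gene helpers
# ---------------------------------------------------------------------------


def _row_median(x: np.ndarray) -> np.ndarray:
    if np.isnan(x).any():
        with np.errstate(invalid="ignore"):
            return np.nanmedian(x, axis=1)
    return np.median(x, axis=1)


def _row_quantile(x: np.ndarray, q) -> np.ndarray:
    if np.isnan(x).any():
        with np.errstate(invalid="ignore"):
            return np.nanquantile(x, q, axis=1, method=QUANTILE_METHOD)
    return np.quantile(x, q, axis=1, method=QUANTILE_METHOD)


def _group_views(matrix: ExpressionMatrix, groups: GroupAssignment):
    """(all, normal-only, disease-only) NaN-masked value matrices."""
    if groups.labels.shape[0] != matrix.n_samples:
        raise ValueError("group labels do not match matrix samples")
    x = matrix.masked()
    xn = x.copy()
    xn[:, groups.disease_mask] = np.nan
    xd = x.copy()
    xd[:, groups.normal_mask] = np.nan
    return x, xn, xd


def _counts(x: np.ndarray) -> np.ndarray:
    return np.sum(~np.isnan(x), axis=1)


# ---------------------------------------------------------------------------
# per-gene statistics (vectorized over genes)
# ---------------------------------------------------------------------------


def t_statistic(
    matrix: ExpressionMatrix, groups: GroupAssignment
) -> np.ndarray:
    """Unpaired pooled-variance t per gene, disease minus normal.

    NaN where either group has fewer than 2 informative samples or the
    pooled standard deviation is 0.
    """
    _, xn, xd = _group_views(matrix, groups)
    n1, n2 = _counts(xn), _counts(xd)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.nansum(xn, axis=1) / n1
        m2 = np.nansum(xd, axis=1) / n2
        ss1 = np.nansum((xn - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((xd - m2[:, None]) ** 2, axis=1)
        s2 = (ss1 + ss2) / (n1 + n2 - 2)
        t = (m2 - m1) / (np.sqrt(s2) * np.sqrt(1.0 / n1 + 1.0 / n2))
    t = np.where((n1 < 2) | (n2 < 2) | (s2 <= 0), np.nan, t)
    return t


def copa_score(
    matrix: ExpressionMatrix, groups: GroupAssignment, r: int = 90
) -> np.ndarray:
    """r-th percentile of the standardized disease values per gene.

    Standardization uses the median and scaled MAD over ALL informative
    samples (both groups).  NaN where that MAD is 0 or a group has no
    informative sample.
    """
    if r not in (75, 90, 95):
        raise ValueError(f"copa percentile r must be 75, 90 or 95, got {r}")
    x, xn, xd = _group_views(matrix, groups)
    med = _row_median(x)
    mad = MAD_SCALE * _row_median(np.abs(x - med[:, None]))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (xd - med[:, None]) / mad[:, None]
        score = _row_quantile(z, r / 100.0)
    bad = (mad <= 0) | (_counts(xd) == 0) | (_counts(xn) == 0)
    return np.where(bad, np.nan, score)


def os_score(matrix: ExpressionMatrix, groups: GroupAssignment) -> np.ndarray:
    """Outlier-sum per gene: standardized disease values above q75+IQR.

    The cutoff, median and MAD all come from ALL informative samples;
    the sum runs over disease samples strictly above the cutoff and is 0
    when none exceed it.  NaN where the all-sample MAD is 0.
    """
    x, xn, xd = _group_views(matrix, groups)
    med = _row_median(x)
    mad = MAD_SCALE * _row_median(np.abs(x - med[:, None]))
    q25, q75 = _row_quantile(x, [0.25, 0.75])
    b = q75 + (q75 - q25)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (xd - med[:, None]) / mad[:, None]
        score = np.nansum(np.where(xd > b[:, None], z, 0.0), axis=1)
    bad = (mad <= 0) | (_counts(xd) == 0) | (_counts(xn) == 0)
    return np.where(bad, np.nan, score)


def ort_score(matrix: ExpressionMatrix, groups: GroupAssignment) -> np.ndarray:
    """Outlier-robust t per gene.

    Each group is centred at its own median; the pooled scaled MAD of
    the centred values replaces the all-sample MAD, and the outlier
    fence comes from the NORMAL samples only.  The score sums
    (x - normal median) / mad* over disease samples strictly above that
    fence, 0 when none.  NaN where mad* is 0 or the normal group has
    fewer than 2 informative samples.
    """
    x, xn, xd = _group_views(matrix, groups)
    n1, n2 = _counts(xn), _counts(xd)
    med1 = _row_median(xn)
    med2 = _row_median(xd)
    centred = np.where(
        np.isnan(x),
        np.nan,
        np.where(
            groups.normal_mask[None, :], x - med1[:, None], x - med2[:, None]
        ),
    )
    mad_star = MAD_SCALE * _row_median(np.abs(centred))
    q25, q75 = _row_quantile(xn, [0.25, 0.75])
    b_normal = q75 + (q75 - q25)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (xd - med1[:, None]) / mad_star[:, None]
        score = np.nansum(np.where(xd > b_normal[:, None], z, 0.0), axis=1)
    bad = (mad_star <= 0) | (n1 < 2) | (n2 == 0)
    return np.where(bad, np.nan, score)


def gti_score(matrix: ExpressionMatrix, groups: GroupAssignment) -> np.ndarray:
    """Gene tissue index per gene: disease-group score minus normal-group.

    The cutoff b = q75 + IQR is taken over ALL informative samples of
    the gene; each group contributes 100 x (proportion above b) x
    (mean exceedance / b).  Large positive values flag disease-group
    outliers, large negative values normal-group outliers.  NaN where
    b <= 0 (relative gap needs a positive scale) or a group has no
    informative sample.
    """
    x, xn, xd = _group_views(matrix, groups)
    q25, q75 = _row_quantile(x, [0.25, 0.75])
    b = q75 + (q75 - q25)

    def group_part(xg: np.ndarray, ng: np.ndarray) -> np.ndarray:
        above = xg > b[:, None]  # NaN > b is False
        n_above = np.sum(above, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_above = np.nansum(np.where(above, xg, 0.0), axis=1) / n_above
            part = 100.0 * (n_above / ng) * ((mean_above - b) / b)
        return np.where(n_above == 0, 0.0, part)

    n1, n2 = _counts(xn), _counts(xd)
    score = group_part(xd, n2) - group_part(xn, n1)
    bad = (b <= 0) | (n1 == 0) | (n2 == 0)
    return np.where(bad, np.nan, score)


# ---------------------------------------------------------------------------
# score table
# ---------------------------------------------------------------------------

_SCORE_FUNCS = {
    "t": t_statistic,
    "os": os_score,
    "ort": ort_score,
    "gti": gti_score,
}

_FLAG_REASONS = {
    "t": "pooled sd 0 or <2 informative samples in a group",
    "copa": "all-sample mad 0 or empty group",
    "os": "all-sample mad 0 or empty group",
    "ort": "group-centred mad 0 or n1<2 or empty disease group",
    "gti": "cutoff b <= 0 (shift data to a positive log scale) or empty group",
}


def _descending_ranks(scores: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    """Ranks 1..p: defined genes by descending score then id; NaN last."""
    order = sorted(
        range(len(gene_ids)),
        key=lambda i: (
            np.isnan(scores[i]),
            -scores[i] if not np.isnan(scores[i]) else 0.0,
            gene_ids[i],
        ),
    )
    ranks = np.empty(len(gene_ids), dtype=int)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    return ranks


def score_all(
    matrix: ExpressionMatrix,
    groups: GroupAssignment,
    methods: Sequence[str] = METHODS,
    copa_r: int = 90,
) -> ScoreTable:
    """Compute the requested statistics and descending ranks per gene."""
    methods = list(methods)
    if not methods:
        raise ValueError("no methods requested")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")

    table = pd.DataFrame(index=pd.Index(matrix.gene_ids, name="gene"))
    flags: list[list[str]] = [[] for _ in range(matrix.n_genes)]
    for m in methods:
        if m == "copa":
            s = copa_score(matrix, groups, r=copa_r)
        else:
            s = _SCORE_FUNCS[m](matrix, groups)
        table[f"score_{m}"] = s
        table[f"rank_{m}"] = _descending_ranks(s, matrix.gene_ids)
        for i in np.flatnonzero(np.isnan(s)):
            flags[i].append(f"{m}:{_FLAG_REASONS[m]}")
    table["flags"] = ["; ".join(f) for f in flags]
    config = {
        "methods": ",".join(methods),
        "copa_r": copa_r,
        "quantile_method": QUANTILE_METHOD,
        "cutoff": "q75+IQR",
        "cutoff_source": "all (normal-only for ort)",
    }
    return ScoreTable(table=table, methods=methods, config=config)
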