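import numpy as np
import pytest

from gti import ExpressionMatrix, GroupAssignment


def make_matrix(values, labels, gene_ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i:03d}" for i in range(n_genes)]
    sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    return (
        ExpressionMatrix(values=values, gene_ids=gene_ids, sample_ids=sample_ids),
        GroupAssignment(np.asarray(labels, dtype=int)),
    )


def random_small_matrix(rng, missing_rate=0.0, loc=5.0):
    """Small random matrix around a positive log-scale baseline.

    <=10 genes, <=8 samples per group, optional missing cells (always
    keeping >=2 informative samples per group per gene).
    """
    n_genes = int(rng.integers(2, 11))
    n1 = int(rng.integers(3, 9))
    n2 = int(rng.integers(3, 9))
    values = loc + rng.standard_normal((n_genes, n1 + n2))
    # sprinkle a few outliers so the statistics exercise non-trivial paths
    n_out = int(rng.integers(0, n_genes + 1))
    for i in rng.choice(n_genes, size=n_out, replace=False):
        j = int(rng.integers(0, n1 + n2))
        values[i, j] += rng.uniform(3, 10)
    if missing_rate > 0:
        labels = np.r_[np.ones(n1, int), np.full(n2, 2, int)]
        mask = rng.random((n_genes, n1 + n2)) < missing_rate
        for i in range(n_genes):
            for grp in (1, 2):
                cols = np.flatnonzero((labels == grp) & mask[i])
                keep_needed = 2 - ((labels == grp) & ~mask[i]).sum()
                if keep_needed > 0:
                    mask[i, cols[:keep_needed]] = False
        values[mask] = np.nan
    labels = [1] * n1 + [2] * n2
    return make_matrix(values, labels)


def split(matrix, groups, gene):
    """(normal values, disease values) lists for one gene, NaNs kept."""
    row = matrix.masked()[gene]
    return (
        row[groups.normal_mask].tolist(),
        row[groups.disease_mask].tolist(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
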