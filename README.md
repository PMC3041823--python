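# gti

Outlier-gene statistics for two-group expression matrices: the gene
tissue index (**GTI**) plus four comparator statistics (**t**, **COPA**,
**OS**, **ORT**), with permutation p-values, a spike-in ROC/AUC
simulation benchmark, and method-comparison diagnostics for integrated
multi-study datasets with varying numbers of informative samples per
gene.

An *outlier gene* is over-expressed in a subset of disease samples but
expressed at low levels in the normal samples and the remaining disease
samples — the typical profile of subtype-restricted oncogenes. The GTI
scores each group as

```
100 × (proportion of samples above the cut-off B) × (mean(outliers) − B) / B
```

with `B = q75 + IQR` computed over **all** informative samples of the
gene, and reports the disease-group score minus the normal-group score.
Positive values flag disease outliers, negative values normal-group
outliers.

Conventions (recorded in every output header):

- quantiles use linear interpolation between order statistics
  (numpy `method="linear"`, the classical type-7 rule);
- the MAD carries the 1.4826 normal-consistency factor;
- cut-off comparisons are strict (`>`);
- group 1 = normal/reference, group 2 = disease;
- undefined scores (zero MAD, non-positive cut-off, too few informative
  samples) are flagged and rank after all defined genes;
- all statistics operate on per-gene informative (non-missing) sample
  sets, the regime of multi-platform integrated matrices.

## File formats

Tab-separated text throughout. Expression matrix: first column gene id,
header row of sample ids, `NA` or empty fields for missing cells.
Group file: two columns (sample id, label `1`/`2` or
`normal`/`cancer`). `#`-prefixed lines are metadata.

## CLI

```sh
# score all genes with every method
gti score --matrix expr.tsv --groups groups.tsv \
    --methods gti,copa,os,ort,t --copa-r 90 --out scores.tsv

# permutation p-values (add-one estimator, per-gene nulls by default)
gti permute --matrix expr.tsv --groups groups.tsv \
    --method gti --n-perm 1000 --seed 7 --out pvals.tsv

# spike-in simulation benchmark (ROC table + AUC summary)
gti simulate --k 10 --m 2 --n-genes 1000 --n1 30 --n2 30 \
    --reps 50 --seed 7 --out roc.tsv --plot roc.png

# top-N overlap regions and sample-count correlations
gti compare --scores scores.tsv --matrix expr.tsv --groups groups.tsv --top 100

# deterministic test fixtures (null / spiked / multistudy)
gti fixture --kind spiked --outdir fx/ --seed 1 --n-genes 200 --k 5 --m 3
```

Every subcommand exits 0 on success and non-zero with a one-line
`Error:` diagnostic on validation failure.

## Python API

```python
import numpy as np
from gti import (ExpressionMatrix, GroupAssignment, score_all,
                 permutation_pvalues, SimulationConfig, roc_experiment)

matrix = ExpressionMatrix(values, gene_ids, sample_ids)   # NaN = missing
groups = GroupAssignment(labels)                          # 1=normal, 2=disease
table = score_all(matrix, groups)                         # scores + ranks
perm = permutation_pvalues(matrix, groups, method="gti", n_perm=1000, seed=7)
roc = roc_experiment(SimulationConfig(k=10, m=2.0, n_reps=50, seed=7))
```

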