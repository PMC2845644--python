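# sagat

Knowledge-augmented differential expression analysis for transcriptomics.

Small expression experiments — one to a handful of replicate arrays — carry
too little information to estimate per-gene variability, so simple scores
like the mean log fold change d̄ᵢ, or per-gene t-statistics, rank
differentially expressed (DE) genes poorly. Large public compendia of
arrays on the same platform, however, encode which genes are *coexpressed*.
`sagat` exploits that: it decomposes a compendium into **eigengenes** by
singular value decomposition and lets coexpressed genes share variance
information when scoring a small novel dataset.

## The method

Given a complete, row-standardized knowledge matrix **X** (genes × arrays),

&nbsp;&nbsp;&nbsp;&nbsp;**X** = **U S Vᵀ**,

the weight matrix **W** is the first *M* columns of **U**. Because **W**
has orthonormal columns, **Wᵀ** is its pseudoinverse, and a novel dataset
**D** of per-replicate log expression ratios (genes × m) projects into
eigengene space as **Ê** = **Wᵀ D** — the least-squares optimal
representation of **D** in terms of the compendium's coexpression
structure. Per-eigengene sample variances s²ⱼ are shrunk toward an
empirical-Bayes scaled-inverse-χ² prior (d₀, s₀²), giving moderated
variances s̃²ⱼ, and each gene is scored with the t-like statistic

&nbsp;&nbsp;&nbsp;&nbsp;Tᵢ = d̄ᵢ / √( (1/m) Σⱼ w²ᵢⱼ s̃²ⱼ ).

Genes that load on the same eigengenes pool their variance information, so
DE genes sitting in coexpression modules are measured more precisely than
any single-gene statistic allows. For single-replicate datasets (m = 1,
where per-gene statistics are impossible) the absolute projected log ratio
|eⱼ| stands in for the eigengene variance:
Tᵢ = dᵢ / √( Σⱼ w²ᵢⱼ |eⱼ| ).

The package also ships the surrounding machinery:

- **expression**: tab-delimited matrix I/O, quantile normalization,
  missing-value handling (array exclusion below a 10% threshold, otherwise
  KNN imputation), row standardization;
- **decomposition**: thin SVD with a deterministic sign convention, the
  default eigengene-count rule *M* ≈ arrays/2, and an AUC-based tuner;
- **modularity**: binarized-covariance module detection (threshold 0.25,
  complete-linkage biclustering, all-ones diagonal blocks) with a
  within-row permutation null;
- **simulate**: multivariate-normal compendia with planted
  block-equicovariance modules and paired DE-spiked datasets, plus the
  paired AUC/TPR study against fold change;
- **evaluate**: rank-sum ROC AUC on |score|, TPR at fixed FPR,
  full-data gold standards (BH-FDR on the moderated t), effective-arrays
  standard-curve interpolation, non-overlapping subset evaluation;
- **rank_products**: geometric-mean-rank integration across platforms with
  permutation per-family error rates (PFER).

## Worked example

Simulate a 1000-gene compendium (200 arrays; four 15-gene modules of DE
genes with within-module covariance 4) and a paired single-replicate
dataset with 100 DE genes, then score it with and without knowledge:

```python
import numpy as np
from sagat import (SimConfig, simulate_knowledge, simulate_dataset,
                   standardize_rows, decompose, weight_matrix,
                   sagat_pipeline, fold_change_scores, roc_auc,
                   run_simulation_study)

cfg = SimConfig(seed=7)
knowledge, truth = simulate_knowledge(cfg)
d = decompose(standardize_rows(knowledge))
w = weight_matrix(d, d.rank)

ds = simulate_dataset(cfg, truth, rng=np.random.default_rng(7))
sagat = sagat_pipeline(ds, w)
fc = fold_change_scores(ds)
print("sagat AUC:", round(roc_auc(sagat.scores, truth.de_labels), 4))
print("fc    AUC:", round(roc_auc(fc.scores, truth.de_labels), 4))

study = run_simulation_study([cfg], n_datasets=50, seed=7)
print(study[["mean_delta_auc", "se_delta_auc", "mean_delta_tpr"]].round(4))
```

prints

```
sagat AUC: 0.8586
fc    AUC: 0.7862
 mean_delta_auc  se_delta_auc  mean_delta_tpr
         0.0143        0.0039          0.0292
```

On this single dataset the eigengene score lifts the ROC AUC for
recovering the 100 planted DE genes from 0.786 to 0.859; across 50
datasets drawn from the same configuration the mean paired AUC improvement
is 0.014 (SE 0.004), and the true-positive rate at a 5% false-positive
rate improves by 0.029. The improvement comes from the 60 DE genes inside
planted modules, whose score denominators borrow variability information
from their module partners.

The same pipeline is available from the shell:

```
sagat simulate --n-datasets 50 --seed 7 --out-dir runs/
sagat decompose --knowledge runs/knowledge.tsv --m auto --out runs/w.h5
sagat score --data runs/dataset.tsv --weights runs/w.h5 --out runs/scores.tsv
```

Every command writes a `*.provenance.json` (parameters, seeds, input
checksums) beside its outputs.

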