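# Methods

## Model

`sagat` treats a large single-platform expression compendium as a source
of coexpression knowledge. After completion (array exclusion or KNN
imputation), optional log transform, quantile normalization, and row
standardization, the compendium **X** (genes × arrays) is factored by thin
SVD, **X** = **U S Vᵀ**. Columns of **U** are eigenarrays; the rows of
**S Vᵀ** are scaled eigengenes. Each gene's expression is modeled as a
linear combination of eigengene activities with weights from **W**, the
first *M* columns of **U**.

A novel dataset **D** (genes × m replicates of log expression ratios) is
projected into eigengene space by **Ê** = **Wᵀ D**. Since **W** has
orthonormal columns this is the pseudoinverse projection, i.e. the
least-squares-optimal reconstruction of **D** in the compendium's
coexpression basis. Writing ε̄ⱼ for the mean log ratio of eigengene j and
assuming the eigengene log ratios are independent with ε̄ⱼ ~ N(0, σ²ⱼ/m),
the variance of a gene's mean log ratio decomposes as
Var(d̄ᵢ) ≈ Σⱼ w²ᵢⱼ σ²ⱼ / m. Replacing the unknown σ²ⱼ with
empirical-Bayes moderated estimates s̃²ⱼ gives the score

    T_i = dbar_i / sqrt( (1/m) * sum_j w_ij^2 * stilde2_j ).

With identity weights this is exactly the one-sample moderated t (a unit
test asserts equality to 1e-10); with a real **W** it pools variance
information across coexpressed genes.

**Assumptions.** (i) Detectable multi-gene transcriptional modules
generate the compendium covariance; (ii) gene expression is approximately
linear in eigengene activities; (iii) eigengene log ratios are
approximately independent and normal. None is enforced; the score remains
usable as a ranking statistic when they are violated, but the analytic
variance decomposition is then only approximate, which is one reason no
closed-form p-value is offered (a seeded sign-flip permutation p-value is
provided instead).

## Variance moderation

The prior on eigengene variances is a scaled inverse-χ²(d₀, s₀²) fitted
by moment matching on log variances: with e = log s² − ψ(df/2) +
log(df/2), the prior df solve ψ′(d₀/2) = Var(e) − ψ′(df/2) by Newton
inversion of the trigamma function, and s₀² = exp(mean(e) + ψ(d₀/2) −
log(d₀/2)). If the moment estimate of Var(e) is non-positive the prior df
are infinite and s₀² is the plain mean of the sample variances, to which
every moderated value collapses. Posterior variances are the usual
precision-weighted compromise (d₀s₀² + df·s²ⱼ)/(d₀ + df). The
implementation is cross-checked in the test suite against Bioconductor's
`limma::squeezeVar` on the same inputs (agreement to 1e-4 relative).

## Single-replicate scoring

With m = 1 no sample variances exist. The score substitutes the absolute
projected log ratio |eⱼ| for the eigengene variance, with no 1/m factor:
T_i = d_i / sqrt(Σⱼ w²ᵢⱼ |eⱼ|). This makes the m = 1 score scale as √c
when the data are scaled by c (the m ≥ 2 score is scale-invariant); both
behaviors are asserted in tests. The surrogate is implemented behind a
dedicated function so alternative single-replicate denominators can be
swapped in without touching the multi-replicate path.

## Choosing M

Two regimes:

- **Real compendia.** The default rule `choose_M_default` returns half
  the number of compendium arrays (rounded half up): for compendium sizes
  of 4440, 14476 and 12217 arrays it selects 2220, 7238 and 6109
  eigengenes. An AUC-based tuner (`tune_M`) is provided to select M on
  data subsets against a gold standard, with ties resolved to the
  smallest M.
- **Simulated compendia.** `run_simulation_study` defaults to the maximal
  eigengene count (the full thin-SVD rank). Running the tuning protocol —
  mean AUC across a grid of M over module structures and replicate counts
  — selects the top of the grid for these 1000-gene × 200-array
  compendia. The reason is structural: with M below the rank, genes whose
  variance lives mostly in the discarded eigenarrays get systematically
  under-reconstructed denominators and hence inflated scores. In the
  simulated compendia the under-reconstructed genes are the isolated
  (mostly non-DE) ones, so truncation directly degrades DE ranking. In
  large real compendia the trailing eigenarrays are dominated by platform
  noise, which is why a truncated M can win there.

## Synthetic data generator

`SimConfig` defaults define the study conditions: 1000 genes, 100 DE,
four 15-gene DE modules (60 of the 100 DE genes in modules), 0–60
non-DE modules of the same size, within-module covariance 4 on a per-gene
variance of 5 (within-module correlation 0.8), 200 compendium arrays.
Compendia are mean-zero multivariate normal draws; the block
equicovariance is sampled as a shared module factor plus independent
residuals, which is exact and avoids factoring the full 1000×1000
covariance. Datasets add a true mean log ratio μᵢ = ±effect_size (random
sign per DE gene) to MVN noise drawn from the same block covariance
scaled by `noise_scale`, so eigengene variance borrowing is exercised.

Parameter notes, all configurable:

- `diag_var = 5`: only the off-diagonal covariance (4) is dictated by the
  module definition; 5 gives a plausible within-module correlation of 0.8
  and guarantees positive semidefiniteness (checked before sampling).
- `effect_size = 3.0` (log₂ units): calibrated once so the fold-change
  AUC of a one-replicate dataset lands mid-range (~0.72) rather than near
  chance or ceiling, making paired AUC comparisons discriminative. With
  per-gene noise SD √5 ≈ 2.24, an effect of 1.0 leaves the |fold-change|
  ranking near AUC 0.52 where no metric comparison is informative.
- `n_arrays = 200`: large enough for a stable SVD of 1000 genes at desk
  scale.
- `noise_scale = 1.0`: dataset noise has the same scale as the knowledge
  covariance.

**What the generator does and does not emulate.** It reproduces planted
block-modularity, the DE/non-DE module split, and module-correlated
dataset noise. It does not emulate heterogeneous per-gene variances
(every gene has true variance `diag_var`), heavy-tailed intensity
distributions, probe-level effects, or coherent (same-sign) regulation
within a DE module. The equal-variance simplification matters for
interpreting results: when every gene has the same true variance, the
fold change is close to the optimal ranking at large m, so the simulated
improvement of the eigengene score is concentrated at small m (largest at
m = 1–2, vanishing by m = 15) and turns slightly negative when all 900
non-DE genes are modular at m = 1. Passing tests therefore demonstrate
the borrowing mechanism and its controls, not a universal advantage on
real data, where variance heterogeneity gives moderated statistics
additional room to improve.

## Modularity characterization

Gene-gene covariance is computed on log/quantile-normalized (not
row-standardized) values, pairwise-ignoring missing entries; entries with
|cov| > 0.25 and the diagonal are set to 1. Rows/columns are ordered by
complete-linkage hierarchical clustering under a Hamming distance on
binary rows (computed via one matrix product; a Jaccard option exists),
and modules are maximal contiguous diagonal runs in which every pairwise
entry is 1, resolved greedily left to right, kept at size ≥ 15 at full
scale (≥ 5 for 1000-gene matrices). The permutation null shuffles the
columns of each row independently, destroying covariance while preserving
marginals; on 1000-gene synthetic compendia it yields zero ≥15-gene
modules in ≥95% of 100 permutations.

## Evaluation harness

DE calls are made irrespective of sign, so all rankings use |score|. AUC
uses the rank-sum identity with average ranks on ties (equal to pair
counting; cross-checked against brute force and scikit-learn). TPR at
FPR is evaluated at the most permissive threshold with FPR ≤ the level
(step convention). Gold standards for highly replicated datasets label
the top n genes by |fold change| or |moderated t|, with n the count of
moderated-t genes passing Benjamini–Hochberg FDR < 0.05 (two-sided p on
d₀ + m − 1 df). Effective array counts invert a standard curve of
fold-change AUC versus sample size; the curve is made monotone by
isotonic regression before piecewise-linear inversion, and out-of-range
observations clamp to the nearest endpoint with a flag. Non-overlapping
replicate subsets are formed by one seeded shuffle per size followed by
consecutive chunking.

## Rank products and PFER

Each platform ranks genes by signed score (descending for upregulation,
ascending for down; ties averaged); the rank product is the geometric
mean over platforms, computed separately per direction on the gene
intersection. The null permutes each platform's ranks independently and
uniformly; PFER(g) is the mean count of null rank products ≤ gene g's
observed value — the expected number of false positives at a cutoff
placed exactly at g. The permutation estimate is validated against
exhaustive enumeration of all (n!)² rank assignments for two platforms
and n ≤ 6 genes. Genes significant in both directions are flagged as
inconsistent.

## Numerical and design choices

- SVD sign ambiguity fixed by making the largest-magnitude entry of each
  U column positive; ties in singular values keep backend order.
- `choose_M_default` rounds half up (4440 → 2220; odd counts need a
  rule).
- Quantile normalization: tied values receive the mean of their pooled
  rank means; columns with unequal missingness are aligned by rank
  quantile interpolation; missing entries never enter the pooled means
  and stay missing.
- KNN imputation uses the k = 10 nearest complete genes by Euclidean
  distance over the target gene's observed columns, unweighted mean at
  the missing column; the exclusion branch never alters retained values.
- Zero score denominators raise with the offending gene ids rather than
  returning infinities; genes absent from **W** are dropped and reported
  by `align_genes`, never silently scored.
- Eigengene variances use the m − 1 (sample) denominator.
- Pipeline order is fixed and documented: complete → log/quantile →
  standardize.

## Known limitations

- The m = 1 denominator is a surrogate, not a variance estimate; its
  score scales with √ of the data scale.
- The generator's equal per-gene variances understate the advantage of
  moderated statistics at large m (see above); conclusions at m ≥ 5 rest
  on the structure of the score, not on simulated superiority.
- Modules are recovered as contiguous diagonal runs after clustering, so
  overlapping or nested modules are split greedily.
- PFER uses rank permutations, not expression-label permutations; with
  few replicates the latter would be coarser but more faithful to the
  data-generating process.
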