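"""Eigengene projection and variance-moderated differential expression scores.

A novel dataset D of per-replicate log expression ratios is projected into
the compendium's eigengene space by the pseudoinverse of the weight matrix,
Ehat = W^T D (optimal in the least-squares sense because W has orthonormal
columns). Per-eigengene sample variances are shrunk toward an
empirical-Bayes prior, and each gene's score divides its mean log ratio by
a standard error assembled from the moderated eigengene variances weighted
by the gene's squared eigengene loadings:

    T_i = dbar_i / sqrt( (1/m) * sum_j w_ij^2 * stilde2_j )

Coexpressed genes share eigengenes and hence share variance information,
which is where the method's power gain over per-gene statistics comes
from. With a single replicate the eigengene variances are undefined and
the absolute projected log ratio |e_j| stands in for the variance, with no
1/m factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, polygamma
from scipy.stats import rankdata

from .decomposition import WeightMatrix
from .expression import ExpressionMatrix

__all__ = [
    "Projection",
    "ModeratedVariances",
    "ScoreTable",
    "align_genes",
    "project",
    "moderate_variances",
    "sagat_scores",
    "sagat_scores_single",
    "fold_change_scores",
    "moderated_t_scores",
    "sagat_pipeline",
    "permutation_pvalues",
]


@dataclass
class Projection:
    """A dataset mapped into eigengene space.

    ``Ehat`` is M x m (eigengenes x replicates); ``eigengene_means`` its
    row means; ``raw_variances`` the per-eigengene sample variances
    (m - 1 degrees of freedom), defined only for m > 1.
    """

    Ehat: np.ndarray
    eigengene_means: np.ndarray
    raw_variances: np.ndarray | None
    m: int


@dataclass
class ModeratedVariances:
    """Empirical-Bayes shrunk eigengene variances.

    The prior is a scaled inverse chi-square with ``d0`` degrees of
    freedom and scale ``s0_sq``, fitted to the observed sample variances
    by moment matching on the log scale. Each posterior variance is the
    precision-weighted compromise

        stilde2_j = (d0 * s0_sq + df * s2_j) / (d0 + df).
    """

    s_tilde_sq: np.ndarray
    d0: float
    s0_sq: float
    df: float


@dataclass
class ScoreTable:
    """Per-gene scores with |score|-descending ranks (average ties)."""

    gene_ids: list[str]
    scores: np.ndarray
    metric: str = "sagat"

    @property
    def ranks(self) -> np.ndarray:
        # rank 1 = largest |score|; average ranks on ties
        return rankdata(-np.abs(self.scores), method="average")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "score": self.scores,
                "rank": self.ranks,
            }
        )


def align_genes(
    dataset: ExpressionMatrix, w: WeightMatrix
) -> tuple[ExpressionMatrix, WeightMatrix, dict[str, list[str]]]:
    """Restrict dataset and weights to their common genes, in weight order.

    Returns the aligned pair plus a report of identifiers dropped from
    each side. Raises on an empty intersection.
    """
    data_idx = {g: i for i, g in enumerate(dataset.gene_ids)}
    shared = [g for g in w.gene_ids if g in data_idx]
    if not shared:
        raise ValueError("dataset and weight matrix share no genes")
    dropped = {
        "dataset_only": [g for g in dataset.gene_ids if g not in set(w.gene_ids)],
        "weights_only": [g for g in w.gene_ids if g not in data_idx],
    }
    rows = [data_idx[g] for g in shared]
    ds = ExpressionMatrix(
        dataset.values[rows].copy(), shared, list(dataset.array_ids)
    )
    keep = [i for i, g in enumerate(w.gene_ids) if g in data_idx]
    wal = WeightMatrix(W=w.W[keep].copy(), M=w.M, gene_ids=shared)
    return ds, wal, dropped


def project(dataset: ExpressionMatrix, w: WeightMatrix) -> Projection:
    """Map a dataset into eigengene space: Ehat = W^T D.

    Requires the dataset genes to already match the weight-matrix gene
    order (use :func:`align_genes` first).
    """
    if dataset.gene_ids != w.gene_ids:
        raise ValueError("dataset genes not aligned to weight matrix")
    if dataset.n_arrays == 0:
        raise ValueError("dataset has no replicate columns")
    if dataset.has_missing:
        raise ValueError("dataset contains missing values")
    m = dataset.n_arrays
    Ehat = w.W.T @ dataset.values
    means = Ehat.mean(axis=1)
    raw = Ehat.var(axis=1, ddof=1) if m > 1 else None
    return Projection(Ehat=Ehat, eigengene_means=means, raw_variances=raw, m=m)


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = _trigamma(y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderate_variances(
    raw: np.ndarray, df: float, d0_override: float | None = None
) -> ModeratedVariances:
    """Fit a scaled inverse-chi-square prior to sample variances and shrink.

    The prior parameters (d0, s0_sq) are estimated by matching the mean
    and variance of log s2 under the scaled-F sampling model (trigamma
    inversion). When the method-of-moments variance estimate is
    nonpositive the prior degrees of freedom are infinite and every
    moderated variance collapses to s0_sq.

    Parameters
    ----------
    raw
        Per-unit sample variances (eigengenes or genes), each on ``df``
        degrees of freedom.
    df
        Residual degrees of freedom of each variance (m - 1).
    d0_override
        Force the prior degrees of freedom (0 disables shrinkage;
        ``np.inf`` collapses to the prior scale).
    """
    s2 = np.asarray(raw, dtype=float)
    if df < 1:
        raise ValueError("need at least 1 residual degree of freedom")
    if (s2 < 0).any():
        raise ValueError("negative variance")
    pos = s2 > 0
    if pos.sum() < 2:
        raise ValueError("need at least 2 positive variances to fit a prior")

    # moment matching on log variances (zeros offset to smallest positive)
    floor = s2[pos].min() * 1e-8
    z = np.log(np.maximum(s2, floor))
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = e.size
    evar = float(((e - emean) ** 2).sum() / (n - 1)) - float(_trigamma(df / 2.0))

    if d0_override is not None:
        d0 = float(d0_override)
        if np.isinf(d0) or d0 <= 0:
            s0_sq = float(s2.mean())
        else:
            s0_sq = float(
                np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
            )
    elif evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no detectable spread beyond sampling noise: infinite prior df,
        # prior scale = plain mean of the variances
        d0 = np.inf
        s0_sq = float(s2.mean())

    if np.isinf(d0):
        s_tilde = np.full_like(s2, s0_sq)
    elif d0 == 0:
        s_tilde = s2.copy()
    else:
        s_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
    return ModeratedVariances(s_tilde_sq=s_tilde, d0=d0, s0_sq=s0_sq, df=df)


def _score_denominator(W: np.ndarray, var_terms: np.ndarray) -> np.ndarray:
    return (W * W) @ var_terms


def sagat_scores(
    dataset: ExpressionMatrix, w: WeightMatrix, mv: ModeratedVariances
) -> ScoreTable:
    """Variance-moderated eigengene-pooled DE score for m >= 2 replicates.

    T_i = dbar_i / sqrt( (1/m) * sum_j w_ij^2 * stilde2_j ), where dbar_i
    is the mean log ratio of gene i and stilde2_j the moderated variance
    of eigengene j.
    """
    if dataset.gene_ids != w.gene_ids:
        raise ValueError("dataset genes not aligned to weight matrix")
    m = dataset.n_arrays
    if m < 2:
        raise ValueError("sagat_scores requires m >= 2 (see sagat_scores_single)")
    dbar = dataset.values.mean(axis=1)
    var_of_mean = _score_denominator(w.W, mv.s_tilde_sq) / m
    zero = var_of_mean <= 0
    if zero.any():
        genes = [g for g, z in zip(dataset.gene_ids, zero) if z]
        raise ValueError(f"zero score variance for genes: {genes}")
    return ScoreTable(
        gene_ids=list(dataset.gene_ids),
        scores=dbar / np.sqrt(var_of_mean),
        metric="sagat",
    )


def sagat_scores_single(
    dataset: ExpressionMatrix, w: WeightMatrix
) -> ScoreTable:
    """Single-replicate variant of the score.

    With m = 1 eigengene variances are undefined; the absolute projected
    log ratio |e_j| is substituted as the variance surrogate:

        T_i = d_i / sqrt( sum_j w_ij^2 * |e_j| ).
    """
    if dataset.gene_ids != w.gene_ids:
        raise ValueError("dataset genes not aligned to weight matrix")
    if dataset.n_arrays != 1:
        raise ValueError("sagat_scores_single requires exactly one replicate")
    d = dataset.values[:, 0]
    e = w.W.T @ d
    denom_sq = _score_denominator(w.W, np.abs(e))
    zero = denom_sq <= 0
    scores = np.zeros_like(d)
    nonzero = ~zero
    scores[nonzero] = d[nonzero] / np.sqrt(denom_sq[nonzero])
    if (zero & (d != 0)).any():
        genes = [
            g for g, z, di in zip(dataset.gene_ids, zero, d) if z and di != 0
        ]
        raise ValueError(f"zero score denominator for genes: {genes}")
    return ScoreTable(
        gene_ids=list(dataset.gene_ids), scores=scores, metric="sagat"
    )


def fold_change_scores(dataset: ExpressionMatrix) -> ScoreTable:
    """Mean log expression ratio per gene."""
    if dataset.n_arrays < 1:
        raise ValueError("dataset has no replicate columns")
    return ScoreTable(
        gene_ids=list(dataset.gene_ids),
        scores=dataset.values.mean(axis=1),
        metric="fold_change",
    )


def moderated_t_scores(
    dataset: ExpressionMatrix, d0_override: float | None = None
) -> ScoreTable:
    """One-sample moderated t: gene-level empirical-Bayes variance shrinkage.

    Not applicable with a single replicate (no variance estimate); raises
    in that case.
    """
    m = dataset.n_arrays
    if m < 2:
        raise ValueError(
            "moderated t requires two or more replicates to score genes"
        )
    dbar = dataset.values.mean(axis=1)
    s2 = dataset.values.var(axis=1, ddof=1)
    mv = moderate_variances(s2, df=m - 1, d0_override=d0_override)
    return ScoreTable(
        gene_ids=list(dataset.gene_ids),
        scores=dbar / np.sqrt(mv.s_tilde_sq / m),
        metric="moderated_t",
    )


def sagat_pipeline(
    dataset: ExpressionMatrix,
    w: WeightMatrix,
    d0_override: float | None = None,
) -> ScoreTable:
    """Score an aligned dataset, dispatching on the replicate count."""
    if dataset.n_arrays == 1:
        return sagat_scores_single(dataset, w)
    proj = project(dataset, w)
    mv = moderate_variances(
        proj.raw_variances, df=dataset.n_arrays - 1, d0_override=d0_override
    )
    return sagat_scores(dataset, w, mv)


def permutation_pvalues(
    dataset: ExpressionMatrix,
    w: WeightMatrix,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Sign-flip permutation p-values for the eigengene-pooled score.

    The score distribution has no tractable closed form, so significance
    is assessed by flipping the sign of each replicate column uniformly at
    random and recomputing scores; the p-value of gene i is the fraction
    of permutations whose |score| meets or exceeds the observed |score|
    (with the +1 correction for the identity permutation).
    """
    rng = np.random.default_rng(seed)
    observed = np.abs(sagat_pipeline(dataset, w).scores)
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=dataset.n_arrays)
        permuted = ExpressionMatrix(
            dataset.values * flips, list(dataset.gene_ids), list(dataset.array_ids)
        )
        perm_scores = np.abs(sagat_pipeline(permuted, w).scores)
        exceed += perm_scores >= observed
    return (exceed + 1.0) / (n_perm + 1.0)
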