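"""DE prediction evaluation: ROC AUC, TPR at fixed FPR, gold standards,
and effective-number-of-arrays interpolation.

Scores are always ranked by absolute value (DE calls are made
irrespective of sign). The AUC uses the rank-sum identity with average
ranks on ties, which equals the pair-counting definition. Gold standards
for highly replicated datasets are built by scoring the full dataset and
labelling the top n genes, with n set by the count of moderated-t genes
passing a Benjamini-Hochberg FDR cutoff. A method's AUC converts to an
"effective number of arrays" by inverting a standard curve of
fold-change AUC versus sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .decomposition import WeightMatrix
from .expression import ExpressionMatrix
from .scoring import (
    align_genes,
    fold_change_scores,
    moderate_variances,
    moderated_t_scores,
    sagat_pipeline,
)

__all__ = [
    "EvalResult",
    "StandardCurve",
    "roc_auc",
    "tpr_at_fpr",
    "build_gold_standard",
    "effective_arrays",
    "subset_evaluation",
]


@dataclass
class EvalResult:
    auc: float
    tpr_at_fpr: float
    fpr_level: float
    n_pos: int
    n_neg: int


@dataclass
class StandardCurve:
    """Fold-change AUC as a function of array count, for inversion."""

    n_arrays: np.ndarray
    auc: np.ndarray

    def __post_init__(self) -> None:
        self.n_arrays = np.asarray(self.n_arrays, dtype=float)
        self.auc = np.asarray(self.auc, dtype=float)
        if self.n_arrays.size < 2:
            raise ValueError("standard curve needs at least 2 points")
        if not np.all(np.diff(self.n_arrays) > 0):
            raise ValueError("n_arrays must be strictly increasing")


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")
    return labels, ~labels


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC of the |score| ranking via the rank-sum identity.

    Equals the probability that a random positive outranks a random
    negative, counting ties as 1/2.
    """
    pos, neg = _check_labels(labels)
    r = rankdata(np.abs(np.asarray(scores, dtype=float)), method="average")
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    return float((r[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def tpr_at_fpr(
    scores: np.ndarray, labels: np.ndarray, fpr_level: float = 0.05
) -> float:
    """TPR at the most permissive |score| threshold with FPR <= fpr_level."""
    pos, neg = _check_labels(labels)
    a = np.abs(np.asarray(scores, dtype=float))
    # thresholds at distinct |score| values, descending
    order = np.argsort(-a, kind="stable")
    sorted_pos = pos[order]
    thresholds = a[order]
    tp = np.cumsum(sorted_pos)
    fp = np.cumsum(~sorted_pos)
    # collapse ties: evaluate only at the last index of each distinct value
    distinct = np.nonzero(np.diff(thresholds, append=-np.inf) != 0)[0]
    tpr = tp[distinct] / pos.sum()
    fpr = fp[distinct] / neg.sum()
    ok = fpr <= fpr_level
    return float(tpr[ok].max()) if ok.any() else 0.0


def build_gold_standard(
    full_dataset: ExpressionMatrix,
    method: str = "modt",
    fdr: float = 0.05,
) -> tuple[dict[str, int], int]:
    """Derive DE labels from a highly replicated dataset.

    The label count n_top is the number of genes whose moderated-t
    statistic is significant at a Benjamini-Hochberg FDR below ``fdr``
    (two-sided p on d0 + m - 1 degrees of freedom); the labelled genes
    are the n_top largest by |fold change| or |moderated t| depending on
    ``method``.
    """
    if method not in ("fc", "modt"):
        raise ValueError(f"unknown gold-standard method {method!r}")
    m = full_dataset.n_arrays
    if m < 2:
        raise ValueError("gold standard requires a replicated dataset")
    modt = moderated_t_scores(full_dataset)
    s2 = full_dataset.values.var(axis=1, ddof=1)
    mv = moderate_variances(s2, df=m - 1)
    df_total = (mv.d0 + m - 1) if np.isfinite(mv.d0) else np.inf
    if np.isinf(df_total):
        from scipy.stats import norm

        pvals = 2 * norm.sf(np.abs(modt.scores))
    else:
        pvals = 2 * t_dist.sf(np.abs(modt.scores), df_total)
    reject, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    n_top = int(reject.sum())
    if n_top == 0:
        raise ValueError(
            "no genes significant at the FDR cutoff; relax the threshold"
        )
    chooser = modt if method == "modt" else fold_change_scores(full_dataset)
    order = np.argsort(-np.abs(chooser.scores), kind="stable")
    labels = {g: 0 for g in full_dataset.gene_ids}
    for i in order[:n_top]:
        labels[full_dataset.gene_ids[i]] = 1
    return labels, n_top


def effective_arrays(
    observed_auc: float, curve: StandardCurve
) -> tuple[float, bool]:
    """Invert the AUC-vs-sample-size standard curve at an observed AUC.

    Curve AUCs are first forced nondecreasing by isotonic regression
    (sampled AUCs can be locally non-monotone); the inverse is then
    piecewise linear. Observed AUCs outside the curve's range clamp to
    the nearest endpoint with ``out_of_range`` True.
    """
    iso = IsotonicRegression(increasing=True)
    auc_mono = iso.fit_transform(curve.n_arrays, curve.auc)
    lo, hi = float(auc_mono[0]), float(auc_mono[-1])
    if observed_auc <= lo:
        return float(curve.n_arrays[0]), observed_auc < lo
    if observed_auc >= hi:
        return float(curve.n_arrays[-1]), observed_auc > hi
    # invert: drop duplicate AUC plateaus so interp is well defined
    keep = np.concatenate(([True], np.diff(auc_mono) > 0))
    return (
        float(np.interp(observed_auc, auc_mono[keep], curve.n_arrays[keep])),
        False,
    )


def subset_evaluation(
    full_dataset: ExpressionMatrix,
    subset_sizes: list[int],
    metrics: list[str],
    w: WeightMatrix,
    gold: dict[str, int],
    seed: int = 0,
    fpr_level: float = 0.05,
) -> pd.DataFrame:
    """Score non-overlapping replicate subsets with each applicable metric.

    Replicates are shuffled once per subset size (seeded) and chunked
    consecutively into floor(m / size) disjoint subsets. The moderated t
    is skipped at size 1 (it needs a variance estimate).
    """
    known = {"sagat", "fc", "modt"}
    bad = set(metrics) - known
    if bad:
        raise ValueError(f"unknown metrics: {sorted(bad)}")
    m = full_dataset.n_arrays
    rng = np.random.default_rng(seed)
    label_arr_cache: dict[tuple[str, ...], np.ndarray] = {}
    records = []
    for size in subset_sizes:
        if size > m:
            raise ValueError(f"subset size {size} exceeds {m} replicates")
        perm = rng.permutation(m)
        n_subsets = m // size
        for si in range(n_subsets):
            cols = perm[si * size : (si + 1) * size]
            sub = ExpressionMatrix(
                full_dataset.values[:, cols],
                list(full_dataset.gene_ids),
                [full_dataset.array_ids[c] for c in cols],
            )
            for metric in metrics:
                if metric == "modt" and size == 1:
                    continue  # needs a fold-change variance estimate
                if metric == "sagat":
                    ds, wal, _ = align_genes(sub, w)
                    table = sagat_pipeline(ds, wal)
                elif metric == "fc":
                    table = fold_change_scores(sub)
                else:
                    table = moderated_t_scores(sub)
                key = tuple(table.gene_ids)
                if key not in label_arr_cache:
                    label_arr_cache[key] = np.array(
                        [gold[g] for g in table.gene_ids]
                    )
                labels = label_arr_cache[key]
                records.append(
                    {
                        "subset_size": size,
                        "subset": si,
                        "metric": metric,
                        "auc": roc_auc(table.scores, labels),
                        "tpr_at_fpr": tpr_at_fpr(
                            table.scores, labels, fpr_level
                        ),
                        "n_pos": int(labels.sum()),
                        "n_neg": int((1 - labels).sum()),
                    }
                )
    return pd.DataFrame.from_records(records)
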