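"""Coexpression modularity of a compendium via binarized covariance.

The gene-gene sample covariance matrix is thresholded on absolute value to
a 0/1 adjacency, hierarchically biclustered (complete linkage on a binary
row distance), and scanned for diagonal blocks in which every pairwise
entry is 1 — these cliques are the expression modules. A permutation null
(independent within-row shuffles destroying gene-gene covariance while
preserving marginals) calibrates how often such blocks arise by chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .expression import ExpressionMatrix

__all__ = [
    "ModuleSet",
    "binarize_covariance",
    "bicluster_order",
    "extract_modules",
    "permutation_null",
    "module_membership_stats",
]


@dataclass
class ModuleSet:
    """Disjoint gene groups whose pairwise binarized covariances are all 1."""

    modules: list[list[str]]
    min_size: int
    ordering: np.ndarray
    threshold: float

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def sizes(self) -> list[int]:
        return [len(m) for m in self.modules]

    def gene_to_module(self) -> dict[str, int]:
        return {g: i for i, mod in enumerate(self.modules) for g in mod}


def binarize_covariance(
    x: ExpressionMatrix, threshold: float = 0.25
) -> np.ndarray:
    """Threshold the absolute gene-gene covariance to a 0/1 matrix.

    Covariance is computed pairwise across arrays, ignoring missing
    values. Entries with |cov| > threshold and the diagonal are set to 1.
    """
    if x.n_arrays < 2:
        raise ValueError("covariance requires at least 2 arrays")
    if x.has_missing:
        # pairwise-complete covariance
        cov = pd.DataFrame(x.values.T).cov(min_periods=2).to_numpy()
    else:
        cov = np.cov(x.values, ddof=1)
    b = (np.abs(cov) > threshold).astype(np.uint8)
    np.fill_diagonal(b, 1)
    return b


def bicluster_order(b: np.ndarray, metric: str = "hamming") -> np.ndarray:
    """Deterministic leaf ordering from complete-linkage clustering.

    Rows of the symmetric binary matrix are clustered under a binary
    distance (``hamming`` or ``jaccard``); the same permutation applies to
    rows and columns.
    """
    if b.shape[0] != b.shape[1]:
        raise ValueError("expected a square matrix")
    if metric not in ("hamming", "jaccard"):
        raise ValueError(f"unsupported metric {metric!r}")
    n = b.shape[0]
    if n < 3:
        return np.arange(n)
    if metric == "hamming":
        # hamming(a_i, a_j) = (|a_i| + |a_j| - 2 a_i.a_j) / n, via one GEMM
        bf = b.astype(np.float64)
        inner = bf @ bf.T
        row_sums = bf.sum(axis=1)
        dmat = (row_sums[:, None] + row_sums[None, :] - 2 * inner) / n
        np.fill_diagonal(dmat, 0.0)
        dist = squareform(dmat, checks=False)
    else:
        dist = pdist(b.astype(float), metric=metric)
    Z = linkage(dist, method="complete")
    return leaves_list(Z)


def extract_modules(
    b: np.ndarray,
    order: np.ndarray,
    min_size: int,
    gene_ids: list[str] | None = None,
    threshold: float = 0.25,
) -> ModuleSet:
    """Scan the reordered matrix for maximal all-ones diagonal blocks.

    Contiguous runs (in clustering order) whose every pairwise entry is 1
    and whose length is at least ``min_size`` become modules. Overlapping
    candidate runs are resolved greedily left to right, so modules are
    disjoint and maximal.
    """
    n = b.shape[0]
    order = np.asarray(order)
    if sorted(order.tolist()) != list(range(n)):
        raise ValueError("order is not a permutation of gene indices")
    if gene_ids is None:
        gene_ids = [str(i) for i in range(n)]
    reordered = b[np.ix_(order, order)]
    modules: list[list[str]] = []
    start = 0
    while start < n:
        # extend the run while the new element is connected to all members
        end = start + 1
        while end < n and reordered[start:end, end].all() and reordered[end, start:end].all():
            end += 1
        if end - start >= min_size:
            modules.append([gene_ids[order[i]] for i in range(start, end)])
            start = end
        else:
            start += 1
    return ModuleSet(
        modules=modules, min_size=min_size, ordering=order, threshold=threshold
    )


def permutation_null(
    x: ExpressionMatrix,
    n_perm: int = 100,
    min_size: int = 15,
    threshold: float = 0.25,
    seed: int = 0,
    metric: str = "hamming",
) -> pd.DataFrame:
    """Null distribution of module structure under within-row permutation.

    Each permutation shuffles the columns of every row independently
    (destroying gene-gene covariance) and reruns the binarize -> order ->
    extract pipeline. Returns one row per permutation with the module
    count and the largest module size found.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    vals = x.values
    n_genes, n_arrays = vals.shape
    for p in range(n_perm):
        idx = np.argsort(rng.random((n_genes, n_arrays)), axis=1)
        permuted = np.take_along_axis(vals, idx, axis=1)
        xm = ExpressionMatrix(permuted, list(x.gene_ids), list(x.array_ids))
        b = binarize_covariance(xm, threshold=threshold)
        order = bicluster_order(b, metric=metric)
        ms = extract_modules(
            b, order, min_size=min_size, gene_ids=list(x.gene_ids),
            threshold=threshold,
        )
        records.append(
            {
                "permutation": p,
                "n_modules": ms.n_modules,
                "max_module_size": max(ms.sizes) if ms.modules else 0,
            }
        )
    return pd.DataFrame.from_records(records)


def module_membership_stats(
    ms: ModuleSet, de_labels: dict[str, int]
) -> dict[str, float]:
    """Summarize module sizes and DE/non-DE membership.

    ``de_labels`` maps every gene id (at minimum all module genes) to a
    0/1 DE indicator. Percentages are fractions of each label class found
    inside any module, expressed in percent.
    """
    in_module = set(g for mod in ms.modules for g in mod)
    missing = [g for g in in_module if g not in de_labels]
    if missing:
        raise ValueError(f"labels missing for module genes: {missing[:5]}")
    n_de = sum(1 for v in de_labels.values() if v)
    n_nonde = len(de_labels) - n_de
    de_in = sum(1 for g in in_module if de_labels[g])
    nonde_in = len(in_module) - de_in
    return {
        "n_modules": ms.n_modules,
        "mean_module_size": float(np.mean(ms.sizes)) if ms.modules else 0.0,
        "pct_de_in_modules": 100.0 * de_in / n_de if n_de else 0.0,
        "pct_nonde_in_modules": 100.0 * nonde_in / n_nonde if n_nonde else 0.0,
    }
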