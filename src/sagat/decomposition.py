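"""SVD decomposition of a knowledge compendium into eigengenes.

A standardized genes x arrays compendium X factors as X = U S V^T. The
columns of U are eigenarrays (gene-space loadings of latent expression
modules) and the rows of S V^T are scaled eigengenes (their activity
across arrays). Truncating U to its first M columns yields the weight
matrix W that maps genes to the M most significant eigengenes; W has
orthonormal columns, so W^T is the pseudoinverse projection used to map
novel datasets into eigengene space.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .expression import ExpressionMatrix

__all__ = [
    "Decomposition",
    "WeightMatrix",
    "decompose",
    "choose_M_default",
    "weight_matrix",
    "tune_M",
    "save_weights",
    "load_weights",
]


@dataclass
class Decomposition:
    """Thin SVD factors of a standardized knowledge matrix.

    ``U`` is genes x r with orthonormal columns, ``S`` the nonincreasing
    singular values, ``V`` arrays x r with orthonormal columns, where
    r = min(genes, arrays).
    """

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray
    gene_ids: list[str]
    array_ids: list[str]

    @property
    def rank(self) -> int:
        return self.S.shape[0]

    def scaled_eigengenes(self, M: int | None = None) -> np.ndarray:
        """Knowledge in eigenarray space: diag(S[:M]) @ V[:, :M].T."""
        M = self.rank if M is None else M
        return self.S[:M, None] * self.V[:, :M].T


@dataclass
class WeightMatrix:
    """First M columns of U: the gene -> eigengene map.

    W^T W = I_M, so projection of a dataset D into eigengene space is the
    least-squares-optimal W^T D.
    """

    W: np.ndarray
    M: int
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if self.W.shape[1] != self.M:
            raise ValueError("W column count disagrees with M")
        if self.W.shape[0] != len(self.gene_ids):
            raise ValueError("W row count disagrees with gene_ids")


def decompose(x: ExpressionMatrix) -> Decomposition:
    """Thin SVD of a complete, row-standardized expression matrix.

    The sign of each left singular vector is fixed so its
    largest-magnitude entry is positive, making the factors deterministic
    (up to ties in singular values) across BLAS backends.
    """
    vals = x.values
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValueError("decompose requires at least a 2x2 matrix")
    if np.isnan(vals).any():
        raise ValueError("decompose requires a complete matrix")
    U, S, Vt = np.linalg.svd(vals, full_matrices=False)
    # sign convention: largest-|entry| of each U column positive
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    U = U * signs
    Vt = Vt * signs[:, None]
    return Decomposition(
        U=U, S=S, V=Vt.T, gene_ids=list(x.gene_ids), array_ids=list(x.array_ids)
    )


def choose_M_default(n_arrays: int) -> int:
    """Default eigengene count: half the number of compendium arrays.

    Rounds half up; never returns less than 1.
    """
    if n_arrays < 2:
        raise ValueError("need at least 2 arrays")
    return max(1, int(np.floor(n_arrays / 2 + 0.5)))


def weight_matrix(d: Decomposition, M: int) -> WeightMatrix:
    """Truncate the decomposition to its first M eigenarrays."""
    if not 1 <= M <= d.U.shape[1]:
        raise ValueError(
            f"M={M} out of range [1, {d.U.shape[1]}]"
        )
    return WeightMatrix(W=d.U[:, :M].copy(), M=M, gene_ids=list(d.gene_ids))


def tune_M(
    data_subsets: list[ExpressionMatrix],
    gold: dict[str, int],
    d: Decomposition,
    grid: list[int] | None = None,
    step: int = 5,
):
    """Select the eigengene count maximizing mean AUC over data subsets.

    For every candidate M the score is the mean, over subsets, of the ROC
    AUC of the eigengene-projection score against the gold-standard labels.
    Ties in the curve resolve to the smallest M.

    Returns ``(best_M, curve)`` where curve is a list of (M, mean_auc).
    """
    from .evaluate import roc_auc
    from .scoring import align_genes, sagat_pipeline

    if grid is None:
        grid = list(range(step, d.U.shape[1] + 1, step))
    if not grid:
        raise ValueError("empty grid of M values")
    for M in grid:
        if not 1 <= M <= d.U.shape[1]:
            raise ValueError(f"grid value {M} invalid for decomposition")

    curve = []
    for M in grid:
        w = weight_matrix(d, M)
        aucs = []
        for subset in data_subsets:
            ds, wal, _ = align_genes(subset, w)
            table = sagat_pipeline(ds, wal)
            labels = np.array([gold[g] for g in table.gene_ids])
            aucs.append(roc_auc(table.scores, labels))
        curve.append((M, float(np.mean(aucs))))
    best_auc = max(a for _, a in curve)
    best_M = min(M for M, a in curve if a == best_auc)
    return best_M, curve


def save_weights(w: WeightMatrix, path) -> None:
    """Persist a weight matrix to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=w.W)
        f.attrs["M"] = w.M
        f.create_dataset(
            "gene_ids",
            data=np.array(w.gene_ids, dtype=h5py.string_dtype()),
        )


def load_weights(path) -> WeightMatrix:
    with h5py.File(path, "r") as f:
        W = f["W"][()]
        M = int(f.attrs["M"])
        gene_ids = [g.decode() for g in f["gene_ids"][()]]
    return WeightMatrix(W=W, M=M, gene_ids=gene_ids)
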