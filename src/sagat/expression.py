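"""Expression matrix container, parsing, normalization, and completion.

The central data structure is :class:`ExpressionMatrix`, a genes x arrays
matrix of log intensities (knowledge role) or per-replicate log expression
ratios (dataset role). Missing entries are represented as NaN. All
downstream stages (SVD decomposition, scoring, modularity analysis) consume
this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ExpressionParseError",
    "read_matrix",
    "write_matrix",
    "log_and_quantile_normalize",
    "complete_matrix",
    "standardize_rows",
]

#: Tokens interpreted as missing values in tab-delimited matrix files.
MISSING_TOKENS = {"", "NA", "NaN", "nan"}


class ExpressionParseError(ValueError):
    """Raised when a matrix file is malformed (bad header, duplicate ids,
    non-numeric cells)."""


@dataclass
class ExpressionMatrix:
    """Genes x arrays numeric matrix with row/column identifiers.

    Parameters
    ----------
    values
        Real matrix of shape (n_genes, n_arrays); missing entries are NaN.
    gene_ids
        Unique gene identifiers, one per row.
    array_ids
        Unique array identifiers, one per column.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    array_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.array_ids = [str(a) for a in self.array_ids]
        n_genes, n_arrays = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} rows"
            )
        if len(self.array_ids) != n_arrays:
            raise ValueError(
                f"{len(self.array_ids)} array ids for {n_arrays} columns"
            )
        for name, ids in (("gene", self.gene_ids), ("array", self.array_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {name} ids: {sorted(dupes)}")

    # -- convenience -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.array_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=[str(i) for i in df.index],
            array_ids=[str(c) for c in df.columns],
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.gene_ids), list(self.array_ids)
        )


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for it in items:
        if it in seen:
            dupes.add(it)
        seen.add(it)
    return dupes


def read_matrix(path, role: str = "knowledge") -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    The first row holds array identifiers, the first column gene
    identifiers. Empty cells and ``NA`` are treated as missing.

    Parameters
    ----------
    path
        File path of the tab-delimited matrix.
    role
        ``"knowledge"`` (compendium of log intensities) or ``"dataset"``
        (per-replicate log ratios). The role does not change parsing; it is
        recorded for provenance by callers.
    """
    if role not in ("knowledge", "dataset"):
        raise ValueError(f"unknown role {role!r}")
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ExpressionParseError(f"{path}: empty or missing header row")
        header_fields = header.split("\t")
        # Header may or may not carry a corner label for the gene-id column.
        array_ids = header_fields[1:] if header_fields[0] else header_fields[1:]
        if not array_ids or any(a == "" for a in array_ids):
            raise ExpressionParseError(
                f"{path}: malformed header (empty array identifier)"
            )
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(array_ids) + 1:
                raise ExpressionParseError(
                    f"{path}:{lineno}: expected {len(array_ids) + 1} fields, "
                    f"got {len(fields)}"
                )
            gene_ids.append(fields[0])
            row = []
            for col, cell in zip(array_ids, fields[1:]):
                if cell in MISSING_TOKENS:
                    row.append(np.nan)
                else:
                    try:
                        row.append(float(cell))
                    except ValueError:
                        raise ExpressionParseError(
                            f"{path}:{lineno}: non-numeric cell {cell!r} "
                            f"(gene {fields[0]!r}, array {col!r})"
                        ) from None
            rows.append(row)
    dupes = _duplicates(gene_ids)
    if dupes:
        raise ExpressionParseError(
            f"{path}: duplicate gene ids: {sorted(dupes)}"
        )
    if not rows:
        raise ExpressionParseError(f"{path}: no data rows")
    return ExpressionMatrix(np.array(rows, dtype=float), gene_ids, array_ids)


def write_matrix(x: ExpressionMatrix, path, missing_token: str = "NA") -> None:
    """Write a tab-delimited matrix in the dialect read by :func:`read_matrix`.

    Round-trips bit-exactly through ``repr`` formatting of floats.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(x.array_ids) + "\n")
        for gid, row in zip(x.gene_ids, x.values):
            cells = [
                missing_token if np.isnan(v) else repr(float(v)) for v in row
            ]
            fh.write(gid + "\t" + "\t".join(cells) + "\n")


def log_and_quantile_normalize(
    x: ExpressionMatrix, log: bool = True, base: float = 2.0
) -> ExpressionMatrix:
    """Log-transform and quantile-normalize arrays onto a common scale.

    After normalization every complete column carries the identical multiset
    of values: the cross-column means of the per-rank sorted values. Missing
    entries are excluded from rank pooling and stay missing. Tied values
    within a column receive the mean of their ranks' pooled means.

    Parameters
    ----------
    x
        Input matrix; strictly positive values required when ``log`` is on.
    log
        Apply a log transform before normalizing. Set to False for
        already-logged input.
    base
        Log base (default 2, the convention for expression ratios).
    """
    vals = x.values.copy()
    if log:
        bad = np.nonzero(~np.isnan(vals) & (vals <= 0))
        if bad[0].size:
            g = x.gene_ids[bad[0][0]]
            a = x.array_ids[bad[1][0]]
            raise ValueError(
                f"non-positive value at gene {g!r}, array {a!r}; "
                "log transform requires strictly positive input"
            )
        vals = np.log(vals) / np.log(base)

    n_genes, n_arrays = vals.shape
    # Pool per-rank means over columns, aligning columns of unequal
    # missingness by rank quantile.
    sorted_cols = []
    for j in range(n_arrays):
        col = vals[:, j]
        sorted_cols.append(np.sort(col[~np.isnan(col)]))
    counts = np.array([len(c) for c in sorted_cols])
    if (counts < 1).any():
        raise ValueError("a column has no observed values")
    n_ref = int(counts.max())
    ref_quantiles = np.linspace(0.0, 1.0, n_ref)
    pooled = np.zeros(n_ref)
    for c in sorted_cols:
        if len(c) == n_ref:
            pooled += c
        else:
            q = np.linspace(0.0, 1.0, len(c))
            pooled += np.interp(ref_quantiles, q, c)
    pooled /= n_arrays

    out = np.full_like(vals, np.nan)
    for j in range(n_arrays):
        col = vals[:, j]
        obs = ~np.isnan(col)
        n_obs = int(obs.sum())
        if n_obs == n_ref:
            target = pooled
        else:
            target = np.interp(
                np.linspace(0.0, 1.0, n_obs), ref_quantiles, pooled
            )
        # average-rank tie handling: tied entries get the mean target value
        order = np.argsort(col[obs], kind="stable")
        col_obs = col[obs]
        assigned = np.empty(n_obs)
        assigned[order] = target
        # group ties
        uniq, inv = np.unique(col_obs, return_inverse=True)
        sums = np.bincount(inv, weights=assigned)
        cnts = np.bincount(inv)
        assigned = (sums / cnts)[inv]
        filled = np.full(n_genes, np.nan)
        filled[obs] = assigned
        out[:, j] = filled
    return ExpressionMatrix(out, list(x.gene_ids), list(x.array_ids))


def complete_matrix(
    x: ExpressionMatrix,
    max_incomplete_frac: float = 0.10,
    k: int = 10,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Produce a complete (no-missing) matrix by exclusion or KNN imputation.

    If fewer than ``max_incomplete_frac`` of arrays contain any missing
    value, those arrays are dropped and retained values are untouched.
    Otherwise every missing entry is imputed as the unweighted mean, at that
    array, of the ``k`` nearest complete genes (Euclidean distance over the
    columns in which the target gene is observed).

    Parameters
    ----------
    x
        Matrix possibly containing missing entries.
    max_incomplete_frac
        Exclusion threshold on the fraction of incomplete arrays
        (default 0.10).
    k
        Neighbor count for imputation (default 10).
    seed
        Unused; accepted so callers can thread a uniform seed interface.
    """
    vals = x.values
    missing = np.isnan(vals)
    all_missing = missing.all(axis=1)
    if all_missing.any():
        genes = [g for g, m in zip(x.gene_ids, all_missing) if m]
        raise ValueError(f"genes missing in every array: {genes}")
    if not missing.any():
        return x.copy()

    incomplete_cols = missing.any(axis=0)
    frac = incomplete_cols.mean()
    if frac < max_incomplete_frac:
        keep = ~incomplete_cols
        return ExpressionMatrix(
            vals[:, keep].copy(),
            list(x.gene_ids),
            [a for a, kf in zip(x.array_ids, keep) if kf],
        )

    complete_rows = ~missing.any(axis=1)
    n_complete = int(complete_rows.sum())
    if n_complete < k:
        raise ValueError(
            f"k={k} neighbors requested but only {n_complete} complete genes"
        )
    out = vals.copy()
    donor = vals[complete_rows]  # complete genes only
    for i in np.nonzero(missing.any(axis=1))[0]:
        obs = ~missing[i]
        # distances over the target gene's observed columns
        diffs = donor[:, obs] - vals[i, obs]
        dist = np.sqrt((diffs * diffs).sum(axis=1))
        nn = np.argsort(dist, kind="stable")[:k]
        fill_cols = np.nonzero(missing[i])[0]
        out[i, fill_cols] = donor[np.ix_(nn, fill_cols)].mean(axis=0)
    return ExpressionMatrix(out, list(x.gene_ids), list(x.array_ids))


def standardize_rows(x: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene to mean 0 and scale to sample standard deviation 1.

    Raises if any gene is constant (zero variance), naming the offenders.
    """
    vals = x.values
    if np.isnan(vals).any():
        raise ValueError("standardize_rows requires a complete matrix")
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = np.nonzero(sd.ravel() == 0)[0]
    if flat.size:
        genes = [x.gene_ids[i] for i in flat]
        raise ValueError(f"constant rows cannot be standardized: {genes}")
    return ExpressionMatrix(
        (vals - mean) / sd, list(x.gene_ids), list(x.array_ids)
    )
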