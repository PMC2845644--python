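"""Rank Products meta-analysis across platforms with PFER control.

Each platform contributes a ranked gene list; a gene's rank product is the
geometric mean of its ranks (rank 1 = most extreme), computed separately
for up- and downregulation. Significance is calibrated by permuting
platform ranks independently and uniformly: the per-family error rate
PFER(g) is the expected number of null rank products at least as extreme
as gene g's observed value — a stricter criterion than the FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .scoring import ScoreTable

__all__ = ["RankProductResult", "rank_products", "pfer", "rank_products_analysis"]


@dataclass
class RankProductResult:
    gene_ids: list[str]
    rp_up: np.ndarray
    rp_down: np.ndarray
    pfer_up: np.ndarray
    pfer_down: np.ndarray
    n_platforms: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.gene_ids):
            rows.append((g, "up", self.rp_up[i], self.pfer_up[i]))
            rows.append((g, "down", self.rp_down[i], self.pfer_down[i]))
        return pd.DataFrame(rows, columns=["gene_id", "direction", "rp", "pfer"])

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        df = self.to_frame()
        sig = df[df["pfer"] <= alpha].copy()
        both = sig.groupby("gene_id").size()
        sig["inconsistent"] = sig["gene_id"].map(both.ge(2))
        return sig.sort_values("pfer").reset_index(drop=True)


def _rank_matrix(
    score_tables: list[ScoreTable], direction: str
) -> tuple[list[str], np.ndarray]:
    if len(score_tables) < 2:
        raise ValueError("rank products require at least 2 platforms")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    common = set(score_tables[0].gene_ids)
    for t in score_tables[1:]:
        common &= set(t.gene_ids)
    if not common:
        raise ValueError("platforms share no genes")
    genes = [g for g in score_tables[0].gene_ids if g in common]
    ranks = np.empty((len(genes), len(score_tables)))
    for k, t in enumerate(score_tables):
        idx = {g: i for i, g in enumerate(t.gene_ids)}
        s = np.array([t.scores[idx[g]] for g in genes], dtype=float)
        # rank 1 = most extreme in the requested direction; ties averaged
        ranks[:, k] = rankdata(-s if direction == "up" else s, method="average")
    return genes, ranks


def rank_products(
    score_tables: list[ScoreTable], direction: str = "up"
) -> tuple[list[str], np.ndarray]:
    """Geometric-mean rank per gene over the platforms' signed rankings.

    Genes are ranked per platform by signed score (descending for "up",
    ascending for "down"); the rank product of gene g over K platforms is
    (prod_k rank_gk)^(1/K). Only the gene intersection is scored.
    """
    genes, ranks = _rank_matrix(score_tables, direction)
    rp = np.exp(np.log(ranks).mean(axis=1))
    return genes, rp


def pfer(
    observed_rp: np.ndarray,
    n_genes: int,
    n_platforms: int,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Permutation estimate of the per-family error rate at each gene's RP.

    Under the null, each platform's ranking is an independent uniform
    permutation of 1..n_genes. PFER(g) is the mean, over permutations, of
    the number of null rank products <= the observed rank product of g —
    the expected count of false positives if the significance cutoff were
    set exactly at gene g.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed_rp = np.asarray(observed_rp, dtype=float)
    rng = np.random.default_rng(seed)
    order = np.argsort(observed_rp, kind="stable")
    sorted_rp = observed_rp[order]
    counts = np.zeros(observed_rp.size)
    base = np.arange(1, n_genes + 1, dtype=float)
    for _ in range(n_perm):
        log_null = np.zeros(n_genes)
        for _k in range(n_platforms):
            log_null += np.log(rng.permutation(base))
        null_rp = np.exp(log_null / n_platforms)
        null_rp.sort()
        counts += np.searchsorted(null_rp, sorted_rp, side="right")
    out = np.empty_like(counts)
    out[order] = counts / n_perm
    return out


def rank_products_analysis(
    score_tables: list[ScoreTable],
    n_perm: int = 1000,
    seed: int = 0,
) -> RankProductResult:
    """Run both directions of RP plus PFER on a set of platform scores."""
    genes_up, rp_up = rank_products(score_tables, "up")
    genes_down, rp_down = rank_products(score_tables, "down")
    assert genes_up == genes_down
    n = len(genes_up)
    k = len(score_tables)
    return RankProductResult(
        gene_ids=genes_up,
        rp_up=rp_up,
        rp_down=rp_down,
        pfer_up=pfer(rp_up, n, k, n_perm=n_perm, seed=seed),
        pfer_down=pfer(rp_down, n, k, n_perm=n_perm, seed=seed + 1),
        n_platforms=k,
    )
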