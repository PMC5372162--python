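"""Chi-square distance ordination and the ANOSIM permutation test.

Correspondence analysis (CA, the "factorial correspondence analysis" of the
French school) ordinates a non-negative colony x taxon table by the singular
value decomposition of its standardized residuals; axis inertias partition
the Pearson chi-square statistic divided by the grand total.  ANOSIM (Clarke
1993) tests compositional differences between predefined colony groups on the
ranks of a pairwise dissimilarity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

__all__ = [
    "OrdinationResult",
    "AnosimResult",
    "correspondence_analysis",
    "community_dissimilarity",
    "anosim",
]


@dataclass
class OrdinationResult:
    """Principal row/column coordinates and per-axis inertia of a CA."""

    row_coords: np.ndarray  # (n_rows, n_axes)
    col_coords: np.ndarray  # (n_cols, n_axes)
    inertia: np.ndarray  # squared singular values, non-increasing
    inertia_pct: np.ndarray  # percent of total inertia per axis
    total_inertia: float  # Pearson chi-square / grand total
    row_ids: list[str] | None = None
    col_ids: list[str] | None = None


@dataclass
class AnosimResult:
    """ANOSIM statistic R in [-1, 1] with its permutation p-value."""

    R: float
    p: float
    n_perm: int
    seed: int | None


def correspondence_analysis(
    table: np.ndarray,
    row_ids: list[str] | None = None,
    col_ids: list[str] | None = None,
    drop_empty: bool = True,
) -> OrdinationResult:
    """Classical CA of a non-negative contingency/abundance table.

    Rows (colonies) and columns (taxa) that are entirely zero are dropped
    first when ``drop_empty`` (chi-square distances are undefined for empty
    profiles).  Principal coordinates are scaled by the singular values, so
    inter-row chi-square distances are reproduced when all axes are kept.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or (x < 0).any():
        raise ValueError("table must be a 2-D non-negative array")
    if drop_empty:
        rkeep = x.sum(axis=1) > 0
        ckeep = x.sum(axis=0) > 0
        x = x[rkeep][:, ckeep]
        if row_ids is not None:
            row_ids = [i for i, k in zip(row_ids, rkeep) if k]
        if col_ids is not None:
            col_ids = [i for i, k in zip(col_ids, ckeep) if k]
    if x.shape[0] < 2 or x.shape[1] < 2 or x.sum() == 0:
        raise ValueError(
            "degenerate table: need at least 2 non-empty rows and columns"
        )

    n = x.sum()
    p = x / n
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    expected = np.outer(r, c)
    resid = (p - expected) / np.sqrt(expected)

    u, sv, vt = np.linalg.svd(resid, full_matrices=False)
    n_axes = min(x.shape) - 1
    u, sv, vt = u[:, :n_axes], sv[:n_axes], vt[:n_axes]

    inertia = sv**2
    total = float(inertia.sum())  # == Pearson chi-square / n
    pct = 100 * inertia / total if total > 0 else np.zeros_like(inertia)
    row_coords = (u * sv) / np.sqrt(r)[:, None]
    col_coords = (vt.T * sv) / np.sqrt(c)[:, None]
    return OrdinationResult(row_coords, col_coords, inertia, pct, total, row_ids, col_ids)


def community_dissimilarity(table: np.ndarray, metric: str = "bray_curtis") -> np.ndarray:
    """Pairwise dissimilarities between the rows of a community table.

    ``bray_curtis`` operates on raw counts; ``chi_square`` measures distances
    between row profiles weighted by inverse column masses (the metric
    underlying CA).
    """
    x = np.asarray(table, dtype=float)
    if (x < 0).any():
        raise ValueError("table must be non-negative")
    totals = x.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero rows have no community profile; drop them first")
    if metric == "bray_curtis":
        d = squareform(pdist(x, metric="braycurtis"))
    elif metric == "chi_square":
        profiles = x / totals[:, None]
        col_mass = x.sum(axis=0) / x.sum()
        if (col_mass == 0).any():
            raise ValueError("all-zero columns have undefined chi-square weight")
        scaled = profiles / np.sqrt(col_mass)
        d = squareform(pdist(scaled, metric="euclidean"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return d


def _anosim_r(rank_matrix: np.ndarray, groups: np.ndarray) -> float:
    same = groups[:, None] == groups[None, :]
    iu = np.triu_indices(len(groups), k=1)
    within = rank_matrix[iu][same[iu]]
    between = rank_matrix[iu][~same[iu]]
    m = len(iu[0])  # n(n-1)/2
    return float((between.mean() - within.mean()) / (m / 2.0))


def anosim(
    dissim: np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> AnosimResult:
    """Clarke's analysis of similarities on a square dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairs, midranks for ties.  The p-value uses random
    relabelings with the +1 correction, so p >= 1/(n_perm + 1) and never 0.
    """
    d = np.asarray(dissim, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    groups = np.asarray(groups)
    if len(groups) != d.shape[0]:
        raise ValueError("one group label per sample required")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("at least two groups required")
    if (counts < 2).any():
        small = labels[counts < 2]
        raise ValueError(f"every group needs >= 2 members; offending: {list(small)}")

    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = np.zeros_like(d)
    ranks[iu] = rankdata(d[iu])  # midranks
    ranks = ranks + ranks.T

    r_obs = _anosim_r(ranks, groups)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _anosim_r(ranks, rng.permutation(groups)) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return AnosimResult(R=r_obs, p=p, n_perm=n_perm, seed=seed)
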