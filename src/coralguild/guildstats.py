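"""Guild statistics compared against the null models.

For the five key exosymbiont species within one analysis stratum:

* the *richness profile* n_k — number of colonies hosting exactly k of the
  key species (non-key residents never count toward k);
* pairwise *co-occurrence counts* c_ij — colonies where key species i and j
  are both present (diagonal = species prevalences f_i);
* *solitary counts* s_i — colonies where species i is the only key species.

``run_guild_analysis`` pits every statistic against its Monte-Carlo null
distribution and flags it below / inside / above the central CI.  Richness
classes are compared under M1 and M2; co-occurrence and solitary counts under
M1, M2 and M3 (a richness-preserving null makes every n_k degenerate, so M3
is only informative for co-occurrence).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .community import ColonyRecord, IncidenceMatrix, Stratum, Taxon, to_incidence
from .nullmodels import NullModelConfig, simulate_null

__all__ = [
    "N_KEY",
    "RichnessProfile",
    "CooccurrenceTable",
    "richness_profile",
    "pairwise_cooccurrence",
    "solitary_count",
    "run_guild_analysis",
]

#: Number of key species the guild analysis is defined over.
N_KEY = 5


@dataclass
class RichnessProfile:
    """n_k = number of colonies hosting exactly k key species, k = 0..5."""

    n_k: np.ndarray  # length N_KEY + 1

    @property
    def n_colonies(self) -> int:
        return int(self.n_k.sum())


@dataclass
class CooccurrenceTable:
    """Symmetric co-occurrence counts c_ij with solitary counts s_i."""

    taxon_ids: list[str]
    c: np.ndarray  # (5, 5), c_ii = prevalence f_i
    s: np.ndarray  # (5,) solitary counts


def _binary(matrix: IncidenceMatrix | np.ndarray) -> np.ndarray:
    a = matrix.incidence if isinstance(matrix, IncidenceMatrix) else np.asarray(matrix)
    if a.ndim != 2 or a.shape[1] != N_KEY:
        raise ValueError(f"expected a matrix with exactly {N_KEY} key-species columns")
    return a


def richness_profile(matrix: IncidenceMatrix | np.ndarray) -> RichnessProfile:
    """Count colonies by their key-species richness."""
    a = _binary(matrix)
    r = a.sum(axis=1)
    return RichnessProfile(np.bincount(r, minlength=N_KEY + 1)[: N_KEY + 1])


def pairwise_cooccurrence(matrix: IncidenceMatrix | np.ndarray) -> CooccurrenceTable:
    """Co-occurrence counts as inner products of binary columns."""
    a = _binary(matrix)
    c = a.T.astype(np.int64) @ a.astype(np.int64)
    solo = a[a.sum(axis=1) == 1]
    s = solo.sum(axis=0).astype(np.int64)
    ids = matrix.taxon_ids if isinstance(matrix, IncidenceMatrix) else [str(j) for j in range(N_KEY)]
    return CooccurrenceTable(list(ids), c, s)


def solitary_count(matrix: IncidenceMatrix, taxon_id: str) -> int:
    """Colonies where ``taxon_id`` is present and is the only key species."""
    j = matrix.column_index(taxon_id)  # raises KeyError for non-key taxa
    a = _binary(matrix)
    return int(((a[:, j] == 1) & (a.sum(axis=1) == 1)).sum())


# --- statistic extractors (pure functions of a binary matrix) ---------------

def _stat_richness(k: int):
    return lambda a: int((a.sum(axis=1) == k).sum())


def _stat_pair(i: int, j: int):
    return lambda a: int((a[:, i] & a[:, j]).sum())


def _stat_solitary(j: int):
    return lambda a: int(((a[:, j] == 1) & (a.sum(axis=1) == 1)).sum())


def run_guild_analysis(
    records: Sequence[ColonyRecord],
    key_taxa: Sequence[Taxon | str],
    stratum: Stratum,
    models: Sequence[str] = ("M1", "M2", "M3"),
    config: NullModelConfig | None = None,
    include_empty_colonies: bool = True,
) -> pd.DataFrame:
    """Full stratum report: every guild statistic against every null model.

    Returns a tidy DataFrame ordered by (family, taxa, model) with columns
    stratum, family, taxon_a, taxon_b, statistic_id, observed, null_mean,
    ci_lo, ci_hi, flag, model, reps, seed, informational.  The k=0 richness
    class is reported but marked informational.  ``include_empty_colonies``
    keeps colonies hosting no key species as rows of the randomized matrix
    (the default; they can gain presences under M1/M2).
    """
    config = config or NullModelConfig()
    members = [r for r in records if stratum.matches(r)]
    if not members:
        raise ValueError(f"stratum {stratum.label()!r} contains no colonies")
    matrix = to_incidence(members, key_taxa, drop_empty=not include_empty_colonies)
    ids = matrix.taxon_ids

    richness_stats = {f"richness_k{k}": _stat_richness(k) for k in range(N_KEY + 1)}
    pair_stats = {
        f"pair_{ids[i]}_{ids[j]}": _stat_pair(i, j)
        for i in range(N_KEY)
        for j in range(i + 1, N_KEY)
    }
    solitary_stats = {f"solitary_{ids[j]}": _stat_solitary(j) for j in range(N_KEY)}

    rows = []
    for model in models:
        mc = replace(config, model=model)
        stats = dict(pair_stats, **solitary_stats)
        if model in ("M1", "M2"):
            stats = dict(richness_stats, **stats)
        for nd in simulate_null(matrix, mc, stats):
            sid = nd.statistic_id
            if sid.startswith("richness"):
                family, ta, tb = "richness", sid.removeprefix("richness_"), ""
            elif sid.startswith("pair"):
                family = "pairwise"
                _, ta, tb = sid.split("_", 2)
            else:
                family, ta, tb = "solitary", sid.removeprefix("solitary_"), ""
            rows.append(
                {
                    "stratum": stratum.label(),
                    "family": family,
                    "taxon_a": ta,
                    "taxon_b": tb,
                    "statistic_id": sid,
                    "observed": nd.observed,
                    "null_mean": nd.null_mean,
                    "ci_lo": nd.ci_lo,
                    "ci_hi": nd.ci_hi,
                    "flag": nd.flag,
                    "model": model,
                    "reps": mc.reps,
                    "seed": mc.seed,
                    "informational": sid == "richness_k0",
                }
            )
    order = {"richness": 0, "pairwise": 1, "solitary": 2}
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["family", "taxon_a", "taxon_b", "model"],
        key=lambda s: s.map(order) if s.name == "family" else s,
        kind="stable",
    ).reset_index(drop=True)
    return df
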