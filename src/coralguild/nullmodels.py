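"""Community null models and Monte-Carlo confidence-interval machinery.

Three randomization schemes generate communities expected under no species
interaction, applied to a binary colonies x species occupancy matrix:

* **M1** (unconstrained): the observed grand total F of presences is placed
  uniformly at random over the N x S cells, without replacement.  Species
  frequencies and per-colony richness are both free.  A per-cell
  Bernoulli(F / (N*S)) variant is available via ``m1_variant="bernoulli"``.
* **M2** (frequency): each species keeps its observed number of occurrences
  f_s, reassigned to f_s distinct colonies chosen uniformly; column sums are
  exact, row sums free.  Mirrors species differing in how many corals they can
  colonize.
* **M3** (richness): each colony keeps its observed number of species r_i,
  reassigned to r_i distinct species chosen uniformly; row sums are exact,
  column sums free.  Mirrors corals differing in how many species they host.

A statistic observed on the real matrix is declared non-random when it falls
outside the central confidence interval (default 95%) of its Monte-Carlo null
distribution; values equal to an interval endpoint count as inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .community import IncidenceMatrix

__all__ = [
    "NullModelConfig",
    "NullDistribution",
    "MODELS",
    "randomize_m1",
    "randomize_m2",
    "randomize_m3",
    "percentile_ci",
    "replicate_rng",
    "simulate_null",
]


@dataclass(frozen=True)
class NullModelConfig:
    """Configuration of one Monte-Carlo null-model run."""

    model: str = "M2"
    reps: int = 10_000
    ci_level: float = 0.95
    seed: int = 0
    m1_variant: str = "fixed_total"  # or "bernoulli"

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown null model {self.model!r}; choose from {sorted(MODELS)}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.m1_variant not in ("fixed_total", "bernoulli"):
            raise ValueError(f"unknown m1_variant {self.m1_variant!r}")


@dataclass
class NullDistribution:
    """Monte-Carlo samples of one statistic under a null model, with its CI."""

    statistic_id: str
    samples: np.ndarray
    ci_lo: int
    ci_hi: int
    observed: int
    flag: str = field(init=False)

    def __post_init__(self) -> None:
        if self.observed < self.ci_lo:
            self.flag = "below"
        elif self.observed > self.ci_hi:
            self.flag = "above"
        else:
            self.flag = "inside"

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.samples))


def _as_array(matrix: IncidenceMatrix | np.ndarray) -> np.ndarray:
    if isinstance(matrix, IncidenceMatrix):
        return matrix.incidence
    a = np.asarray(matrix)
    if not np.isin(a, (0, 1)).all():
        raise ValueError("matrix must be binary")
    return a.astype(np.int8)


def randomize_m1(
    matrix: IncidenceMatrix | np.ndarray,
    rng: np.random.Generator,
    variant: str = "fixed_total",
) -> np.ndarray:
    """Unconstrained model: presences placed uniformly over all cells."""
    a = _as_array(matrix)
    n, s = a.shape
    out = np.zeros(n * s, dtype=np.int8)
    if variant == "fixed_total":
        f = int(a.sum())
        if f:
            out[rng.choice(n * s, size=f, replace=False)] = 1
    elif variant == "bernoulli":
        p = a.sum() / (n * s)
        out = (rng.random(n * s) < p).astype(np.int8)
    else:
        raise ValueError(f"unknown m1 variant {variant!r}")
    return out.reshape(n, s)


def randomize_m2(
    matrix: IncidenceMatrix | np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Frequency model: every column sum f_s preserved exactly."""
    a = _as_array(matrix)
    n, s = a.shape
    out = np.zeros_like(a)
    col_sums = a.sum(axis=0)
    for j in range(s):
        f = int(col_sums[j])
        if f:
            out[rng.permutation(n)[:f], j] = 1
    return out


def randomize_m3(
    matrix: IncidenceMatrix | np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Richness model: every row sum r_i preserved exactly."""
    a = _as_array(matrix)
    n, s = a.shape
    out = np.zeros_like(a)
    row_sums = a.sum(axis=1)
    for i in range(n):
        r = int(row_sums[i])
        if r:
            out[i, rng.permutation(s)[:r]] = 1
    return out


MODELS: dict[str, Callable[..., np.ndarray]] = {
    "M1": randomize_m1,
    "M2": randomize_m2,
    "M3": randomize_m3,
}


def percentile_ci(samples: Sequence[int] | np.ndarray, level: float) -> tuple[int, int]:
    """Central empirical CI by inverse-ECDF (type-1) quantiles.

    Endpoints are always attained sample values, matching integer-valued
    count statistics.
    """
    samples = np.asarray(samples)
    if samples.size == 0:
        raise ValueError("samples must be non-empty")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [tail, 1.0 - tail], method="inverted_cdf")
    return int(lo), int(hi)


def replicate_rng(seed: int, rep: int) -> np.random.Generator:
    """Counter-based per-replicate stream: Philox keyed on (seed, rep).

    Streams depend only on the master seed and replicate index, so serial and
    parallel runs agree draw-for-draw.
    """
    return np.random.Generator(np.random.Philox(np.random.SeedSequence((seed, rep))))


def simulate_null(
    matrix: IncidenceMatrix | np.ndarray,
    config: NullModelConfig,
    statistics: Mapping[str, Callable[[np.ndarray], int]],
) -> list[NullDistribution]:
    """Monte-Carlo null distributions for a set of integer statistics.

    ``statistics`` maps statistic ids to pure functions of a binary matrix.
    All statistics are evaluated on the same replicate stream, so adding a
    statistic never changes the samples of another.
    """
    a = _as_array(matrix)
    randomizer = MODELS[config.model]
    kwargs = {"variant": config.m1_variant} if config.model == "M1" else {}

    ids = list(statistics)
    samples = np.empty((len(ids), config.reps), dtype=np.int64)
    for rep in range(config.reps):
        b = randomizer(a, replicate_rng(config.seed, rep), **kwargs)
        for k, sid in enumerate(ids):
            samples[k, rep] = statistics[sid](b)

    out = []
    for k, sid in enumerate(ids):
        lo, hi = percentile_ci(samples[k], config.ci_level)
        out.append(
            NullDistribution(
                statistic_id=sid,
                samples=samples[k],
                ci_lo=lo,
                ci_hi=hi,
                observed=int(statistics[sid](a)),
            )
        )
    return out
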