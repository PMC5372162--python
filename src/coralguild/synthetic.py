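"""Synthetic stratified colony communities with controlled interactions.

The generator draws the five key species jointly from a pairwise
exponential-family (auto-logistic / Ising-like) model over presence vectors
x in {0,1}^5:

    P(x)  proportional to  exp( sum_s alpha_s x_s  +  sum_{s<t} theta_st x_s x_t )

``alpha_s`` sets a species' marginal propensity (log scale) and ``theta_st``
the pairwise attraction (> 0) or repulsion (< 0) between species s and t on
the log-odds scale.  With only 32 states the distribution is exactly
enumerable, so every downstream statistic has a closed-form oracle:
marginal prevalences, pairwise co-occurrence expectations, and the exact
state distribution that sampling must match.

``power_experiment`` closes the loop: it generates many synthetic strata
from a null (theta = 0) or structured model and measures how often the
null-model CI test flags each species pair — the empirical type-I error and
power of the decision procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .community import ColonyRecord
from .datasets import KEY_TAXA
from .guildstats import N_KEY
from .nullmodels import MODELS, NullModelConfig, percentile_ci, replicate_rng

__all__ = [
    "InteractionModel",
    "STATES",
    "state_distribution",
    "state_moments",
    "solve_alpha",
    "generate_communities",
    "power_experiment",
]

#: All 2^5 presence states, row s of column ordering = KEY_TAXA order.
STATES = np.array(list(product((0, 1), repeat=N_KEY)), dtype=np.int8)


@dataclass
class InteractionModel:
    """Per-species propensities and pairwise interactions for 5 key species.

    Defaults give the symmetric null: every species at prevalence 1/2,
    no interactions.  ``n_colonies`` defaults to 60, the scale of one
    field stratum.
    """

    alpha: np.ndarray = field(default_factory=lambda: np.zeros(N_KEY))
    theta: np.ndarray = field(default_factory=lambda: np.zeros((N_KEY, N_KEY)))
    n_colonies: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.alpha.shape != (N_KEY,):
            raise ValueError(f"alpha must have shape ({N_KEY},)")
        if self.theta.shape != (N_KEY, N_KEY):
            raise ValueError(f"theta must have shape ({N_KEY}, {N_KEY})")
        if not np.allclose(self.theta, self.theta.T):
            raise ValueError("theta must be symmetric")
        if np.diag(self.theta).any():
            raise ValueError("theta diagonal must be zero")

    def with_pair(self, i: int, j: int, value: float) -> "InteractionModel":
        """Copy of the model with theta_ij = theta_ji = value."""
        theta = self.theta.copy()
        theta[i, j] = theta[j, i] = value
        return replace(self, theta=theta)


def state_distribution(model: InteractionModel) -> np.ndarray:
    """Exact probabilities of the 32 presence states, by enumeration."""
    # alpha_s = -inf excludes species s; gate on presence so absent species
    # contribute exactly 0 rather than 0 * inf
    energy = np.where(STATES.astype(bool), model.alpha[None, :], 0.0).sum(axis=1)
    energy = energy + 0.5 * np.einsum("ks,st,kt->k", STATES, model.theta, STATES)
    w = np.exp(energy - np.max(energy[np.isfinite(energy)]))
    return w / w.sum()


def state_moments(model: InteractionModel) -> tuple[np.ndarray, np.ndarray]:
    """Exact marginal prevalences E[x_s] and co-occurrence E[x_s x_t]."""
    p = state_distribution(model)
    marg = p @ STATES
    pair = (STATES.T * p) @ STATES
    return marg, pair


def solve_alpha(
    targets: Sequence[float],
    theta: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Solve alpha so marginal prevalences hit ``targets`` (fixed point).

    With theta = 0 this is the logit in one step; with interactions the
    fixed-point iteration alpha += logit(target) - logit(current) converges
    for moderate theta.
    """
    targets = np.asarray(targets, dtype=float)
    if ((targets <= 0) | (targets >= 1)).any():
        raise ValueError("target prevalences must lie strictly in (0, 1)")
    theta = np.zeros((N_KEY, N_KEY)) if theta is None else np.asarray(theta, float)
    logit = lambda p: np.log(p / (1 - p))
    alpha = logit(targets)
    for _ in range(max_iter):
        marg, _ = state_moments(InteractionModel(alpha=alpha, theta=theta))
        if np.max(np.abs(marg - targets)) < tol:
            return alpha
        alpha = alpha + logit(targets) - logit(marg)
    raise RuntimeError("alpha fixed point did not converge; reduce |theta|")


def generate_communities(
    model: InteractionModel,
    region: str = "RI",
    site: str = "LI",
    stage: str = "adult",
    host_type: str = "beta",
    nonkey_taxa: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
    id_prefix: str = "SYN",
) -> list[ColonyRecord]:
    """Draw ``model.n_colonies`` i.i.d. colonies from the state distribution.

    Key species follow the joint interaction model; optional non-key taxa are
    added independently with the given per-taxon probabilities (they only
    matter for ordination realism).  Reproducible via ``model.seed``.
    """
    rng = rng or np.random.default_rng(model.seed)
    probs = state_distribution(model)
    idx = rng.choice(len(STATES), size=model.n_colonies, p=probs)
    records = []
    for i, k in enumerate(idx):
        assemblage = {KEY_TAXA[s]: 1 for s in range(N_KEY) if STATES[k, s]}
        for tid, p in (nonkey_taxa or {}).items():
            if rng.random() < p:
                assemblage[tid] = 1
        records.append(
            ColonyRecord(
                colony_id=f"{id_prefix}-{i:04d}",
                region=region,
                site=site,
                stage=stage,
                host_type=host_type,
                assemblage=assemblage,
            )
        )
    return records


def _pair_counts(a: np.ndarray) -> np.ndarray:
    c = a.T.astype(np.int64) @ a.astype(np.int64)
    iu = np.triu_indices(N_KEY, k=1)
    return c[iu]


def power_experiment(
    model: InteractionModel,
    config: NullModelConfig,
    n_datasets: int = 400,
    seed: int = 0,
) -> pd.DataFrame:
    """Flag rates of the pairwise CI test over many synthetic datasets.

    For each dataset: draw a stratum from ``model``, build the null CI of all
    10 pairwise co-occurrence counts under ``config`` and record each flag.
    Under a theta = 0 model the two-sided flag rate per pair estimates the
    test's type-I error; under an interacting model the directional flag rate
    estimates power.  Returns one row per species pair with columns
    rate_below / rate_above / rate_outside.
    """
    randomizer = MODELS[config.model]
    kwargs = {"variant": config.m1_variant} if config.model == "M1" else {}
    iu = np.triu_indices(N_KEY, k=1)
    pair_ids = [f"{KEY_TAXA[i]}_{KEY_TAXA[j]}" for i, j in zip(*iu)]
    probs = state_distribution(model)

    below = np.zeros(len(pair_ids))
    above = np.zeros(len(pair_ids))
    for ds in range(n_datasets):
        rng = np.random.default_rng(np.random.SeedSequence((seed, ds)))
        a = STATES[rng.choice(len(STATES), size=model.n_colonies, p=probs)]
        observed = _pair_counts(a)
        samples = np.empty((config.reps, len(pair_ids)), dtype=np.int64)
        for rep in range(config.reps):
            b = randomizer(a, replicate_rng(seed + 1_000_003 * (ds + 1), rep), **kwargs)
            samples[rep] = _pair_counts(b)
        for k in range(len(pair_ids)):
            lo, hi = percentile_ci(samples[:, k], config.ci_level)
            below[k] += observed[k] < lo
            above[k] += observed[k] > hi
    return pd.DataFrame(
        {
            "pair": pair_ids,
            "rate_below": below / n_datasets,
            "rate_above": above / n_datasets,
            "rate_outside": (below + above) / n_datasets,
        }
    )
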