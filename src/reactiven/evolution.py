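"""Rare-mutation pairwise-comparison dynamics over a strategy family.

A population of size N is monomorphic at a resident strategy. Each elementary
step introduces a single mutant drawn uniformly from the family (every entry
i.i.d. uniform on [0, 1]); the mutant either fixes, replacing the resident,
or goes extinct before the next mutation arrives. Under the pairwise
comparison rule with selection strength beta, the fixation probability of a
mutant with mixed-population payoffs pi_M,k (k mutants) against resident
payoffs pi_R,k is

    phi_M = 1 / (1 + sum_{i=1}^{N-1} prod_{j=1}^{i} exp(-beta (pi_M,j - pi_R,j)))

computed in log-space. Mixed-population payoffs use complete mixing excluding
self-interaction:

    pi_M,k = ((k-1) pi(M,M) + (N-k) pi(M,R)) / (N-1)
    pi_R,k = (k pi(R,M) + (N-1-k) pi(R,R)) / (N-1)

Pairwise payoffs come from the exact paired-history chain. Strategies with
entries exactly 0 or 1 (e.g. the initial all-defector resident) make the
chain reducible; payoffs involving them are computed with a small
implementation-error regularization (eps = 1e-6) to restore ergodicity.

Residents are classified as partners with a relaxed niceness requirement:
they must satisfy the non-niceness partner inequalities of their family, and
cooperate after full cooperation with probability at least 0.95 by default.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .payoff_engine import (
    GameParameters,
    _kernel_from_memory,
    _solve_stationary,
    _state_tables,
)
from .strategy_spaces import (
    CountingStrategy,
    ReactiveStrategy,
    Strategy,
    counting_to_reactive,
    sample_uniform,
)
from . import equilibrium

__all__ = [
    "EvolutionConfig",
    "EvolutionTrace",
    "mixed_population_payoffs",
    "fixation_probability",
    "classify_partner_resident",
    "run_simulation",
]

_REGULARIZATION_EPS = 1e-6


@dataclasses.dataclass(frozen=True)
class EvolutionConfig:
    family: str
    n: int
    game: GameParameters
    N: int = 100
    beta: float = 1.0
    steps: int = 100_000
    seed: Optional[int] = None
    initial_resident: Optional[Strategy] = None
    partner_threshold: float = 0.95

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if not 0.0 < self.partner_threshold <= 1.0:
            raise ValueError("partner_threshold must lie in (0, 1]")
        if self.beta < 0.0:
            raise ValueError("selection strength beta must be >= 0")
        if self.family not in ("reactive", "counting"):
            raise ValueError("evolution supports the reactive and counting families")


@dataclasses.dataclass
class ResidentEpoch:
    """Aggregate statistics for one resident's tenure."""

    probs: np.ndarray
    sojourn: int  # elementary steps spent as resident
    resisted: int  # mutants that failed to invade


@dataclasses.dataclass
class EvolutionTrace:
    """Per-step records of the resident lineage plus summary statistics."""

    config: EvolutionConfig
    resident_probs: np.ndarray  # (steps, dim), resident after each step
    resident_payoff: np.ndarray
    resident_coop_rate: np.ndarray
    partner_flag: np.ndarray
    accepted_flag: np.ndarray
    epochs: List[ResidentEpoch]

    @property
    def partner_abundance(self) -> float:
        return float(self.partner_flag.mean())

    @property
    def average_cooperation_rate(self) -> float:
        return float(self.resident_coop_rate.mean())

    def summary(self) -> dict:
        return {
            "steps": len(self.partner_flag),
            "partner_abundance": self.partner_abundance,
            "average_cooperation_rate": self.average_cooperation_rate,
            "acceptance_rate": float(self.accepted_flag.mean()),
            "num_residents": len(self.epochs),
        }

    def to_dataframe(self) -> pd.DataFrame:
        dim = self.resident_probs.shape[1]
        df = pd.DataFrame(
            self.resident_probs, columns=[f"p{i}" for i in range(dim)]
        )
        df.insert(0, "step", np.arange(len(df)))
        df["payoff"] = self.resident_payoff
        df["coop_rate"] = self.resident_coop_rate
        df["partner"] = self.partner_flag.astype(int)
        df["accepted"] = self.accepted_flag.astype(int)
        return df


def _reactive_vector(strategy: Strategy) -> np.ndarray:
    if isinstance(strategy, CountingStrategy):
        return counting_to_reactive(strategy).probs
    if isinstance(strategy, ReactiveStrategy):
        return strategy.probs
    raise TypeError("expected a reactive or counting strategy")


def _pair_payoffs(p1: np.ndarray, p2: np.ndarray, n: int, game: GameParameters):
    """(pi1, pi2, coop1, coop2) for reactive vectors p1 vs p2, regularizing
    boundary entries with a small error rate to keep the chain ergodic."""
    if np.any((p1 <= 0.0) | (p1 >= 1.0)) or np.any((p2 <= 0.0) | (p2 >= 1.0)):
        e = _REGULARIZATION_EPS
        p1 = p1 * (1.0 - 2.0 * e) + e
        p2 = p2 * (1.0 - 2.0 * e) + e
    h1, h2, _, _ = _state_tables(n)
    m1 = p1[h2]  # player 1 reacts to the coplayer's history
    m2 = p2[h2]  # player 2's own-major vector: reacts to opp (=h2 under swap)
    K = _kernel_from_memory(m1, m2, n)
    dist = _solve_stationary(K)
    a1 = (h1 & 1).astype(np.intp)
    a2 = (h2 & 1).astype(np.intp)
    pm = game.payoff_matrix
    return (
        float(dist @ pm[a1, a2]),
        float(dist @ pm[a2, a1]),
        float(dist @ (1 - a1)),
        float(dist @ (1 - a2)),
    )


def mixed_population_payoffs(
    mutant: Strategy,
    resident: Strategy,
    k: int,
    N: int,
    game: GameParameters,
) -> Tuple[float, float]:
    """Expected payoffs (pi_M,k, pi_R,k) with k mutants among N players,
    complete mixing, self-interaction excluded."""
    if not 1 <= k <= N - 1:
        raise ValueError(f"mutant count k={k} must satisfy 1 <= k <= N-1")
    n = max(mutant.n, resident.n)
    pM = _lift(_reactive_vector(mutant), mutant.n, n)
    pR = _lift(_reactive_vector(resident), resident.n, n)
    piMM, _, _, _ = _pair_payoffs(pM, pM, n, game)
    piMR, piRM, _, _ = _pair_payoffs(pM, pR, n, game)
    piRR, _, _, _ = _pair_payoffs(pR, pR, n, game)
    pi_m = ((k - 1) * piMM + (N - k) * piMR) / (N - 1)
    pi_r = (k * piRM + (N - 1 - k) * piRR) / (N - 1)
    return pi_m, pi_r


def _lift(p: np.ndarray, n_from: int, n_to: int) -> np.ndarray:
    if n_from == n_to:
        return p
    idx = np.arange(2**n_to) & (2**n_from - 1)
    return p[idx]


def fixation_probability(pi_m, pi_r, beta: float) -> float:
    """Fixation probability of a single mutant under pairwise comparison.

    ``pi_m`` and ``pi_r`` are the mixed-population payoff sequences over
    k = 1 .. N-1. Computed in log-space; beta = 0 or identical payoffs give
    the neutral value 1/N.
    """
    pi_m = np.asarray(pi_m, dtype=float)
    pi_r = np.asarray(pi_r, dtype=float)
    if pi_m.shape != pi_r.shape or pi_m.ndim != 1 or len(pi_m) < 1:
        raise ValueError("payoff sequences must be equal-length 1-d arrays")
    if beta < 0.0:
        raise ValueError("beta must be >= 0")
    log_terms = np.concatenate(([0.0], np.cumsum(-beta * (pi_m - pi_r))))
    m = log_terms.max()
    return float(np.exp(-(m + np.log(np.exp(log_terms - m).sum()))))


def classify_partner_resident(
    resident: Strategy,
    game: GameParameters,
    threshold: float = 0.95,
) -> bool:
    """Partner classification with the niceness equality relaxed to a
    threshold on the post-full-cooperation entry (default 0.95).

    Uses the closed-form inequalities for donation-game reactive n <= 3 and
    counting-n; otherwise falls back to the cycle oracle applied to the
    strategy with its all-C entry set to 1.
    """
    probs = resident.probs
    if probs[0] < threshold:
        return False
    if isinstance(resident, CountingStrategy) and game.is_donation:
        ok, slacks = equilibrium.is_partner_counting(
            CountingStrategy(resident.n, _with_first(probs, 1.0)), game
        )
        return ok
    if isinstance(resident, ReactiveStrategy) and game.is_donation and resident.n <= 3:
        nice = ReactiveStrategy(resident.n, _with_first(probs, 1.0))
        if resident.n == 1:
            return bool(probs[1] <= 1.0 - game.c / game.b + equilibrium.NASH_TOL)
        checker = (
            equilibrium.is_partner_reactive2
            if resident.n == 2
            else equilibrium.is_partner_reactive3
        )
        ok, _ = checker(nice, game)
        return ok
    nice = resident.with_probs(_with_first(probs, 1.0))
    return equilibrium.is_partner_oracle(nice, game).is_partner


def _with_first(probs: np.ndarray, value: float) -> np.ndarray:
    out = np.array(probs, dtype=float)
    out[0] = value
    return out


def run_simulation(config: EvolutionConfig) -> EvolutionTrace:
    """Iterate the rare-mutation process and record the resident lineage.

    Each step: draw a mutant uniformly from the family, compute its fixation
    probability from the exact mixed-population payoffs, and replace the
    resident with that probability. Reproducible under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    game, N, beta, n = config.game, config.N, config.beta, config.n
    k = np.arange(1, N)

    if config.initial_resident is not None:
        resident = config.initial_resident
    elif config.family == "counting":
        resident = CountingStrategy(n, np.zeros(n + 1))
    else:
        resident = ReactiveStrategy(n, np.zeros(2**n))

    res_vec = _reactive_vector(resident)
    piRR, _, coopRR, _ = _pair_payoffs(res_vec, res_vec, n, game)
    res_partner = classify_partner_resident(resident, game, config.partner_threshold)

    dim = len(resident.probs)
    rec_probs = np.empty((config.steps, dim))
    rec_payoff = np.empty(config.steps)
    rec_coop = np.empty(config.steps)
    rec_partner = np.empty(config.steps, dtype=bool)
    rec_accept = np.empty(config.steps, dtype=bool)
    epochs: List[ResidentEpoch] = [ResidentEpoch(np.array(resident.probs), 0, 0)]

    for step in range(config.steps):
        mutant = sample_uniform(config.family, n, rng)
        mut_vec = _reactive_vector(mutant)
        piMM, _, _, _ = _pair_payoffs(mut_vec, mut_vec, n, game)
        piMR, piRM, _, _ = _pair_payoffs(mut_vec, res_vec, n, game)
        pi_m = ((k - 1) * piMM + (N - k) * piMR) / (N - 1)
        pi_r = (k * piRM + (N - 1 - k) * piRR) / (N - 1)
        phi = fixation_probability(pi_m, pi_r, beta)
        accepted = bool(rng.random() < phi)
        if accepted:
            resident = mutant
            res_vec = mut_vec
            piRR, _, coopRR, _ = _pair_payoffs(res_vec, res_vec, n, game)
            res_partner = classify_partner_resident(
                resident, game, config.partner_threshold
            )
            epochs.append(ResidentEpoch(np.array(resident.probs), 0, 0))
        else:
            epochs[-1].resisted += 1
        epochs[-1].sojourn += 1
        rec_probs[step] = resident.probs
        rec_payoff[step] = piRR
        rec_coop[step] = coopRR
        rec_partner[step] = res_partner
        rec_accept[step] = accepted

    return EvolutionTrace(
        config=config,
        resident_probs=rec_probs,
        resident_payoff=rec_payoff,
        resident_coop_rate=rec_coop,
        partner_flag=rec_partner,
        accepted_flag=rec_accept,
        epochs=epochs,
    )
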