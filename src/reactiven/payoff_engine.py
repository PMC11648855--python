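"""Exact long-run payoffs for finite-memory strategy pairs.

The repeated game between two memory-n players is a Markov chain whose states
are the 4**n possible combinations of the two players' n-histories, aligned by
round. Given both strategies, the transition kernel is the product of the two
players' conditional action probabilities, and long-run per-round payoffs are
expectations under the stationary (or Cesaro-average) distribution.

State encoding: state ``s = h1 * 2**n + h2`` where ``h1`` and ``h2`` are the
history indices (oldest action = most significant bit, C = 0) of player 1 and
player 2. The most recent actions are therefore the least significant bits of
``h1`` and ``h2``.

Three payoff routes are provided:

- :func:`stationary_payoffs` for ergodic chains (all effective cooperation
  probabilities strictly inside (0, 1)), solving the singular linear system;
- :func:`cesaro_payoffs` for possibly reducible chains, averaging over the
  recurrent classes reachable from an explicit initial joint history;
- :func:`cycle_payoff` for the long-run payoff of a deterministic periodic
  action sequence played against a reactive strategy (no chain needed).

Implementation errors: with probability ``epsilon`` a player executes the
opposite of the intended action, which is equivalent to replacing every entry
``q`` of its strategy by ``(1 - eps) q + eps (1 - q)``
(:func:`effective_strategy`). Errors are applied to both players, and reactive
strategies condition on executed, post-error actions.
"""

from __future__ import annotations

import dataclasses
import functools
import warnings
from typing import Optional, Sequence, Union

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .strategy_spaces import (
    CountingStrategy,
    ReactiveStrategy,
    Strategy,
    history_index,
)

__all__ = [
    "GameParameters",
    "PairedHistoryChain",
    "PayoffResult",
    "effective_strategy",
    "build_chain",
    "stationary_payoffs",
    "cesaro_payoffs",
    "cycle_payoff",
    "monte_carlo_payoffs",
]

_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class GameParameters:
    """Stage-game payoffs (R, S, T, P) plus an implementation-error rate.

    A prisoner's dilemma satisfies T > R > P > S and 2R > T + S. The donation
    game (cooperate = pay cost c to give the coplayer benefit b) is the special
    case R = b - c, S = -c, T = b, P = 0.
    """

    R: float
    S: float
    T: float
    P: float
    epsilon: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must lie in [0, 0.5)")

    @classmethod
    def donation(cls, b: float, c: float, epsilon: float = 0.0, strict: bool = True):
        """Donation game with benefit ``b`` and cost ``c``.

        With ``strict=True`` (default) requires b > c > 0, the prisoner's
        dilemma regime. ``strict=False`` permits degenerate parameters (e.g.
        c >= b) for exploratory use such as volume computations.
        """
        if strict and not (b > c > 0):
            raise ValueError(f"donation game requires b > c > 0, got b={b}, c={c}")
        return cls(R=b - c, S=-c, T=b, P=0.0, epsilon=epsilon)

    @property
    def is_prisoners_dilemma(self) -> bool:
        return (
            self.T > self.R > self.P > self.S and 2 * self.R > self.T + self.S
        )

    @property
    def is_donation(self) -> bool:
        return (
            abs(self.P) < _TOL
            and abs(self.R - (self.T + self.S)) < _TOL
            and self.T > 0
            and self.S < 0
        )

    @property
    def b(self) -> float:
        self._require_donation()
        return self.T

    @property
    def c(self) -> float:
        self._require_donation()
        return -self.S

    def _require_donation(self):
        if not self.is_donation:
            raise ValueError("operation requires donation-game parameterization")

    @property
    def payoff_matrix(self) -> np.ndarray:
        """2x2 payoff matrix for player 1, indexed [own action][coplayer action]
        with C = 0, D = 1."""
        return np.array([[self.R, self.S], [self.T, self.P]])


@dataclasses.dataclass(frozen=True)
class PairedHistoryChain:
    """Markov chain over the 4**n joint n-history states."""

    n: int
    kernel: np.ndarray  # (4**n, 4**n), rows sum to 1

    @property
    def num_states(self) -> int:
        return 4**self.n

    def state_label(self, s: int) -> tuple:
        from .strategy_spaces import index_to_history

        h1, h2 = s >> self.n, s & (2**self.n - 1)
        return (
            "".join(index_to_history(h1, self.n)),
            "".join(index_to_history(h2, self.n)),
        )


@dataclasses.dataclass(frozen=True)
class PayoffResult:
    """Long-run per-round payoffs and cooperation rates for both players."""

    pi1: float
    pi2: float
    cooperation_rate_1: float
    cooperation_rate_2: float
    stationary: Optional[np.ndarray] = None
    n: int = 0

    def as_record(self) -> dict:
        return {
            "pi1": self.pi1,
            "pi2": self.pi2,
            "coop1": self.cooperation_rate_1,
            "coop2": self.cooperation_rate_2,
        }


@functools.lru_cache(maxsize=None)
def _state_tables(n: int):
    """Cached index arrays for the joint-history state space at memory n.

    Returns (h1, h2, swap, nxt) where ``swap[s]`` re-indexes the state from
    player 2's perspective and ``nxt[s, a1, a2]`` is the successor state after
    joint action (a1, a2) with C = 0, D = 1.
    """
    S = 4**n
    mask = 2**n - 1
    states = np.arange(S)
    h1 = states >> n
    h2 = states & mask
    swap = (h2 << n) | h1
    nxt = np.empty((S, 2, 2), dtype=np.intp)
    for a1 in (0, 1):
        nh1 = ((h1 << 1) | a1) & mask
        for a2 in (0, 1):
            nh2 = ((h2 << 1) | a2) & mask
            nxt[:, a1, a2] = (nh1 << n) | nh2
    return h1, h2, swap, nxt


def effective_strategy(s: Strategy, epsilon: float) -> Strategy:
    """Strategy actually executed under implementation errors of rate epsilon."""
    if not 0.0 <= epsilon < 0.5:
        raise ValueError("epsilon must lie in [0, 0.5)")
    if epsilon == 0.0:
        return s
    return s.with_probs(s.probs * (1.0 - 2.0 * epsilon) + epsilon)


def _memory_vectors(s1: Strategy, s2: Strategy, epsilon: float = 0.0):
    n = max(s1.n, s2.n)
    m1 = effective_strategy(s1, epsilon).as_memory(n)
    m2 = effective_strategy(s2, epsilon).as_memory(n)
    return n, m1, m2


def _kernel_from_memory(m1: np.ndarray, m2: np.ndarray, n: int) -> np.ndarray:
    """Transition kernel over joint states from the two memory vectors.

    ``m1`` is player 1's cooperation probability per state (own-major), and
    likewise ``m2`` from player 2's own perspective, so player 2's probability
    in state ``s`` is ``m2[swap[s]]``.
    """
    _, _, swap, nxt = _state_tables(n)
    S = 4**n
    q1 = m1
    q2 = m2[swap]
    K = np.zeros((S, S))
    rows = np.arange(S)
    K[rows, nxt[:, 0, 0]] = q1 * q2
    K[rows, nxt[:, 0, 1]] = q1 * (1.0 - q2)
    K[rows, nxt[:, 1, 0]] = (1.0 - q1) * q2
    K[rows, nxt[:, 1, 1]] = (1.0 - q1) * (1.0 - q2)
    return K


def build_chain(s1: Strategy, s2: Strategy, game: GameParameters) -> PairedHistoryChain:
    """Paired-history chain for two strategies (error rate NOT applied here;
    pass strategies through :func:`effective_strategy` first if needed)."""
    n, m1, m2 = _memory_vectors(s1, s2, 0.0)
    return PairedHistoryChain(n=n, kernel=_kernel_from_memory(m1, m2, n))


def _solve_stationary(K: np.ndarray) -> np.ndarray:
    # (K' - I) pi = 0 with sum(pi) = 1; adding the rank-one matrix 11' makes
    # the system nonsingular for chains with a unique stationary distribution.
    S = K.shape[0]
    A = K.T - np.eye(S) + 1.0
    pi = np.linalg.solve(A, np.ones(S))
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _result_from_distribution(
    dist: np.ndarray, n: int, game: GameParameters, keep_stationary: bool = True
) -> PayoffResult:
    h1, h2, _, _ = _state_tables(n)
    a1 = (h1 & 1).astype(np.intp)
    a2 = (h2 & 1).astype(np.intp)
    pm = game.payoff_matrix
    pi1 = float(dist @ pm[a1, a2])
    pi2 = float(dist @ pm[a2, a1])
    coop1 = float(dist @ (1 - a1))
    coop2 = float(dist @ (1 - a2))
    return PayoffResult(
        pi1=pi1,
        pi2=pi2,
        cooperation_rate_1=coop1,
        cooperation_rate_2=coop2,
        stationary=dist if keep_stationary else None,
        n=n,
    )


def _parse_initial_state(initial_state, n: int) -> int:
    if initial_state is None:
        return 0  # mutual cooperation throughout the last n rounds
    if isinstance(initial_state, (int, np.integer)):
        s = int(initial_state)
        if not 0 <= s < 4**n:
            raise ValueError(f"initial state {s} out of range for n={n}")
        return s
    h1, h2 = initial_state
    i1, i2 = history_index(h1), history_index(h2)
    if max(i1, i2) >= 2**n:
        raise ValueError("initial histories longer than the chain memory")
    return (i1 << n) | i2


def _recurrent_classes(K: np.ndarray):
    support = csr_matrix(K > 0.0)
    ncomp, labels = connected_components(support, directed=True, connection="strong")
    rows, cols = np.nonzero(K)
    leaky = set(labels[rows[labels[rows] != labels[cols]]])
    recurrent = [c for c in range(ncomp) if c not in leaky]
    return labels, recurrent


def _cesaro_distribution(K: np.ndarray, s0: int) -> np.ndarray:
    """Long-run occupation distribution from initial state ``s0``.

    Equals the absorption-probability-weighted mixture of the stationary
    distributions of the recurrent classes reachable from ``s0``.
    """
    S = K.shape[0]
    labels, recurrent = _recurrent_classes(K)
    class_stationary = {}
    for c in recurrent:
        idx = np.nonzero(labels == c)[0]
        sub = K[np.ix_(idx, idx)]
        class_stationary[c] = (idx, _solve_stationary(sub))
    if labels[s0] in class_stationary:
        idx, pi = class_stationary[labels[s0]]
        dist = np.zeros(S)
        dist[idx] = pi
        return dist
    transient = np.nonzero(~np.isin(labels, recurrent))[0]
    pos = {s: i for i, s in enumerate(transient)}
    A = np.eye(len(transient)) - K[np.ix_(transient, transient)]
    B = np.column_stack(
        [K[np.ix_(transient, np.nonzero(labels == c)[0])].sum(axis=1) for c in recurrent]
    )
    absorb = np.linalg.solve(A, B)[pos[s0]]
    dist = np.zeros(S)
    for weight, c in zip(absorb, recurrent):
        idx, pi = class_stationary[c]
        dist[idx] += weight * pi
    return dist / dist.sum()


def stationary_payoffs(
    s1: Strategy,
    s2: Strategy,
    game: GameParameters,
    initial_state=None,
) -> PayoffResult:
    """Exact long-run per-round payoffs from the paired-history chain.

    When every effective cooperation probability lies strictly in (0, 1) the
    chain is ergodic and the unique stationary distribution is used. Otherwise
    the chain may be reducible; the result is then the Cesaro average from
    ``initial_state`` (defaulting, with a warning, to the mutual-cooperation
    history).
    """
    n, m1, m2 = _memory_vectors(s1, s2, game.epsilon)
    K = _kernel_from_memory(m1, m2, n)
    interior = np.all((m1 > 0.0) & (m1 < 1.0)) and np.all((m2 > 0.0) & (m2 < 1.0))
    if interior:
        dist = _solve_stationary(K)
    else:
        if initial_state is None:
            warnings.warn(
                "chain may be reducible (deterministic strategy entries); "
                "falling back to the Cesaro average from the all-cooperation "
                "initial history",
                stacklevel=2,
            )
        dist = _cesaro_distribution(K, _parse_initial_state(initial_state, n))
    return _result_from_distribution(dist, n, game)


def cesaro_payoffs(
    s1: Strategy,
    s2: Strategy,
    game: GameParameters,
    initial_state,
) -> PayoffResult:
    """Long-run Cesaro-average payoffs from an explicit initial joint history.

    ``initial_state`` may be a state index or a pair of n-histories such as
    ``("DC", "CC")`` (oldest action first).
    """
    n, m1, m2 = _memory_vectors(s1, s2, game.epsilon)
    K = _kernel_from_memory(m1, m2, n)
    dist = _cesaro_distribution(K, _parse_initial_state(initial_state, n))
    return _result_from_distribution(dist, n, game)


def cycle_payoff(
    action_cycle: Union[str, Sequence[str]],
    p: Union[ReactiveStrategy, CountingStrategy],
    game: GameParameters,
) -> float:
    """Per-round payoff of a player repeating ``action_cycle`` forever against
    a reactive strategy ``p``.

    The cycle is read as infinitely repeated, so the n actions preceding each
    position wrap around cyclically. At a position with action a and own
    preceding n-history h, the opponent cooperates with probability p_h, and
    the cycling player earns R or T (a = C or D) when it does, S or P when it
    does not.
    """
    if isinstance(p, CountingStrategy):
        p = p.to_reactive()
    seq = tuple(action_cycle)
    if not seq:
        raise ValueError("action cycle must be nonempty")
    bits = [{"C": 0, "D": 1}[a] for a in seq]
    L, n = len(bits), p.n
    pm = game.payoff_matrix
    total = 0.0
    for t in range(L):
        h = 0
        for j in range(n):
            h = (h << 1) | bits[(t - n + j) % L]
        q = p.probs[h]
        a = bits[t]
        total += q * pm[a, 0] + (1.0 - q) * pm[a, 1]
    return total / L


def monte_carlo_payoffs(
    s1: Strategy,
    s2: Strategy,
    game: GameParameters,
    rounds: int = 1_000_000,
    replicates: int = 50,
    seed: Optional[int] = None,
    initial_state=None,
    burn_in: int = 1_000,
):
    """Simulation cross-check of the exact chain payoffs.

    Runs ``replicates`` independent games of ``rounds // replicates`` rounds
    each (after ``burn_in`` discarded rounds) and returns a dict with payoff /
    cooperation-rate means and their across-replicate standard errors.
    """
    n, m1, m2 = _memory_vectors(s1, s2, game.epsilon)
    _, _, swap, nxt = _state_tables(n)
    nxt_flat = nxt.reshape(4**n, 4)
    pm = game.payoff_matrix
    rng = np.random.default_rng(seed)
    T = rounds // replicates
    s = np.full(replicates, _parse_initial_state(initial_state, n), dtype=np.intp)
    pay1 = np.zeros(replicates)
    pay2 = np.zeros(replicates)
    co1 = np.zeros(replicates)
    co2 = np.zeros(replicates)
    for t in range(burn_in + T):
        q1 = m1[s]
        q2 = m2[swap[s]]
        a1 = (rng.random(replicates) >= q1).astype(np.intp)
        a2 = (rng.random(replicates) >= q2).astype(np.intp)
        if t >= burn_in:
            pay1 += pm[a1, a2]
            pay2 += pm[a2, a1]
            co1 += 1 - a1
            co2 += 1 - a2
        s = nxt_flat[s, 2 * a1 + a2]
    for arr in (pay1, pay2, co1, co2):
        arr /= T
    sqrtB = np.sqrt(replicates)
    return {
        "pi1": pay1.mean(),
        "pi2": pay2.mean(),
        "coop1": co1.mean(),
        "coop2": co2.mean(),
        "se_pi1": pay1.std(ddof=1) / sqrtB,
        "se_pi2": pay2.std(ddof=1) / sqrtB,
        "rounds": T * replicates,
    }
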