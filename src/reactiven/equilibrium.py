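"""Partner and defector verification for reactive-n strategies.

The key reduction: against a reactive-n strategy, a best response always
exists among the *deterministic self-reactive-n* strategies. The long-run
behavior of such a deviator is a periodic action sequence, i.e. a simple cycle
of the order-n de Bruijn graph on {C, D} (nodes are own n-histories, edges
append C or D). A nice reactive strategy ``p`` is therefore a partner (full
cooperation is a Nash equilibrium) if and only if no deviation cycle earns
more than the mutual-cooperation payoff R per round against ``p`` — a finite
check. The same machinery characterizes defector strategies (stable mutual
defection), extracts the minimal irredundant set of deviation constraints,
and estimates partner volumes by Monte Carlo.

Closed-form partner conditions for the donation game (benefit b, cost c):

- reactive-2:  p_CC = 1,  (p_CD + p_DC)/2 <= 1 - c/(2b),  p_DD <= 1 - c/b;
- reactive-3:  p_CCC = 1 plus five averaged inequalities (see
  :func:`is_partner_reactive3`);
- counting-n:  r_n = 1 and r_{n-k} <= 1 - (k/n)(c/b) for k = 1..n — the
  cooperation probability drops by c/(nb) per remembered defection.
"""

from __future__ import annotations

import dataclasses
import functools
from fractions import Fraction
from math import gcd
from typing import Dict, List, Tuple, Union

import networkx as nx
import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .payoff_engine import GameParameters, _solve_stationary, _state_tables, cycle_payoff
from .strategy_spaces import (
    CountingStrategy,
    ReactiveStrategy,
    counting_to_reactive,
)

__all__ = [
    "DeviationCycleSet",
    "PartnerReport",
    "enumerate_deviation_cycles",
    "deviation_payoffs",
    "is_partner_oracle",
    "is_defector_oracle",
    "is_partner_reactive2",
    "is_partner_reactive3",
    "is_partner_counting",
    "minimal_constraints",
    "partner_volume",
    "counting_partner_volume_exact",
    "reactive2_partner_volume_exact",
    "best_self_reactive_deviation",
    "best_pure_memory_deviation",
]

NASH_TOL = 1e-9
_MAX_N = 6


@dataclasses.dataclass(frozen=True)
class DeviationCycleSet:
    """All simple cycles of the order-n de Bruijn graph, as canonical action
    strings (lexicographically minimal rotation)."""

    n: int
    cycles: Tuple[str, ...]

    def __len__(self) -> int:
        return len(self.cycles)

    def __iter__(self):
        return iter(self.cycles)

    def __contains__(self, cycle: str) -> bool:
        return _canonical_rotation(cycle) in self.cycles


@dataclasses.dataclass(frozen=True)
class PartnerReport:
    """Verdict of the cycle-oracle Nash check for a candidate strategy."""

    strategy: ReactiveStrategy
    verdict: str  # "partner" | "not_nice" | "exploitable"
    worst_deviation: str
    worst_payoff: float
    margin: float  # mutual-cooperation payoff minus best deviation payoff
    binding_constraints: Tuple[str, ...]

    @property
    def is_partner(self) -> bool:
        return self.verdict == "partner"

    def as_dict(self) -> dict:
        return {
            "strategy": [float(x) for x in self.strategy.probs],
            "n": self.strategy.n,
            "verdict": self.verdict,
            "worst_deviation": self.worst_deviation,
            "worst_payoff": self.worst_payoff,
            "margin": self.margin,
            "binding_constraints": list(self.binding_constraints),
        }


def _canonical_rotation(cycle: str) -> str:
    return min(cycle[i:] + cycle[:i] for i in range(len(cycle)))


@functools.lru_cache(maxsize=None)
def enumerate_deviation_cycles(n: int) -> DeviationCycleSet:
    """Enumerate the periodic behaviors of pure self-reactive-n strategies.

    Nodes of the de Bruijn graph are own n-histories; appending an action
    moves to the shifted history. Every deterministic self-reactive strategy
    settles on a simple cycle of this graph, and conversely every simple cycle
    (visiting distinct histories) is realized by such a strategy, so this set
    is exactly the space of candidate best-response behaviors.
    """
    if not 1 <= n <= _MAX_N:
        raise ValueError(f"n must be between 1 and {_MAX_N}")
    mask = 2**n - 1
    g = nx.DiGraph()
    g.add_nodes_from(range(2**n))
    for h in range(2**n):
        for a in (0, 1):
            g.add_edge(h, ((h << 1) | a) & mask)
    cycles = set()
    for node_cycle in nx.simple_cycles(g):
        k = len(node_cycle)
        seq = "".join(
            "CD"[node_cycle[(i + 1) % k] & 1] for i in range(k)
        )
        cycles.add(_canonical_rotation(seq))
    ordered = tuple(sorted(cycles, key=lambda s: (len(s), s)))
    return DeviationCycleSet(n=n, cycles=ordered)


@functools.lru_cache(maxsize=None)
def _cycle_weights(n: int):
    """Per-cycle integer visit counts over opponent-history indices.

    Returns (cycles, WC, WD, lengths): WC[k, h] counts positions of cycle k
    whose action is C and whose preceding n-history has index h; WD likewise
    for D. Payoff of cycle k against reactive p is then
    ((R*WC + T*WD) @ p + (S*WC + P*WD) @ (1 - p)) / length.
    """
    cs = enumerate_deviation_cycles(n)
    m = len(cs.cycles)
    WC = np.zeros((m, 2**n), dtype=np.int64)
    WD = np.zeros((m, 2**n), dtype=np.int64)
    lengths = np.zeros(m, dtype=np.int64)
    for k, cycle in enumerate(cs.cycles):
        bits = [a == "D" for a in cycle]
        L = len(bits)
        lengths[k] = L
        for t in range(L):
            h = 0
            for j in range(n):
                h = (h << 1) | bits[(t - n + j) % L]
            if bits[t]:
                WD[k, h] += 1
            else:
                WC[k, h] += 1
    return cs.cycles, WC, WD, lengths


def deviation_payoffs(
    P: np.ndarray, n: int, game: GameParameters
) -> Tuple[Tuple[str, ...], np.ndarray]:
    """Cycle-average payoffs of every deviation cycle against a batch of
    reactive-n strategies.

    ``P`` has shape (batch, 2**n); returns (cycles, payoffs) with payoffs of
    shape (batch, num_cycles).
    """
    cycles, WC, WD, lengths = _cycle_weights(n)
    P = np.atleast_2d(np.asarray(P, dtype=float))
    on = (game.R * WC + game.T * WD).T
    off = (game.S * WC + game.P * WD).T
    pay = (P @ on + (1.0 - P) @ off) / lengths
    return cycles, pay


def self_reactive_from_cycle(cycle: str, n: int):
    """Pure self-reactive-n strategy whose long-run behavior repeats ``cycle``.

    Returns (strategy, initial_history_index): starting from the returned own
    n-history, the strategy deterministically plays the cycle forever.
    Histories never visited by the cycle are mapped to defection.
    """
    from .strategy_spaces import SelfReactiveStrategy

    bits = [{"C": 0, "D": 1}[a] for a in cycle]
    L = len(bits)
    probs = np.zeros(2**n)
    start = None
    for t in range(L):
        h = 0
        for j in range(n):
            h = (h << 1) | bits[(t - n + j) % L]
        probs[h] = 1.0 - bits[t]
        if t == 0:
            start = h
    return SelfReactiveStrategy(n, probs), start


def _as_reactive(p) -> ReactiveStrategy:
    if isinstance(p, CountingStrategy):
        return counting_to_reactive(p)
    if not isinstance(p, ReactiveStrategy):
        raise TypeError("expected a ReactiveStrategy or CountingStrategy")
    return p


def best_self_reactive_deviation(
    p: Union[ReactiveStrategy, CountingStrategy], game: GameParameters
) -> Tuple[float, str]:
    """Best per-round payoff achievable against ``p`` by any pure
    self-reactive deviator (maximizing over its initial history), and the
    cycle that achieves it."""
    p = _as_reactive(p)
    cycles, pay = deviation_payoffs(p.probs, p.n, game)
    k = int(np.argmax(pay[0]))
    return float(pay[0, k]), cycles[k]


def is_partner_oracle(
    p: Union[ReactiveStrategy, CountingStrategy],
    game: GameParameters,
    tol: float = NASH_TOL,
) -> PartnerReport:
    """Brute-force Nash check over all deviation cycles (any PD, any n <= 6).

    A partner is nice (cooperates for sure after n rounds of coplayer
    cooperation) and concedes no deviation cycle more than the mutual
    cooperation payoff R per round (weak inequality: ties are partners).
    """
    p = _as_reactive(p)
    cycles, pay = deviation_payoffs(p.probs, p.n, game)
    pay = pay[0]
    k = int(np.argmax(pay))
    margin = float(game.R - pay[k])
    binding = tuple(c for c, v in zip(cycles, pay) if abs(game.R - v) <= tol)
    if p.probs[0] < 1.0 - tol:
        verdict = "not_nice"
    elif margin >= -tol:
        verdict = "partner"
    else:
        verdict = "exploitable"
    return PartnerReport(
        strategy=p,
        verdict=verdict,
        worst_deviation=cycles[k],
        worst_payoff=float(pay[k]),
        margin=margin,
        binding_constraints=binding,
    )


def is_defector_oracle(
    p: Union[ReactiveStrategy, CountingStrategy],
    game: GameParameters,
    tol: float = NASH_TOL,
) -> bool:
    """True if mutual defection against ``p`` is a Nash outcome: ``p`` defects
    for sure after n rounds of coplayer defection, and no deviation cycle
    earns more than P per round."""
    p = _as_reactive(p)
    if p.probs[-1] > tol:
        return False
    _, pay = deviation_payoffs(p.probs, p.n, game)
    return bool(np.max(pay[0]) <= game.P + tol)


def _donation_ratio(game: GameParameters) -> float:
    return game.c / game.b


def is_partner_reactive2(
    p: ReactiveStrategy, game: GameParameters, tol: float = NASH_TOL
) -> Tuple[bool, Dict[str, float]]:
    """Closed-form partner conditions for reactive-2 in the donation game.

    Slack of each inequality is returned (threshold minus attained value;
    nonnegative means satisfied). Requires the donation parameterization.
    """
    if p.n != 2:
        raise ValueError("is_partner_reactive2 requires a reactive-2 strategy")
    cb = _donation_ratio(game)
    pCC, pCD, pDC, pDD = p.probs
    slacks = {
        "nice": pCC - 1.0,
        "CD": (1.0 - cb / 2.0) - (pCD + pDC) / 2.0,
        "D": (1.0 - cb) - pDD,
    }
    ok = pCC >= 1.0 - tol and slacks["CD"] >= -tol and slacks["D"] >= -tol
    return ok, slacks


def is_partner_reactive3(
    p: ReactiveStrategy, game: GameParameters, tol: float = NASH_TOL
) -> Tuple[bool, Dict[str, float]]:
    """Closed-form partner conditions for reactive-3 in the donation game.

    Histories are ordered CCC, CCD, CDC, CDD, DCC, DCD, DDC, DDD. Besides
    niceness, five averaged inequalities must hold; the right-hand side of
    each is 1 minus c/b times the fraction of defections across the
    corresponding deviation sequences.
    """
    if p.n != 3:
        raise ValueError("is_partner_reactive3 requires a reactive-3 strategy")
    cb = _donation_ratio(game)
    q = p.probs
    slacks = {
        "nice": q[0] - 1.0,
        "CD": (1.0 - cb / 2.0) - (q[2] + q[5]) / 2.0,
        "CCD": (1.0 - cb / 3.0) - (q[1] + q[2] + q[4]) / 3.0,
        "CDD": (1.0 - 2.0 * cb / 3.0) - (q[3] + q[5] + q[6]) / 3.0,
        "CCDD": (1.0 - cb / 2.0) - (q[1] + q[3] + q[4] + q[6]) / 4.0,
        "D": (1.0 - cb) - q[7],
    }
    ok = q[0] >= 1.0 - tol and all(
        s >= -tol for name, s in slacks.items() if name != "nice"
    )
    return ok, slacks


def is_partner_counting(
    r: CountingStrategy, game: GameParameters, tol: float = NASH_TOL
) -> Tuple[bool, Dict[str, float]]:
    """Closed-form partner conditions for counting-n in the donation game:
    r_n = 1 and r_{n-k} <= 1 - (k/n)(c/b) for k = 1..n."""
    if not isinstance(r, CountingStrategy):
        raise TypeError("expected a CountingStrategy")
    cb = _donation_ratio(game)
    n = r.n
    slacks = {"nice": r.probs[0] - 1.0}
    ok = r.probs[0] >= 1.0 - tol
    for k in range(1, n + 1):
        s = (1.0 - (k / n) * cb) - r.probs[k]
        slacks[f"r_{n - k}"] = s
        ok = ok and s >= -tol
    return ok, slacks


def _cycle_inequality(cycle_idx: int, n: int, cb: Fraction):
    """Exact inequality a . p[1:] <= rhs induced by one deviation cycle on a
    nice strategy (all-C entry substituted as 1), scaled to integer counts."""
    cycles, WC, WD, lengths = _cycle_weights(n)
    cnt = (WC[cycle_idx] + WD[cycle_idx]).astype(int)
    L = int(lengths[cycle_idx])
    nC = int(WC[cycle_idx].sum())
    # (1/L) sum_h cnt_h p_h <= 1 - (1 - nC/L) cb  (donation game)
    rhs = Fraction(L) * (1 - (1 - Fraction(nC, L)) * cb) - cnt[0]
    return tuple(cnt[1:]), rhs


def minimal_constraints(n: int, game: GameParameters) -> List[str]:
    """Irredundant deviation cycles constraining nice donation-game partners.

    Starting from the inequalities induced by every de Bruijn deviation cycle
    (with the all-C entry fixed at 1), proportional duplicates are merged
    exactly and each remaining inequality is dropped when it is implied by the
    others over the probability box [0, 1]^(2**n - 1), tested by linear
    programming. Returns the canonical cycle labels of the surviving
    constraints, shortest first.
    """
    if not 1 <= n <= 4:
        raise ValueError("minimal_constraints supports 1 <= n <= 4")
    cb = Fraction(game.c).limit_denominator(10**12) / Fraction(
        game.b
    ).limit_denominator(10**12)
    cycles, _, _, lengths = _cycle_weights(n)
    order = sorted(range(len(cycles)), key=lambda k: (lengths[k], cycles[k]))
    ineqs = {}  # normalized key -> (representative cycle, a, rhs)
    for k in order:
        a, rhs = _cycle_inequality(k, n, cb)
        if all(x == 0 for x in a):
            continue  # the all-C loop: satisfied with equality by niceness
        g = 0
        for x in a:
            g = gcd(g, x)
        key = (tuple(Fraction(x, g) for x in a), rhs / g)
        if key not in ineqs:
            ineqs[key] = (cycles[k], np.array(a, dtype=float), float(rhs))
    entries = list(ineqs.values())
    # Drop redundant inequalities, longest representative cycle first so the
    # short canonical deviations are retained.
    active = sorted(range(len(entries)), key=lambda i: (-len(entries[i][0]), entries[i][0]))
    kept = set(range(len(entries)))
    dim = 2**n - 1
    for i in active:
        others = [j for j in kept if j != i]
        a_i, rhs_i = entries[i][1], entries[i][2]
        if not others:
            continue
        res = linprog(
            -a_i,
            A_ub=np.array([entries[j][1] for j in others]),
            b_ub=np.array([entries[j][2] for j in others]),
            bounds=[(0.0, 1.0)] * dim,
            method="highs",
        )
        if res.status == 0 and -res.fun <= rhs_i + 1e-9:
            kept.discard(i)
    result = [entries[i][0] for i in kept]
    return sorted(result, key=lambda s: (len(s), s))


def _classify_partner_batch(
    P: np.ndarray, family: str, n: int, game: GameParameters, tol: float = NASH_TOL
) -> np.ndarray:
    """Vectorized partner classification for a batch of strategy vectors."""
    cb = _donation_ratio(game) if game.is_donation else None
    nice = P[:, 0] >= 1.0 - tol
    if family == "counting":
        ok = nice.copy()
        for k in range(1, n + 1):
            ok &= P[:, k] <= (1.0 - (k / n) * cb) + tol
        return ok
    if family == "reactive" and cb is not None and n == 1:
        return nice & (P[:, 1] <= 1.0 - cb + tol)
    if family == "reactive" and cb is not None and n == 2:
        return (
            nice
            & ((P[:, 1] + P[:, 2]) / 2.0 <= 1.0 - cb / 2.0 + tol)
            & (P[:, 3] <= 1.0 - cb + tol)
        )
    if family == "reactive" and cb is not None and n == 3:
        return (
            nice
            & ((P[:, 2] + P[:, 5]) / 2.0 <= 1.0 - cb / 2.0 + tol)
            & ((P[:, 1] + P[:, 2] + P[:, 4]) / 3.0 <= 1.0 - cb / 3.0 + tol)
            & ((P[:, 3] + P[:, 5] + P[:, 6]) / 3.0 <= 1.0 - 2.0 * cb / 3.0 + tol)
            & ((P[:, 1] + P[:, 3] + P[:, 4] + P[:, 6]) / 4.0 <= 1.0 - cb / 2.0 + tol)
            & (P[:, 7] <= 1.0 - cb + tol)
        )
    # generic oracle route (reactive vectors; counting handled above)
    _, pay = deviation_payoffs(P, n, game)
    return nice & (pay.max(axis=1) <= game.R + tol)


def partner_volume(
    family: str,
    n: int,
    game: GameParameters,
    samples: int,
    seed,
    nice_only: bool = True,
) -> Tuple[float, float]:
    """Monte-Carlo estimate of the relative volume of partner strategies.

    With ``nice_only=True`` (default) the all-C entry is fixed to 1 and the
    remaining entries are drawn uniformly, measuring the partner fraction of
    the nice-strategy slice. With ``nice_only=False`` all entries are free (an
    exact-niceness partner then has measure zero). Returns (estimate,
    binomial standard error).
    """
    if family not in ("reactive", "counting"):
        raise ValueError("partner volume is defined for reactive or counting families")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dim = 2**n if family == "reactive" else n + 1
    P = rng.random((samples, dim))
    if nice_only:
        P[:, 0] = 1.0
    hits = _classify_partner_batch(P, family, n, game)
    est = float(hits.mean())
    se = float(np.sqrt(est * (1.0 - est) / samples))
    return est, se


def counting_partner_volume_exact(n: int, game: GameParameters) -> float:
    """Exact nice-slice partner volume for counting-n in the donation game:
    the thresholds are independent, so the volume is the product of the
    interval lengths max(0, 1 - (k/n)(c/b))."""
    cb = _donation_ratio(game)
    vol = 1.0
    for k in range(1, n + 1):
        vol *= max(0.0, 1.0 - (k / n) * cb)
    return vol


def reactive2_partner_volume_exact(game: GameParameters) -> float:
    """Exact nice-slice partner volume for reactive-2 in the donation game:
    a box in p_DD times the unit square truncated by p_CD + p_DC <= 2 - c/b."""
    cb = _donation_ratio(game)
    if cb >= 1.0:
        return 0.0
    return (1.0 - cb) * (1.0 - cb**2 / 2.0)


# ---------------------------------------------------------------------------
# Reduction-theorem cross-check: best response among ALL pure memory-n
# deviators equals the best pure self-reactive deviation.
# ---------------------------------------------------------------------------


def _policy_average_payoff(
    a1: np.ndarray, pc2: np.ndarray, reward: np.ndarray, nxt: np.ndarray
) -> float:
    """Exact best long-run average reward of one deterministic policy.

    The deviator picks its initial state, so the value is the maximum of the
    stationary average reward over the recurrent classes of the induced chain.
    """
    S = len(a1)
    rows = np.arange(S)
    succC = nxt[rows, a1, 0]
    succD = nxt[rows, a1, 1]
    K = np.zeros((S, S))
    np.add.at(K, (rows, succC), pc2)
    np.add.at(K, (rows, succD), 1.0 - pc2)
    support = csr_matrix(K > 0.0)
    ncomp, labels = connected_components(support, directed=True, connection="strong")
    r, c = np.nonzero(K)
    leaky = set(labels[r[labels[r] != labels[c]]])
    best = -np.inf
    for comp in range(ncomp):
        if comp in leaky:
            continue
        idx = np.nonzero(labels == comp)[0]
        pi = _solve_stationary(K[np.ix_(idx, idx)])
        best = max(best, float(pi @ reward[idx]))
    return best


def best_pure_memory_deviation(
    p: ReactiveStrategy,
    game: GameParameters,
    alpha: float = 1.0 - 1e-6,
    margin: float = 1e-5,
    cap: int = 512,
    batch: int = 65536,
) -> float:
    """Best long-run payoff over ALL deterministic memory-n deviators.

    Enumerates every pure memory-n strategy (2**(4**n): 16 at n=1, 65,536 at
    n=2) against the reactive strategy ``p``. Each deviator's value is first
    computed by a batched discounted solve at discount ``alpha`` (a screening
    pass over the full enumeration); the near-optimal candidates are then
    re-evaluated exactly via the stationary distributions of their recurrent
    classes, and the exact maximum is returned.
    """
    n = p.n
    if n > 2:
        raise ValueError("exhaustive memory-deviator enumeration supports n <= 2")
    S = 4**n
    npol = 2**S
    h1, _, _, nxt = _state_tables(n)
    pc2 = p.probs[h1]  # opponent reacts to the deviator's own history
    pm = game.payoff_matrix
    rewC = pc2 * pm[0, 0] + (1.0 - pc2) * pm[0, 1]
    rewD = pc2 * pm[1, 0] + (1.0 - pc2) * pm[1, 1]

    best_gain = -np.inf
    candidates: List[np.ndarray] = []
    rows = np.arange(S)
    for start in range(0, npol, batch):
        pols = np.arange(start, min(start + batch, npol))
        a1 = ((pols[:, None] >> rows[None, :]) & 1).astype(np.intp)  # (B, S)
        B = len(pols)
        reward = np.where(a1 == 0, rewC, rewD)
        succC = nxt[rows[None, :], a1, 0]
        succD = nxt[rows[None, :], a1, 1]
        M = np.tile(np.eye(S), (B, 1, 1))
        b_idx = np.repeat(np.arange(B), S)
        s_idx = np.tile(rows, B)
        np.add.at(M, (b_idx, s_idx, succC.ravel()), -alpha * np.tile(pc2, B))
        np.add.at(M, (b_idx, s_idx, succD.ravel()), -alpha * np.tile(1.0 - pc2, B))
        V = np.linalg.solve(M, reward[..., None])[..., 0]
        gains = (1.0 - alpha) * V.max(axis=1)
        gmax = float(gains.max())
        best_gain = max(best_gain, gmax)
        keep = np.nonzero(gains >= best_gain - margin * (1.0 + abs(best_gain)))[0]
        for i in keep:
            candidates.append((float(gains[i]), a1[i].copy()))
    cutoff = best_gain - margin * (1.0 + abs(best_gain))
    finalists = [a for g, a in candidates if g >= cutoff]
    if len(finalists) > cap:
        finalists = [
            a
            for _, a in sorted(
                ((g, a) for g, a in candidates if g >= cutoff),
                key=lambda t: -t[0],
            )[:cap]
        ]
    reward_table = np.stack([rewC, rewD])
    best = -np.inf
    for a1 in finalists:
        reward = reward_table[a1, rows]
        best = max(best, _policy_average_payoff(a1, pc2, reward, nxt))
    return best
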