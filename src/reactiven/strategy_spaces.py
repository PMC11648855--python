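"""Finite-memory strategy families for the repeated prisoner's dilemma.

A player with *n* rounds of memory conditions its cooperation probability on
some part of the last *n* rounds of play. Four families are provided:

``ReactiveStrategy``
    conditions on the *coplayer's* last ``n`` actions (2**n entries);
``SelfReactiveStrategy``
    conditions on the player's *own* last ``n`` actions (2**n entries);
``CountingStrategy``
    conditions only on how often the coplayer cooperated in the last ``n``
    rounds (n+1 entries, ordered from "cooperated n times" down to "never");
``MemoryStrategy``
    conditions on the joint history of both players (4**n entries).

Histories are tuples over {"C", "D"} with the *oldest* action first. They are
indexed lexicographically with C before D, i.e. C maps to bit 0 and D to bit 1
with the oldest action in the most significant position. For n = 2 the order
is CC, CD, DC, DD.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Sequence, Union

import numpy as np

ACTIONS = ("C", "D")

__all__ = [
    "ACTIONS",
    "History",
    "history_index",
    "index_to_history",
    "shift_history",
    "ReactiveStrategy",
    "SelfReactiveStrategy",
    "CountingStrategy",
    "MemoryStrategy",
    "Strategy",
    "counting_to_reactive",
    "named_strategy",
    "sample_uniform",
    "num_pure_strategies",
    "strategy_to_json",
    "strategy_from_json",
    "FAMILIES",
]

History = tuple  # tuple of "C"/"D", oldest action first


def _as_history(h: Union[str, Iterable[str]]) -> tuple:
    h = tuple(h)
    for a in h:
        if a not in ACTIONS:
            raise ValueError(f"invalid action {a!r}; actions must be 'C' or 'D'")
    return h


def history_index(h: Union[str, Iterable[str]]) -> int:
    """Map an n-history to its lexicographic index in 0 .. 2**n - 1.

    C sorts before D at every position and the oldest action occupies the
    most significant bit, so e.g. (C,C) -> 0, (C,D) -> 1, (D,C) -> 2.
    """
    idx = 0
    for a in _as_history(h):
        idx = (idx << 1) | (a == "D")
    return idx


def index_to_history(index: int, n: int) -> tuple:
    """Inverse of :func:`history_index` for histories of length ``n``."""
    if not 0 <= index < 2**n:
        raise ValueError(f"index {index} out of range for n={n}")
    return tuple(ACTIONS[(index >> (n - 1 - k)) & 1] for k in range(n))


def shift_history(h: Union[str, Iterable[str]], action: str) -> tuple:
    """Drop the oldest action and append ``action`` as the most recent one."""
    h = _as_history(h)
    if action not in ACTIONS:
        raise ValueError(f"invalid action {action!r}")
    return h[1:] + (action,)


def _validated_probs(probs, expected_len: int) -> np.ndarray:
    arr = np.asarray(probs, dtype=float)
    if arr.ndim != 1 or arr.shape[0] != expected_len:
        raise ValueError(
            f"expected a probability vector of length {expected_len}, "
            f"got shape {arr.shape}"
        )
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError("cooperation probabilities must lie in [0, 1]")
    arr = arr.copy()
    arr.setflags(write=False)
    return arr


@dataclasses.dataclass(frozen=True)
class _BaseStrategy:
    n: int
    probs: np.ndarray

    family = ""  # class attribute, not a dataclass field

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("memory length n must be >= 1")
        object.__setattr__(
            self, "probs", _validated_probs(self.probs, self._expected_len())
        )

    def _expected_len(self) -> int:  # pragma: no cover - overridden
        raise NotImplementedError

    @property
    def is_pure(self) -> bool:
        return bool(np.all((self.probs == 0.0) | (self.probs == 1.0)))

    def with_probs(self, probs) -> "_BaseStrategy":
        return type(self)(self.n, probs)

    def as_memory(self, n: int | None = None) -> np.ndarray:
        """Full joint-history cooperation vector of length 4**n.

        Entry ``s`` is the cooperation probability given joint state
        ``s = own_index * 2**n + coplayer_index``.
        """
        raise NotImplementedError

    def __eq__(self, other):
        return (
            type(self) is type(other)
            and self.n == other.n
            and np.array_equal(self.probs, other.probs)
        )

    def __hash__(self):
        return hash((type(self).__name__, self.n, self.probs.tobytes()))


def _lift_vector(probs: np.ndarray, n_from: int, n_to: int) -> np.ndarray:
    """Lift a 2**n_from history-indexed vector to memory n_to.

    The response only depends on the last ``n_from`` actions, which occupy the
    least significant bits of the longer history index.
    """
    if n_to < n_from:
        raise ValueError(f"cannot lift memory-{n_from} strategy down to n={n_to}")
    idx = np.arange(2**n_to) & (2**n_from - 1)
    return probs[idx]


class ReactiveStrategy(_BaseStrategy):
    """Cooperation probability indexed by the coplayer's n-history."""

    family = "reactive"

    def _expected_len(self) -> int:
        return 2**self.n

    @property
    def is_nice(self) -> bool:
        """Never the first to defect: cooperate for sure after n rounds of C."""
        return self.probs[0] == 1.0

    def lift(self, n: int) -> "ReactiveStrategy":
        return ReactiveStrategy(n, _lift_vector(self.probs, self.n, n))

    def as_memory(self, n: int | None = None) -> np.ndarray:
        n = self.n if n is None else n
        lifted = _lift_vector(self.probs, self.n, n)
        states = np.arange(4**n)
        return lifted[states & (2**n - 1)]  # depends on coplayer bits only


class SelfReactiveStrategy(_BaseStrategy):
    """Cooperation probability indexed by the player's own n-history."""

    family = "self_reactive"

    def _expected_len(self) -> int:
        return 2**self.n

    def lift(self, n: int) -> "SelfReactiveStrategy":
        return SelfReactiveStrategy(n, _lift_vector(self.probs, self.n, n))

    def as_memory(self, n: int | None = None) -> np.ndarray:
        n = self.n if n is None else n
        lifted = _lift_vector(self.probs, self.n, n)
        states = np.arange(4**n)
        return lifted[states >> n]  # depends on own bits only


class CountingStrategy(_BaseStrategy):
    """Reactive strategy that only counts the coplayer's cooperative acts.

    ``probs`` is ordered (r_n, r_{n-1}, ..., r_0): entry ``j`` applies when the
    coplayer cooperated ``n - j`` times during the last ``n`` rounds, i.e.
    defected ``j`` times.
    """

    family = "counting"

    def _expected_len(self) -> int:
        return self.n + 1

    @property
    def is_nice(self) -> bool:
        return self.probs[0] == 1.0

    def to_reactive(self) -> ReactiveStrategy:
        return counting_to_reactive(self)

    def as_memory(self, n: int | None = None) -> np.ndarray:
        return self.to_reactive().as_memory(n)


class MemoryStrategy(_BaseStrategy):
    """Cooperation probability indexed by the joint n-history (own, coplayer)."""

    family = "memory"

    def _expected_len(self) -> int:
        return 4**self.n

    def lift(self, n: int) -> "MemoryStrategy":
        if n < self.n:
            raise ValueError(f"cannot lift memory-{self.n} strategy down to n={n}")
        states = np.arange(4**n)
        mask = 2**self.n - 1
        own = (states >> n) & mask
        opp = states & mask
        return MemoryStrategy(n, self.probs[own * 2**self.n + opp])

    def as_memory(self, n: int | None = None) -> np.ndarray:
        n = self.n if n is None else n
        return self.lift(n).probs if n != self.n else self.probs.copy()


Strategy = Union[ReactiveStrategy, SelfReactiveStrategy, CountingStrategy, MemoryStrategy]

FAMILIES = {
    "reactive": ReactiveStrategy,
    "self_reactive": SelfReactiveStrategy,
    "counting": CountingStrategy,
    "memory": MemoryStrategy,
}


def counting_to_reactive(r: CountingStrategy) -> ReactiveStrategy:
    """Expand a counting strategy to the equivalent reactive-n vector.

    Every history with the same number of cooperative acts receives the same
    entry: p_h = r_{#C(h)}. Since the counting vector is ordered by the number
    of defections, history index ``h`` maps to entry ``popcount(h)``.
    """
    if not isinstance(r, CountingStrategy):
        raise TypeError("expected a CountingStrategy")
    idx = np.arange(2**r.n)
    defections = np.array([bin(h).count("1") for h in idx])
    return ReactiveStrategy(r.n, r.probs[defections])


_NAMED_BASE = {
    "ALLD": (1, (0.0, 0.0)),
    "ALLC": (1, (1.0, 1.0)),
    "TFT": (1, (1.0, 0.0)),
    "TF2T": (2, (1.0, 1.0, 1.0, 0.0)),
    "2TFT": (2, (1.0, 0.0, 0.0, 0.0)),
}


def named_strategy(name: str, n: int = 1, game=None) -> ReactiveStrategy:
    """Return a canonical named strategy at memory length ``n``.

    Shorter-memory strategies are lifted by replicating the response over the
    ignored (older) history positions; e.g. TFT at n=2 is (1, 0, 1, 0).
    GTFT's generosity depends on the game: 1 - c/b in the donation game, and
    min(1 - (T-R)/(R-S), (R-P)/(T-P)) for a general prisoner's dilemma, so it
    requires ``game``.
    """
    key = name.upper()
    if key == "GTFT":
        if game is None:
            raise ValueError("GTFT requires game parameters to set its generosity")
        if game.is_donation:
            g = 1.0 - game.c / game.b
        else:
            g = min(
                1.0 - (game.T - game.R) / (game.R - game.S),
                (game.R - game.P) / (game.T - game.P),
            )
        g = float(np.clip(g, 0.0, 1.0))
        return ReactiveStrategy(1, (1.0, g)).lift(n)
    if key not in _NAMED_BASE:
        raise ValueError(
            f"unknown strategy name {name!r}; known: "
            f"{sorted(_NAMED_BASE) + ['GTFT']}"
        )
    base_n, probs = _NAMED_BASE[key]
    if n < base_n:
        raise ValueError(f"{name} needs memory length >= {base_n}, got n={n}")
    return ReactiveStrategy(base_n, probs).lift(n)


def sample_uniform(family: str, n: int, rng) -> Strategy:
    """Draw a strategy with i.i.d. uniform [0,1] entries.

    ``rng`` is a :class:`numpy.random.Generator` or an integer seed.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; known: {sorted(FAMILIES)}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cls = FAMILIES[family]
    length = {"reactive": 2**n, "self_reactive": 2**n, "counting": n + 1, "memory": 4**n}[family]
    return cls(n, rng.random(length))


def num_pure_strategies(family: str, n: int) -> int:
    """Number of deterministic strategies in a family at memory length n."""
    length = {"reactive": 2**n, "self_reactive": 2**n, "counting": n + 1, "memory": 4**n}
    if family not in length:
        raise ValueError(f"unknown family {family!r}")
    return 2 ** length[family]


def strategy_to_json(s: Strategy) -> str:
    return json.dumps(
        {"family": s.family, "n": s.n, "probs": [float(x) for x in s.probs]}
    )


def strategy_from_json(text: Union[str, dict]) -> Strategy:
    obj = json.loads(text) if isinstance(text, str) else text
    cls = FAMILIES[obj["family"]]
    return cls(int(obj["n"]), obj["probs"])
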