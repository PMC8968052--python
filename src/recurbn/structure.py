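"""Score-based structure learning: decomposable BIC + hill climbing.

Sign convention: HIGHER IS BETTER. The score of a DAG is the maximum-
likelihood log-likelihood minus ``(log N / 2) * parameter count``, summed
over nodes; it decomposes, so each move re-scores only the affected
children. Moves are single-arc additions, deletions and reversals, greedy
best-improvement from the empty graph, with seeded random-restart
perturbations of the incumbent optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bn import DAG, check_acyclic

logger = logging.getLogger(__name__)

__all__ = ["ScoreCache", "local_score", "bic", "hill_climb"]

TOL = 1e-9


class ScoreCache:
    """Cache of local BIC scores keyed by (node, frozen parent set).

    Bound to one dataset; holds the integer-coded columns so repeated
    contingency counts stay cheap.
    """

    def __init__(self, data: pd.DataFrame, columns: Sequence[str] | None = None):
        if len(data) == 0:
            raise ValueError("empty data")
        self.columns = list(columns) if columns is not None else list(data.columns)
        self.n = len(data)
        self._codes: dict[str, np.ndarray] = {}
        self._cards: dict[str, int] = {}
        for c in self.columns:
            cat = pd.Categorical(data[c])
            if cat.codes.min() < 0:
                raise ValueError(f"column {c!r} contains missing values")
            self._codes[c] = cat.codes.astype(np.int64)
            self._cards[c] = len(cat.categories)
        self._cache: dict[tuple[str, frozenset[str]], float] = {}

    def cardinality(self, node: str) -> int:
        return self._cards[node]

    def local_score(self, node: str, parents: Iterable[str]) -> float:
        parents = frozenset(parents)
        key = (node, parents)
        if key in self._cache:
            return self._cache[key]
        ordered = sorted(parents)
        r = self._cards[node]
        q = 1
        idx = np.zeros(self.n, dtype=np.int64)
        for p in ordered:
            idx = idx * self._cards[p] + self._codes[p]
            q *= self._cards[p]
        counts = np.bincount(idx * r + self._codes[node], minlength=q * r).reshape(q, r)
        totals = counts.sum(axis=1, keepdims=True)
        nz = counts > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = float((counts[nz] * np.log(counts[nz] / np.broadcast_to(totals, counts.shape)[nz])).sum())
        penalty = 0.5 * np.log(self.n) * (r - 1) * q
        score = ll - penalty
        self._cache[key] = score
        return score


def local_score(node: str, parents: Iterable[str], data: pd.DataFrame) -> float:
    """BIC local score of one node given a parent set (higher is better)."""
    return ScoreCache(data).local_score(node, parents)


def bic(dag: DAG, data: pd.DataFrame, cache: ScoreCache | None = None) -> float:
    """Decomposable BIC of a DAG: sum of local scores (higher is better)."""
    if not check_acyclic(dag):
        raise ValueError("bic requires an acyclic graph")
    cache = cache or ScoreCache(data, columns=list(dag.nodes))
    return sum(cache.local_score(n, dag.parents(n)) for n in dag.nodes)


@dataclass
class _State:
    """Mutable parent-set representation of the current DAG."""

    nodes: tuple[str, ...]
    parents: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for n in self.nodes:
            self.parents.setdefault(n, set())

    def arcs(self) -> set[tuple[str, str]]:
        return {(p, c) for c, ps in self.parents.items() for p in ps}

    def creates_cycle(self, u: str, v: str) -> bool:
        """Would adding u -> v close a directed cycle? (DFS from v to u)."""
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for c, ps in self.parents.items():
            for p in ps:
                children[p].append(c)
        stack, seen = [v], set()
        while stack:
            x = stack.pop()
            if x == u:
                return True
            if x in seen:
                continue
            seen.add(x)
            stack.extend(children[x])
        return False

    def to_dag(self) -> DAG:
        return DAG(self.nodes, self.arcs())


def _candidate_moves(state: _State, forbidden: set[tuple[str, str]]):
    """Yield (move_type, u, v) tuples; order is deterministic."""
    nodes = state.nodes
    arcs = state.arcs()
    for u in nodes:
        for v in nodes:
            if u == v:
                continue
            if (u, v) in arcs:
                yield ("delete", u, v)
                if (v, u) not in forbidden and not _reverse_creates_cycle(state, u, v):
                    yield ("reverse", u, v)
            elif (v, u) not in arcs and (u, v) not in forbidden:
                if not state.creates_cycle(u, v):
                    yield ("add", u, v)


def _reverse_creates_cycle(state: _State, u: str, v: str) -> bool:
    state.parents[v].discard(u)
    bad = state.creates_cycle(v, u)
    state.parents[v].add(u)
    return bad


def _move_gain(state: _State, cache: ScoreCache, move: tuple[str, str, str]) -> float:
    kind, u, v = move
    if kind == "add":
        return cache.local_score(v, state.parents[v] | {u}) - cache.local_score(v, state.parents[v])
    if kind == "delete":
        return cache.local_score(v, state.parents[v] - {u}) - cache.local_score(v, state.parents[v])
    # reverse u -> v
    gain_v = cache.local_score(v, state.parents[v] - {u}) - cache.local_score(v, state.parents[v])
    gain_u = cache.local_score(u, state.parents[u] | {v}) - cache.local_score(u, state.parents[u])
    return gain_v + gain_u


def _apply(state: _State, move: tuple[str, str, str]) -> None:
    kind, u, v = move
    if kind == "add":
        state.parents[v].add(u)
    elif kind == "delete":
        state.parents[v].discard(u)
    else:
        state.parents[v].discard(u)
        state.parents[u].add(v)


def _climb(state: _State, cache: ScoreCache, forbidden: set[tuple[str, str]], log: list) -> float:
    score = sum(cache.local_score(n, state.parents[n]) for n in state.nodes)
    while True:
        best_gain, best_move = TOL, None
        for move in _candidate_moves(state, forbidden):
            gain = _move_gain(state, cache, move)
            # deterministic tie-break: larger gain, then (parent, child, kind)
            if gain > best_gain + TOL or (
                best_move is not None
                and abs(gain - best_gain) <= TOL
                and (move[1], move[2], move[0]) < (best_move[1], best_move[2], best_move[0])
            ):
                best_gain, best_move = gain, move
        if best_move is None:
            return score
        _apply(state, best_move)
        score += best_gain
        log.append((best_move, best_gain))


def hill_climb(
    data: pd.DataFrame,
    nodes: Sequence[str] | None = None,
    forbidden: Iterable[tuple[str, str]] = (),
    restarts: int = 5,
    perturb: int = 5,
    seed: int = 0,
    move_log: list | None = None,
) -> DAG:
    """Greedy BIC hill climbing from the empty graph with random restarts.

    Each restart applies ``perturb`` random admissible moves to the best DAG
    seen, re-climbs, and keeps the better optimum. Forbidden arcs are never
    proposed; every returned DAG is acyclic and blacklist-compliant.
    """
    if restarts < 0:
        raise ValueError("restarts must be >= 0")
    if len(data) == 0:
        raise ValueError("no data rows")
    nodes = tuple(nodes) if nodes is not None else tuple(data.columns)
    forbidden = {tuple(a) for a in forbidden}
    cache = ScoreCache(data, columns=nodes)
    log: list = move_log if move_log is not None else []
    rng = np.random.default_rng(seed)

    state = _State(nodes)
    best_score = _climb(state, cache, forbidden, log)
    best_parents = {n: set(ps) for n, ps in state.parents.items()}

    for r in range(restarts):
        log.append(("restart", r))
        state = _State(nodes, {n: set(ps) for n, ps in best_parents.items()})
        for _ in range(perturb):
            moves = list(_candidate_moves(state, forbidden))
            if not moves:
                break
            _apply(state, moves[rng.integers(len(moves))])
        score = _climb(state, cache, forbidden, log)
        if score > best_score + TOL:
            best_score = score
            best_parents = {n: set(ps) for n, ps in state.parents.items()}
            logger.info("hill_climb: restart %d improved score to %.4f", r, best_score)

    final = _State(nodes, best_parents)
    dag = final.to_dag()
    assert not (dag.arcs & forbidden)
    return dag
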