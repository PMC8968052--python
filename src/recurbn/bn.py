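"""Discrete Bayesian network core: DAG, CPTs, fitting, likelihood, sampling.

All variables are categorical with explicit, ordered category label lists.
CPT tables are stored as ``(n_parent_configs, n_categories)`` arrays whose
rows sum to one; parent configurations are enumerated in mixed-radix order
with the *last* parent varying fastest (C order of ``np.ndindex``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DAG",
    "CPT",
    "BayesianNetwork",
    "check_acyclic",
    "fit_parameters",
    "log_likelihood",
    "ancestral_sample",
]


class CyclicGraphError(ValueError):
    """Raised when an operation requires a DAG but the graph has a cycle."""


@dataclass(frozen=True)
class DAG:
    """A directed acyclic graph over named variables.

    Parameters
    ----------
    nodes
        Variable names. Order is preserved and used for deterministic output.
    arcs
        Directed ``(parent, child)`` pairs.
    """

    nodes: tuple[str, ...]
    arcs: frozenset[tuple[str, str]]

    def __init__(self, nodes: Iterable[str], arcs: Iterable[tuple[str, str]] = ()):
        nodes = tuple(nodes)
        arcs_list = [tuple(a) for a in arcs]
        arcset = frozenset(arcs_list)
        if len(set(nodes)) != len(nodes):
            raise ValueError("duplicate node names")
        if len(arcs_list) != len(arcset):
            raise ValueError("duplicate arcs")
        node_set = set(nodes)
        for u, v in arcset:
            if u == v:
                raise ValueError(f"self-arc {u!r} -> {v!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"arc ({u!r}, {v!r}) references undeclared node")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "arcs", arcset)
        if not check_acyclic(self):
            cycle = nx.find_cycle(self.to_networkx())
            raise CyclicGraphError(f"graph contains a cycle: {cycle}")

    def parents(self, node: str) -> tuple[str, ...]:
        """Parents of ``node`` in declaration order of ``self.nodes``."""
        ps = {u for (u, v) in self.arcs if v == node}
        return tuple(n for n in self.nodes if n in ps)

    def children(self, node: str) -> tuple[str, ...]:
        cs = {v for (u, v) in self.arcs if u == node}
        return tuple(n for n in self.nodes if n in cs)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g

    def topological_order(self) -> list[str]:
        order = list(nx.lexicographical_topological_sort(self.to_networkx()))
        return order

    def with_arcs(self, add: Iterable[tuple[str, str]] = (), remove: Iterable[tuple[str, str]] = ()) -> "DAG":
        arcs = (set(self.arcs) - set(map(tuple, remove))) | set(map(tuple, add))
        return DAG(self.nodes, arcs)


def check_acyclic(dag: DAG | nx.DiGraph) -> bool:
    """Return True iff the directed graph has no cycle."""
    g = dag.to_networkx() if isinstance(dag, DAG) else dag
    return nx.is_directed_acyclic_graph(g)


@dataclass
class CPT:
    """Conditional probability table of one node given its parents.

    ``table[j, i]`` is ``P(node = categories[i] | parents in config j)`` where
    configuration ``j`` decodes in mixed radix over ``parent_order`` with the
    last parent fastest.
    """

    node: str
    categories: tuple[str, ...]
    parent_order: tuple[str, ...]
    parent_cards: tuple[int, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        self.categories = tuple(self.categories)
        self.parent_order = tuple(self.parent_order)
        self.parent_cards = tuple(int(c) for c in self.parent_cards)
        self.table = np.asarray(self.table, dtype=float)
        q = int(np.prod(self.parent_cards)) if self.parent_cards else 1
        if self.table.shape != (q, len(self.categories)):
            raise ValueError(
                f"CPT for {self.node!r}: table shape {self.table.shape} != ({q}, {len(self.categories)})"
            )
        if (self.table < 0).any():
            raise ValueError(f"CPT for {self.node!r} has negative entries")
        if not np.allclose(self.table.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"CPT rows for {self.node!r} do not sum to 1")

    @property
    def cardinality(self) -> int:
        return len(self.categories)

    def config_index(self, parent_values: Mapping[str, int]) -> int:
        """Mixed-radix row index for integer-coded parent values."""
        idx = 0
        for p, card in zip(self.parent_order, self.parent_cards):
            idx = idx * card + parent_values[p]
        return idx


@dataclass
class BayesianNetwork:
    """A DAG plus one CPT per node with consistent category sets."""

    dag: DAG
    cpts: dict[str, CPT] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.cpts) != set(self.dag.nodes):
            raise ValueError("CPTs must cover exactly the DAG nodes")
        for node, cpt in self.cpts.items():
            if set(cpt.parent_order) != set(self.dag.parents(node)):
                raise ValueError(
                    f"CPT parents {cpt.parent_order} for {node!r} differ from DAG parents {self.dag.parents(node)}"
                )
            for p, card in zip(cpt.parent_order, cpt.parent_cards):
                if card != self.cpts[p].cardinality:
                    raise ValueError(f"parent cardinality mismatch on arc {p!r} -> {node!r}")

    def categories(self, node: str) -> tuple[str, ...]:
        return self.cpts[node].categories

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": list(self.dag.nodes),
            "arcs": sorted(self.dag.arcs),
            "cpts": {
                n: {
                    "categories": list(c.categories),
                    "parents": list(c.parent_order),
                    "table": c.table.tolist(),
                }
                for n, c in self.cpts.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "BayesianNetwork":
        dag = DAG(d["nodes"], [tuple(a) for a in d["arcs"]])
        cpts = {}
        for n, c in d["cpts"].items():
            parents = tuple(c["parents"])
            cards = tuple(len(d["cpts"][p]["categories"]) for p in parents)
            cpts[n] = CPT(n, tuple(c["categories"]), parents, cards, np.array(c["table"]))
        return cls(dag, cpts)

    @classmethod
    def from_json(cls, path) -> "BayesianNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ----------------------------------------------------------------------
# fitting / likelihood / sampling
# ----------------------------------------------------------------------

def _encode(data: pd.DataFrame, node: str, categories: Sequence[str]) -> np.ndarray:
    codes = pd.Categorical(data[node], categories=list(categories)).codes
    if (codes < 0).any():
        bad = sorted(set(data[node][codes < 0].astype(str)))
        raise ValueError(f"column {node!r} contains values outside its category set: {bad}")
    return codes.astype(np.int64)


def infer_categories(data: pd.DataFrame, nodes: Iterable[str]) -> dict[str, tuple[str, ...]]:
    """Sorted observed category labels per column."""
    return {n: tuple(sorted(map(str, pd.unique(data[n].dropna())))) for n in nodes}


def fit_parameters(
    dag: DAG,
    data: pd.DataFrame,
    alpha: float = 1.0,
    categories: Mapping[str, Sequence[str]] | None = None,
) -> BayesianNetwork:
    """Estimate all CPTs from complete categorical data.

    Each CPT cell is ``(count + alpha) / (config total + alpha * cardinality)``;
    ``alpha=0`` gives maximum-likelihood frequencies. Parent configurations
    never observed get a uniform row when ``alpha=0`` (with a logged warning).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    missing = [n for n in dag.nodes if n not in data.columns]
    if missing:
        raise ValueError(f"data lacks columns for nodes: {missing}")
    cats = dict(categories) if categories is not None else infer_categories(data, dag.nodes)
    for n in dag.nodes:
        cats[n] = tuple(cats[n])
    codes = {n: _encode(data, n, cats[n]) for n in dag.nodes}
    cpts: dict[str, CPT] = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        r = len(cats[node])
        cards = tuple(len(cats[p]) for p in parents)
        q = int(np.prod(cards)) if cards else 1
        idx = np.zeros(len(data), dtype=np.int64)
        for p, card in zip(parents, cards):
            idx = idx * card + codes[p]
        counts = np.bincount(idx * r + codes[node], minlength=q * r).reshape(q, r).astype(float)
        totals = counts.sum(axis=1, keepdims=True)
        if alpha == 0:
            empty = totals[:, 0] == 0
            if empty.any():
                logger.warning(
                    "node %r: %d unseen parent configuration(s); substituting uniform rows",
                    node,
                    int(empty.sum()),
                )
                counts[empty] = 1.0
                totals = counts.sum(axis=1, keepdims=True)
            table = counts / totals
        else:
            table = (counts + alpha) / (totals + alpha * r)
        cpts[node] = CPT(node, cats[node], parents, cards, table)
    return BayesianNetwork(dag, cpts)


def log_likelihood(bn: BayesianNetwork, data: pd.DataFrame) -> float:
    """Joint log-likelihood of complete rows; ``-inf`` if any zero cell is hit."""
    total = 0.0
    codes = {n: _encode(data, n, bn.categories(n)) for n in bn.dag.nodes}
    for node in bn.dag.nodes:
        cpt = bn.cpts[node]
        idx = np.zeros(len(data), dtype=np.int64)
        for p, card in zip(cpt.parent_order, cpt.parent_cards):
            idx = idx * card + codes[p]
        probs = cpt.table[idx, codes[node]]
        if (probs == 0).any():
            logger.warning("node %r: zero-probability cell hit; log-likelihood is -inf", node)
            return float("-inf")
        total += float(np.log(probs).sum())
    return total


def ancestral_sample(bn: BayesianNetwork, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` complete rows in topological order; deterministic per seed."""
    if n <= 0:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    order = bn.dag.topological_order()
    codes: dict[str, np.ndarray] = {}
    for node in order:
        cpt = bn.cpts[node]
        idx = np.zeros(n, dtype=np.int64)
        for p, card in zip(cpt.parent_order, cpt.parent_cards):
            idx = idx * card + codes[p]
        u = rng.random(n)
        cum = np.cumsum(cpt.table, axis=1)
        codes[node] = (u[:, None] > cum[idx]).sum(axis=1)
    out = {
        node: pd.Categorical.from_codes(codes[node], categories=list(bn.categories(node)))
        for node in bn.dag.nodes
    }
    return pd.DataFrame({n_: pd.Series(c).astype(str) for n_, c in out.items()})
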