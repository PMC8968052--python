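"""Exact inference by variable elimination.

Factors are dense numpy arrays with one axis per variable. Elimination order
is the min-degree heuristic on the moralized evidence-reduced graph, ties
broken alphabetically, so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .bn import BayesianNetwork

__all__ = ["Factor", "posterior", "joint_distribution", "InconsistentEvidenceError"]


class InconsistentEvidenceError(ValueError):
    """Evidence assignment with zero probability under the network."""


@dataclass
class Factor:
    variables: tuple[str, ...]
    values: np.ndarray  # one axis per variable, axis order == variables

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != len(self.variables):
            raise ValueError("factor rank does not match variable count")

    def multiply(self, other: "Factor") -> "Factor":
        out_vars = self.variables + tuple(v for v in other.variables if v not in self.variables)
        a = _expand(self, out_vars)
        b = _expand(other, out_vars)
        return Factor(out_vars, a * b)

    def marginalize(self, var: str) -> "Factor":
        axis = self.variables.index(var)
        return Factor(
            self.variables[:axis] + self.variables[axis + 1 :],
            self.values.sum(axis=axis),
        )

    def reduce(self, var: str, index: int) -> "Factor":
        axis = self.variables.index(var)
        return Factor(
            self.variables[:axis] + self.variables[axis + 1 :],
            np.take(self.values, index, axis=axis),
        )


def _expand(f: Factor, out_vars: Sequence[str]) -> np.ndarray:
    """Broadcast a factor's array onto the axis order ``out_vars``."""
    shape = []
    src_axes = []
    for v in out_vars:
        if v in f.variables:
            src_axes.append(f.variables.index(v))
    arr = np.transpose(f.values, src_axes) if f.variables else f.values
    present = [v for v in out_vars if v in f.variables]
    # insert singleton axes for absent variables
    full_shape = []
    it = iter(range(arr.ndim))
    dims = dict(zip(present, arr.shape))
    for v in out_vars:
        full_shape.append(dims.get(v, 1))
    return arr.reshape(full_shape)


def _cpt_factor(bn: BayesianNetwork, node: str) -> Factor:
    cpt = bn.cpts[node]
    vars_ = cpt.parent_order + (node,)
    shape = cpt.parent_cards + (cpt.cardinality,)
    return Factor(vars_, cpt.table.reshape(shape))


def _elimination_order(factors: list[Factor], keep: set[str]) -> list[str]:
    """Min-degree order over the interaction graph, ties alphabetical."""
    neighbors: dict[str, set[str]] = {}
    for f in factors:
        for v in f.variables:
            neighbors.setdefault(v, set()).update(u for u in f.variables if u != v)
    to_elim = set(neighbors) - keep
    order = []
    while to_elim:
        v = min(to_elim, key=lambda x: (len(neighbors[x] & to_elim), x))
        order.append(v)
        nbrs = neighbors[v] & to_elim - {v}
        for a in nbrs:
            neighbors[a].update(nbrs - {a})
            neighbors[a].discard(v)
        to_elim.remove(v)
    return order


def _eliminate(factors: list[Factor], order: Sequence[str]) -> Factor:
    factors = list(factors)
    for var in order:
        involved = [f for f in factors if var in f.variables]
        rest = [f for f in factors if var not in f.variables]
        if not involved:
            continue
        prod = involved[0]
        for f in involved[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.marginalize(var)]
    result = factors[0]
    for f in factors[1:]:
        result = result.multiply(f)
    return result


def _evidence_codes(bn: BayesianNetwork, evidence: Mapping[str, str]) -> dict[str, int]:
    codes = {}
    for var, val in evidence.items():
        if var not in bn.cpts:
            raise ValueError(f"evidence variable {var!r} not in network")
        cats = bn.categories(var)
        if str(val) not in cats:
            raise ValueError(f"evidence value {val!r} not a category of {var!r} {cats}")
        codes[var] = cats.index(str(val))
    return codes


def posterior(bn: BayesianNetwork, query: str, evidence: Mapping[str, str] | None = None) -> dict[str, float]:
    """Exact posterior distribution of ``query`` given a partial assignment.

    Evidence values are ordinary categories (an ``Unknown`` label is evidence
    like any other). Raises :class:`InconsistentEvidenceError` when the
    evidence has zero joint probability.
    """
    evidence = dict(evidence or {})
    if query in evidence:
        raise ValueError(f"query {query!r} appears in evidence")
    codes = _evidence_codes(bn, evidence)
    factors = []
    for node in bn.dag.nodes:
        f = _cpt_factor(bn, node)
        for var, idx in codes.items():
            if var in f.variables:
                f = f.reduce(var, idx)
        factors.append(f)
    order = _elimination_order(factors, keep={query})
    result = _eliminate(factors, order)
    if result.variables != (query,):
        # stray scalar factors multiplied in; marginalize anything else out
        for v in result.variables:
            if v != query:
                result = result.marginalize(v)
    total = float(result.values.sum())
    if total <= 0.0:
        raise InconsistentEvidenceError(
            f"evidence {evidence} has zero probability under the network"
        )
    probs = result.values / total
    return dict(zip(bn.categories(query), map(float, probs)))


def joint_distribution(bn: BayesianNetwork, variables: Sequence[str]) -> Factor:
    """Exact joint factor over ``variables`` (all others marginalized out)."""
    keep = set(variables)
    factors = [_cpt_factor(bn, n) for n in bn.dag.nodes]
    order = _elimination_order(factors, keep=keep)
    result = _eliminate(factors, order)
    # normalize axis order to requested order
    out_vars = tuple(variables)
    arr = _expand(result, out_vars)
    return Factor(out_vars, arr.reshape([len(bn.categories(v)) for v in out_vars]))
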