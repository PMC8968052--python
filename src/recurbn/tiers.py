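"""Clinical-timeline tier constraints and the multi-expert consensus protocol.

Variables are ordered into tiers by when they become available in clinical
practice (diagnosis -> neoadjuvant treatment -> surgery -> pathology ->
adjuvant treatment -> follow-up). Arcs may point within a tier or to any
later tier; arcs pointing backward in time are forbidden.

The elicitation protocol is a monotone pipeline of set reductions:
independent proposals from two experts -> intersection -> unanimous review
by two further experts -> final single-expert validation -> DAG build with
cycle and tier checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .bn import DAG, CyclicGraphError

__all__ = [
    "TierMap",
    "TierViolationError",
    "ExpertElicitation",
    "forbidden_arc_set",
    "consensus_intersection",
    "approval_filter",
    "build_expert_dag",
]

Arc = tuple[str, str]


class TierViolationError(ValueError):
    """An arc points from a later tier to an earlier tier."""


@dataclass(frozen=True)
class TierMap:
    """Mapping variable -> tier index along the extraction timeline."""

    tiers: Mapping[str, int]

    def __init__(self, tiers: Mapping[str, int]):
        object.__setattr__(self, "tiers", dict(tiers))
        for v, t in self.tiers.items():
            if not isinstance(t, int) or t < 0:
                raise ValueError(f"tier of {v!r} must be a nonnegative integer, got {t!r}")

    def __contains__(self, var: str) -> bool:
        return var in self.tiers

    def __getitem__(self, var: str) -> int:
        if var not in self.tiers:
            raise KeyError(f"variable {var!r} has no tier assignment")
        return self.tiers[var]

    def variables(self) -> list[str]:
        return list(self.tiers)

    def allows(self, arc: Arc) -> bool:
        """True iff the arc stays within its tier or points forward in time."""
        u, v = arc
        return self[v] >= self[u]


def forbidden_arc_set(tiers: TierMap) -> set[Arc]:
    """All backward-in-time arcs over the tier map's variables.

    Within-tier and forward arcs are absent: they are admissible (subject to
    the global acyclicity check).
    """
    vs = tiers.variables()
    return {
        (u, v)
        for u in vs
        for v in vs
        if u != v and tiers[v] < tiers[u]
    }


def consensus_intersection(arcs_a: Iterable[Arc], arcs_b: Iterable[Arc]) -> set[Arc]:
    """Direction-sensitive intersection of two proposed arc sets."""
    return set(map(tuple, arcs_a)) & set(map(tuple, arcs_b))


def approval_filter(arcs: Iterable[Arc], approvals: Mapping[Arc, tuple[bool, bool]]) -> set[Arc]:
    """Keep only arcs unanimously approved by both reviewers."""
    arcs = set(map(tuple, arcs))
    missing = [a for a in arcs if a not in approvals]
    if missing:
        raise ValueError(f"missing reviewer votes for arcs: {sorted(missing)}")
    out = set()
    for a in arcs:
        votes = approvals[a]
        if len(votes) != 2:
            raise ValueError(f"arc {a} needs exactly two votes, got {len(votes)}")
        if all(votes):
            out.add(a)
    return out


def build_expert_dag(arcs: Iterable[Arc], tiers: TierMap) -> tuple[DAG, list[str]]:
    """Build the consensus DAG from surviving arcs; verify tiers and acyclicity.

    Returns the DAG over the variables incident to at least one arc, plus the
    list of tier-mapped variables excluded because no arc touches them.
    """
    arcs = sorted(set(map(tuple, arcs)))
    for u, v in arcs:
        if u not in tiers or v not in tiers:
            raise KeyError(f"arc ({u!r}, {v!r}) references a variable with no tier")
        if not tiers.allows((u, v)):
            raise TierViolationError(
                f"arc {u!r} (tier {tiers[u]}) -> {v!r} (tier {tiers[v]}) points backward in time"
            )
    used = sorted({u for a in arcs for u in a}, key=lambda v: (tiers[v], v))
    g = nx.DiGraph()
    g.add_nodes_from(used)
    g.add_edges_from(arcs)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise CyclicGraphError(f"expert arcs contain a cycle: {cycle}")
    excluded = [v for v in tiers.variables() if v not in set(used)]
    return DAG(used, arcs), excluded


@dataclass
class ExpertElicitation:
    """Audit record of the consensus protocol.

    Stages run in order: two independent proposals, their intersection, a
    unanimous two-reviewer filter, and a final single-expert validation.
    Each stage's output is a subset of its input.
    """

    proposed_a: set[Arc]
    proposed_b: set[Arc]
    review_votes: Mapping[Arc, tuple[bool, bool]] = field(default_factory=dict)
    final_votes: Mapping[Arc, bool] = field(default_factory=dict)

    def run(self, tiers: TierMap) -> tuple[DAG, list[str], dict[str, set[Arc]]]:
        """Execute the full protocol; returns (dag, excluded, stage trace)."""
        for name, proposal in (("A", self.proposed_a), ("B", self.proposed_b)):
            for arc in proposal:
                if not tiers.allows(arc):
                    raise TierViolationError(
                        f"expert {name} proposed backward-in-time arc {arc}"
                    )
        common = consensus_intersection(self.proposed_a, self.proposed_b)
        reviewed = approval_filter(common, self.review_votes)
        missing = [a for a in reviewed if a not in self.final_votes]
        if missing:
            raise ValueError(f"missing final validation votes for arcs: {sorted(missing)}")
        final = {a for a in reviewed if self.final_votes[a]}
        dag, excluded = build_expert_dag(final, tiers)
        trace = {
            "proposed_a": set(self.proposed_a),
            "proposed_b": set(self.proposed_b),
            "common": common,
            "reviewed": reviewed,
            "final": final,
        }
        return dag, excluded, trace
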