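"""Markov-equivalence utilities: DAG -> CPDAG conversion and Hamming distances.

The CPDAG keeps an edge directed iff it is compelled: v-structure arcs plus
the closure under the Meek orientation rules R1-R3; all other skeleton edges
are undirected.
"""

from __future__ import annotations

from itertools import combinations

from .bn import DAG

__all__ = ["cpdag", "shd", "shd_cpdag"]

Edge = frozenset


def cpdag(dag: DAG) -> tuple[set[tuple[str, str]], set[frozenset]]:
    """Return (directed arcs, undirected edges) of the equivalence class."""
    adj: dict[str, set[str]] = {n: set() for n in dag.nodes}
    for u, v in dag.arcs:
        adj[u].add(v)
        adj[v].add(u)

    directed: set[tuple[str, str]] = set()
    for c in dag.nodes:
        ps = dag.parents(c)
        for a, b in combinations(ps, 2):
            if b not in adj[a]:  # unshielded collider a -> c <- b
                directed.add((a, c))
                directed.add((b, c))

    undirected: set[frozenset] = {
        Edge((u, v)) for u, v in dag.arcs if (u, v) not in directed and (v, u) not in directed
    }
    # arcs sharing a pair with a compelled arc stay as that compelled arc
    undirected = {e for e in undirected if not any((x, y) in directed for x in e for y in e)}

    def orient(u: str, v: str) -> bool:
        e = Edge((u, v))
        if e in undirected:
            undirected.discard(e)
            directed.add((u, v))
            return True
        return False

    changed = True
    while changed:
        changed = False
        for e in list(undirected):
            a, b = tuple(e)
            for u, v in ((a, b), (b, a)):
                # R1: w -> u, w not adjacent to v  =>  u -> v
                if any((w, u) in directed and v not in adj[w] and w != v for w in adj[u]):
                    changed |= orient(u, v)
                    break
                # R2: directed path u -> w -> v  =>  u -> v
                if any((u, w) in directed and (w, v) in directed for w in adj[u] & adj[v]):
                    changed |= orient(u, v)
                    break
                # R3: u - w1 -> v, u - w2 -> v, w1,w2 nonadjacent  =>  u -> v
                ws = [
                    w
                    for w in adj[u] & adj[v]
                    if Edge((u, w)) in undirected and (w, v) in directed
                ]
                if any(w2 not in adj[w1] for w1, w2 in combinations(ws, 2)):
                    changed |= orient(u, v)
                    break
    return directed, undirected


def shd(dag_a: DAG, dag_b: DAG) -> int:
    """Plain structural Hamming distance between two DAGs.

    Additions + deletions + reversals needed to turn A into B (a reversed
    arc counts once).
    """
    a, b = set(dag_a.arcs), set(dag_b.arcs)
    dist = 0
    seen = set()
    for u, v in a | b:
        pair = Edge((u, v))
        if pair in seen:
            continue
        seen.add(pair)
        in_a = (u, v) in a or (v, u) in a
        in_b = (u, v) in b or (v, u) in b
        if in_a != in_b:
            dist += 1
        elif in_a and in_b:
            same = ((u, v) in a) == ((u, v) in b) and ((v, u) in a) == ((v, u) in b)
            if not same:
                dist += 1
    return dist


def shd_cpdag(dag_a: DAG, dag_b: DAG) -> int:
    """SHD between the CPDAGs of two DAGs.

    Each variable pair contributes 1 when its edge differs in presence or in
    type (directed vs. undirected vs. opposite direction).
    """
    da, ua = cpdag(dag_a)
    db, ub = cpdag(dag_b)

    def edge_type(directed, undirected, x, y):
        if (x, y) in directed:
            return ">"
        if (y, x) in directed:
            return "<"
        if Edge((x, y)) in undirected:
            return "-"
        return None

    pairs = {Edge((u, v)) for u, v in da | db} | ua | ub
    dist = 0
    for pair in pairs:
        x, y = sorted(pair)
        if edge_type(da, ua, x, y) != edge_type(db, ub, x, y):
            dist += 1
    return dist
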