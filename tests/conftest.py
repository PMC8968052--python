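"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from recurbn.bn import CPT, DAG, BayesianNetwork


def make_random_bn(rng: np.random.Generator, n_nodes: int, max_card: int = 3, p_arc: float = 0.4) -> BayesianNetwork:
    """Random small network with Dirichlet CPTs (for oracle comparisons)."""
    names = [f"X{i}" for i in range(n_nodes)]
    cards = rng.integers(2, max_card + 1, n_nodes)
    arcs = [
        (names[i], names[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p_arc
    ]
    dag = DAG(names, arcs)
    cpts = {}
    for i, node in enumerate(names):
        parents = dag.parents(node)
        pc = tuple(int(cards[names.index(p)]) for p in parents)
        q = int(np.prod(pc)) if pc else 1
        table = rng.dirichlet(np.ones(cards[i]), size=q)
        cpts[node] = CPT(node, tuple(str(c) for c in range(cards[i])), parents, pc, table)
    return BayesianNetwork(dag, cpts)


def enum_posterior(bn: BayesianNetwork, query: str, evidence: dict[str, str]) -> dict[str, float]:
    """Posterior by explicit full-joint enumeration (independent oracle)."""
    names = list(bn.dag.nodes)
    cats = {n: bn.categories(n) for n in names}
    probs = np.zeros(len(cats[query]))
    ev_codes = {v: cats[v].index(val) for v, val in evidence.items()}
    for combo in itertools.product(*[range(len(cats[n])) for n in names]):
        assign = dict(zip(names, combo))
        if any(assign[v] != c for v, c in ev_codes.items()):
            continue
        p = 1.0
        for n in names:
            cpt = bn.cpts[n]
            idx = cpt.config_index({pp: assign[pp] for pp in cpt.parent_order})
            p *= cpt.table[idx, assign[n]]
        probs[assign[query]] += p
    total = probs.sum()
    return dict(zip(cats[query], probs / total))


def brute_force_auc(probs, labels) -> float:
    """Pairwise concordance count (independent AUC oracle)."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels)
    pos = p[y == 1]
    neg = p[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


@pytest.fixture
def two_node_bn() -> BayesianNetwork:
    """A -> B with P(A=T)=0.3, P(B=T|A=T)=0.9, P(B=T|A=F)=0.2."""
    dag = DAG(["A", "B"], [("A", "B")])
    cpt_a = CPT("A", ("F", "T"), (), (), np.array([[0.7, 0.3]]))
    cpt_b = CPT("B", ("F", "T"), ("A",), (2,), np.array([[0.8, 0.2], [0.1, 0.9]]))
    return BayesianNetwork(dag, {"A": cpt_a, "B": cpt_b})


@pytest.fixture
def toy_cohort() -> pd.DataFrame:
    rng = np.random.default_rng(5)
    n = 200
    a = rng.integers(0, 2, n)
    b = (a + (rng.random(n) < 0.25)) % 2
    return pd.DataFrame(
        {
            "cohort": np.where(np.arange(n) < 120, "c1", "c2"),
            "A": np.where(a == 1, "yes", "no"),
            "B": np.where(b == 1, "yes", "no"),
            "outcome": np.where((b + (rng.random(n) < 0.3)) % 2 == 1, "True", "False"),
        }
    )
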