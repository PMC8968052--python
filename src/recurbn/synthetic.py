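"""Synthetic patient cohorts sampled from a known ground-truth network.

The generator config (see ``data/generator.yaml`` for the documented schema)
declares every variable with its tier, category labels and target marginal,
the tier-valid arc list with per-arc effect strengths, outcome nodes with
prevalence targets, per-variable missingness fractions, and cohort-label
sizes. CPTs are built by exponentially tilting each target marginal by the
parent effects and calibrating offsets so the implied marginals match the
targets exactly; outcome nodes use a logistic CPT with a solved intercept.

Randomness: all sampling flows from one integer seed. Convenience entry
points split it with ``numpy``'s spawning mechanism in a documented order:
child 0 drives ancestral sampling, child 1 drives missingness masking.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .bn import DAG, CPT, BayesianNetwork, ancestral_sample
from .inference import joint_distribution
from .tiers import TierMap, TierViolationError

__all__ = [
    "GeneratorSpec",
    "GroundTruthNetwork",
    "build_ground_truth",
    "sample_cohort",
    "inject_missingness",
    "default_spec",
    "compact_spec",
    "generate_cohort",
]

MISSING = np.nan


class DegenerateSpecError(ValueError):
    """A prevalence or marginal target that makes the spec degenerate."""


@dataclass
class VariableSpec:
    name: str
    tier: int
    categories: tuple[str, ...]
    marginal: tuple[float, ...]

    def __post_init__(self) -> None:
        self.categories = tuple(str(c) for c in self.categories)
        m = np.asarray(self.marginal, dtype=float)
        if len(m) != len(self.categories):
            raise ValueError(f"{self.name}: marginal length != category count")
        if (m <= 0).any():
            raise DegenerateSpecError(f"{self.name}: marginal targets must be strictly positive")
        self.marginal = tuple(m / m.sum())


@dataclass
class OutcomeSpec:
    name: str
    tier: int
    parents: tuple[str, ...]
    prevalence: float
    strength: float = 1.2

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        if not 0.0 < self.prevalence < 1.0:
            raise DegenerateSpecError(
                f"{self.name}: prevalence target must lie strictly in (0, 1), got {self.prevalence}"
            )


@dataclass
class GeneratorSpec:
    """Parsed generator config."""

    variables: list[VariableSpec]
    arcs: list[tuple[str, str, float]]
    outcomes: list[OutcomeSpec]
    missingness: dict[str, float] = field(default_factory=dict)
    cohorts: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorSpec":
        variables = [
            VariableSpec(v["name"], int(v["tier"]), v["categories"], v["marginal"])
            for v in d["variables"]
        ]
        arcs = []
        for a in d.get("arcs", []):
            u, v = str(a[0]), str(a[1])
            strength = float(a[2]) if len(a) > 2 else 0.8
            arcs.append((u, v, strength))
        outcomes = [
            OutcomeSpec(
                o["name"],
                int(o.get("tier", max((v["tier"] for v in d["variables"]), default=0) + 1)),
                o["parents"],
                float(o["prevalence"]),
                float(o.get("strength", 1.2)),
            )
            for o in d.get("outcomes", [])
        ]
        return cls(
            variables=variables,
            arcs=arcs,
            outcomes=outcomes,
            missingness={str(k): float(v) for k, v in (d.get("missingness") or {}).items()},
            cohorts={str(k): int(v) for k, v in (d.get("cohorts") or {}).items()},
        )

    @classmethod
    def from_yaml(cls, path) -> "GeneratorSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def tier_map(self) -> TierMap:
        tiers = {v.name: v.tier for v in self.variables}
        tiers.update({o.name: o.tier for o in self.outcomes})
        return TierMap(tiers)


@dataclass
class GroundTruthNetwork:
    """A fully specified generating network with its tier map and noise plan."""

    network: BayesianNetwork
    tier_map: TierMap
    missingness_rates: dict[str, float]
    outcome_names: list[str]
    seed_used: int

    def __post_init__(self) -> None:
        for (u, v) in self.network.dag.arcs:
            if not self.tier_map.allows((u, v)):
                raise TierViolationError(f"generated arc {u!r} -> {v!r} violates the tier map")
        for var, rate in self.missingness_rates.items():
            if var not in self.network.dag.nodes:
                raise ValueError(f"missingness rate for unknown variable {var!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate for {var!r} outside [0, 1]: {rate}")
        for o in self.outcome_names:
            if len(self.network.categories(o)) != 2:
                raise ValueError(f"outcome {o!r} must be binary")


def _level_scores(m: int) -> np.ndarray:
    """Evenly spaced scores in [-1, 1]; a single level scores 0."""
    return np.linspace(-1.0, 1.0, m) if m > 1 else np.zeros(1)


def _parent_effect(parents: Sequence[str], cards: Sequence[int], strengths: Sequence[float]) -> np.ndarray:
    """Per-parent-config scalar effect: sum of strength * level score."""
    q = int(np.prod(cards)) if cards else 1
    eff = np.zeros(q)
    if not parents:
        return eff
    grids = np.meshgrid(*[_level_scores(c) for c in cards], indexing="ij")
    for g, s in zip(grids, strengths):
        eff += s * g.ravel()
    return eff


def _calibrated_cpt(
    marginal: np.ndarray,
    parent_weights: np.ndarray,
    parent_effect: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-12,
) -> np.ndarray:
    """Tilted CPT whose implied marginal under parent_weights equals marginal.

    Row j is softmax(log marginal + lambda + effect_j * z_child); lambda is
    found by fixed-point matching of the single category margin (an IPF step).
    """
    z = _level_scores(len(marginal))
    log_m = np.log(marginal)
    lam = np.zeros_like(log_m)
    logits_base = log_m[None, :] + parent_effect[:, None] * z[None, :]
    for _ in range(max_iter):
        logits = logits_base + lam[None, :]
        logits -= logits.max(axis=1, keepdims=True)
        rows = np.exp(logits)
        rows /= rows.sum(axis=1, keepdims=True)
        current = parent_weights @ rows
        if np.max(np.abs(current - marginal)) < tol:
            break
        lam += log_m - np.log(current)
    return rows


def build_ground_truth(spec: GeneratorSpec, seed: int = 0) -> GroundTruthNetwork:
    """Construct the generating network from a generator spec.

    The construction is deterministic given the spec; ``seed`` is recorded
    for provenance and used by downstream convenience samplers.
    """
    tier_map = spec.tier_map()
    var_by_name = {v.name: v for v in spec.variables}
    for (u, v, _s) in spec.arcs:
        if u not in tier_map or v not in tier_map:
            raise KeyError(f"arc ({u!r}, {v!r}) references an undeclared variable")
        if not tier_map.allows((u, v)):
            raise TierViolationError(
                f"spec arc {u!r} (tier {tier_map[u]}) -> {v!r} (tier {tier_map[v]}) points backward in time"
            )

    predictor_dag = DAG([v.name for v in spec.variables], [(u, v) for (u, v, _s) in spec.arcs])
    strength_of = {(u, v): s for (u, v, s) in spec.arcs}

    cpts: dict[str, CPT] = {}
    built: list[str] = []
    for node in predictor_dag.topological_order():
        vs = var_by_name[node]
        parents = predictor_dag.parents(node)
        cards = tuple(len(var_by_name[p].categories) for p in parents)
        marginal = np.asarray(vs.marginal)
        if not parents:
            table = marginal[None, :]
        else:
            done = set(built)
            partial = BayesianNetwork(
                DAG(
                    [n for n in predictor_dag.nodes if n in done],
                    [(u, v) for (u, v) in predictor_dag.arcs if v in done],
                ),
                {n: cpts[n] for n in built},
            )
            w = joint_distribution(partial, parents).values.ravel()
            eff = _parent_effect(parents, cards, [strength_of[(p, node)] for p in parents])
            table = _calibrated_cpt(marginal, w, eff)
        cpts[node] = CPT(node, vs.categories, parents, cards, table)
        built.append(node)

    predictor_bn = BayesianNetwork(predictor_dag, cpts)

    all_nodes = list(predictor_dag.nodes)
    all_arcs = [(u, v) for (u, v, _s) in spec.arcs]
    out_cpts = dict(cpts)
    for o in spec.outcomes:
        for p in o.parents:
            if p not in var_by_name:
                raise KeyError(f"outcome {o.name!r} parent {p!r} is not a declared variable")
            if not tier_map.allows((p, o.name)):
                raise TierViolationError(f"outcome arc {p!r} -> {o.name!r} violates the tier map")
        cards = tuple(len(var_by_name[p].categories) for p in o.parents)
        w = joint_distribution(predictor_bn, o.parents).values.ravel()
        eta = _parent_effect(o.parents, cards, [o.strength] * len(o.parents))

        def marginal_gap(b: float) -> float:
            return float(w @ expit(b + eta)) - o.prevalence

        intercept = brentq(marginal_gap, -30.0, 30.0, xtol=1e-12)
        p_true = expit(intercept + eta)
        table = np.column_stack([1.0 - p_true, p_true])
        out_cpts[o.name] = CPT(o.name, ("False", "True"), o.parents, cards, table)
        all_nodes.append(o.name)
        all_arcs.extend((p, o.name) for p in o.parents)

    network = BayesianNetwork(DAG(all_nodes, all_arcs), out_cpts)
    return GroundTruthNetwork(
        network=network,
        tier_map=tier_map,
        missingness_rates=dict(spec.missingness),
        outcome_names=[o.name for o in spec.outcomes],
        seed_used=int(seed),
    )


def sample_cohort(
    gt: GroundTruthNetwork,
    n: int,
    seed: int,
    cohort_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Draw ``n`` complete rows; adds a ``cohort`` label column.

    When ``cohort_sizes`` is given its values must sum to ``n`` and label
    blocks are assigned in key order; otherwise a single label is used.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    df = ancestral_sample(gt.network, n, seed)
    if cohort_sizes:
        total = sum(cohort_sizes.values())
        if total != n:
            raise ValueError(f"cohort sizes sum to {total}, expected {n}")
        labels = np.repeat(list(cohort_sizes.keys()), list(cohort_sizes.values()))
    else:
        labels = np.repeat("cohort_01", n)
    df.insert(0, "cohort", labels)
    return df


def inject_missingness(
    cohort: pd.DataFrame,
    rates: Mapping[str, float],
    seed: int,
) -> pd.DataFrame:
    """Mask values completely at random, per variable at the given rate."""
    for var, rate in rates.items():
        if var not in cohort.columns:
            raise ValueError(f"missingness rate given for absent column {var!r}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {var!r} outside [0, 1]: {rate}")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    # iterate in column order for seed-stable masking
    for var in cohort.columns:
        rate = rates.get(var)
        if not rate:
            continue
        mask = rng.random(len(out)) < rate
        col = out[var].astype(object)
        col[mask] = MISSING
        out[var] = col
    return out


def _load_packaged(name: str) -> GeneratorSpec:
    ref = importlib.resources.files("recurbn.data").joinpath(name)
    return GeneratorSpec.from_dict(yaml.safe_load(ref.read_text()))


def default_spec() -> GeneratorSpec:
    """Full study-like generator (13 predictors + 3 outcome endpoints)."""
    return _load_packaged("generator.yaml")


def compact_spec() -> GeneratorSpec:
    """Compact all-binary 10-node ground truth for structure recovery."""
    return _load_packaged("compact10.yaml")


def generate_cohort(spec: GeneratorSpec, seed: int, n: int | None = None) -> pd.DataFrame:
    """Build the ground truth, sample it, and apply missingness.

    Seed split order: child 0 -> ancestral sampling, child 1 -> missingness.
    """
    gt = build_ground_truth(spec, seed)
    root = np.random.default_rng(seed)
    sample_seed, missing_seed = [int(s.integers(2**31 - 1)) for s in root.spawn(2)]
    sizes = spec.cohorts or None
    if n is None:
        n = sum(spec.cohorts.values()) if spec.cohorts else 1000
        cohort_sizes = sizes
    else:
        cohort_sizes = sizes if sizes and sum(sizes.values()) == n else None
    df = sample_cohort(gt, n, sample_seed, cohort_sizes)
    if spec.missingness:
        df = inject_missingness(df, spec.missingness, missing_seed)
    return df
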