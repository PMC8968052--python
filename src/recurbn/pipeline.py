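"""End-to-end experiment: cohort -> preprocess -> both structures -> comparison.

For each recurrence endpoint the pipeline drops missing-outcome rows,
encodes predictor missingness as ``Unknown``, rebalances the training
partition with categorical SMOTE, fits the expert-consensus network and a
BIC hill-climbing network (tier blacklist enforced), and evaluates both on
the original training rows and the held-out validation rows.

All randomness derives from one experiment seed, split in documented order:
child 0 -> train/validation split, then per endpoint children
(1 + 3*i .. 3 + 3*i) -> SMOTE, hill climbing, calibration bootstrap.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bn import BayesianNetwork, DAG, fit_parameters
from .evaluate import (
    CalibrationCurve,
    EvaluationReport,
    StructureDiff,
    calibration,
    compare_auc,
    predict_cohort,
    structure_diff,
)
from .preprocess import (
    DEFAULT_RULES,
    UNKNOWN,
    CategorizationRules,
    categorize,
    encode_missing_and_filter,
    smote_categorical,
    stratified_split,
)
from .structure import hill_climb
from .synthetic import GeneratorSpec, default_spec, generate_cohort
from .tiers import TierMap, build_expert_dag, forbidden_arc_set

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ReportBundle", "run_experiment", "load_default_tiers", "load_default_expert_arcs"]


def load_default_tiers() -> TierMap:
    ref = importlib.resources.files("recurbn.data").joinpath("tiers.yaml")
    return TierMap(yaml.safe_load(ref.read_text())["tiers"])


def load_default_expert_arcs() -> list[tuple[str, str]]:
    ref = importlib.resources.files("recurbn.data").joinpath("expert_arcs.yaml")
    return [tuple(a) for a in yaml.safe_load(ref.read_text())["arcs"]]


@dataclass
class ExperimentConfig:
    """One config drives the whole comparison; CLI flags override scalars."""

    csv_path: str | None = None  # when None, generate synthetically
    generator: GeneratorSpec | None = None  # defaults to the packaged spec
    tiers: TierMap | None = None
    expert_arcs: list[tuple[str, str]] | None = None
    outcomes: list[str] = field(default_factory=lambda: ["recurrence_2y", "recurrence_3y", "recurrence_5y"])
    rules: CategorizationRules = field(default_factory=lambda: DEFAULT_RULES)
    test_fraction: float = 0.2
    smote_k: int = 5
    smote_enabled: bool = True
    hc_restarts: int = 5
    hc_perturb: int = 5
    threshold: float = 0.5
    calibration_bins: int = 10
    calibration_boot: int = 200
    train_metrics_on_smote: bool = False
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.tiers is None:
            self.tiers = load_default_tiers()
        if self.expert_arcs is None:
            self.expert_arcs = load_default_expert_arcs()
        if self.generator is None and self.csv_path is None:
            self.generator = default_spec()

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        data = d.get("data", {})
        kwargs["csv_path"] = data.get("csv")
        if data.get("generator"):
            kwargs["generator"] = GeneratorSpec.from_yaml(data["generator"])
        if d.get("tiers"):
            kwargs["tiers"] = TierMap(yaml.safe_load(Path(d["tiers"]).read_text())["tiers"])
        if d.get("expert_arcs"):
            kwargs["expert_arcs"] = [tuple(a) for a in yaml.safe_load(Path(d["expert_arcs"]).read_text())["arcs"]]
        if d.get("rules"):
            kwargs["rules"] = CategorizationRules.from_dict(d["rules"])
        for key in (
            "outcomes", "test_fraction", "smote_k", "smote_enabled", "hc_restarts",
            "hc_perturb", "threshold", "calibration_bins", "calibration_boot",
            "train_metrics_on_smote", "seed", "output_dir",
        ):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)

    def fingerprint(self) -> str:
        payload = {
            "csv": self.csv_path,
            "outcomes": self.outcomes,
            "test_fraction": self.test_fraction,
            "smote_k": self.smote_k,
            "smote_enabled": self.smote_enabled,
            "hc": [self.hc_restarts, self.hc_perturb],
            "threshold": self.threshold,
            "seed": self.seed,
            "expert_arcs": sorted(map(list, self.expert_arcs)),
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    config_fingerprint: str
    seed: int
    report: EvaluationReport
    auc_comparisons: dict[str, dict[str, float]]
    diffs: dict[str, StructureDiff]
    calibrations: dict[tuple[str, str, str], CalibrationCurve]
    networks: dict[tuple[str, str], BayesianNetwork]
    dags: dict[tuple[str, str], DAG]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frame = self.report.to_frame()
        frame.to_csv(outdir / "metrics.csv", index=False)
        with open(outdir / "metrics.json", "w") as fh:
            json.dump(
                {
                    "config_fingerprint": self.config_fingerprint,
                    "seed": self.seed,
                    "metrics": self.report.rows,
                    "auc_comparisons": self.auc_comparisons,
                },
                fh,
                indent=1,
            )
        for tp, diff in self.diffs.items():
            (outdir / f"structure_diff_{tp}.txt").write_text(diff.summary() + "\n")
        for (tp, structure, ds), curve in self.calibrations.items():
            curve.to_frame().to_csv(outdir / f"calibration_{tp}_{structure}_{ds}.csv", index=False)
        for (tp, structure), bn in self.networks.items():
            bn.to_json(outdir / f"network_{tp}_{structure}.json")
            arcs = pd.DataFrame(sorted(bn.dag.arcs), columns=["parent", "child"])
            arcs.to_csv(outdir / f"arcs_{tp}_{structure}.tsv", sep="\t", index=False)
        logger.info("wrote report bundle to %s", outdir)


def _bind_outcome(arcs: list[tuple[str, str]], outcome: str) -> list[tuple[str, str]]:
    return [(u if u != "outcome" else outcome, v if v != "outcome" else outcome) for (u, v) in arcs]


def _category_sets(train: pd.DataFrame, val: pd.DataFrame, predictors, outcome: str) -> dict:
    cats = {}
    for c in predictors:
        observed = set(map(str, train[c])) | set(map(str, val[c])) | {UNKNOWN}
        cats[c] = tuple(sorted(observed))
    cats[outcome] = ("False", "True")
    return cats


def run_experiment(config: ExperimentConfig) -> ReportBundle:
    """Execute the full per-endpoint comparison; deterministic per config."""
    rng_children = np.random.default_rng(config.seed).spawn(1 + 3 * len(config.outcomes))
    seeds = [int(c.integers(2**31 - 1)) for c in rng_children]
    split_seed, endpoint_seeds = seeds[0], seeds[1:]

    if config.csv_path is not None:
        cohort = pd.read_csv(config.csv_path, dtype=str)
        cohort = cohort.replace("", np.nan)
    else:
        cohort = generate_cohort(config.generator, config.seed)
    cohort = categorize(cohort, config.rules)
    logger.info("cohort loaded: %d rows, %d columns", *cohort.shape)

    tiers: TierMap = config.tiers
    for outcome in config.outcomes:
        if outcome not in cohort.columns:
            raise ValueError(f"configured outcome {outcome!r} not in cohort columns")

    train_raw, val_raw = stratified_split(cohort, config.test_fraction, seed=split_seed)

    predictors = [c for c in cohort.columns if c != "cohort" and c not in config.outcomes]
    report = EvaluationReport()
    diffs: dict[str, StructureDiff] = {}
    calibrations: dict[tuple[str, str, str], CalibrationCurve] = {}
    networks: dict[tuple[str, str], BayesianNetwork] = {}
    dags: dict[tuple[str, str], DAG] = {}
    auc_comparisons: dict[str, dict[str, float]] = {}

    for i, outcome in enumerate(config.outcomes):
        smote_seed, hc_seed, cal_seed = endpoint_seeds[3 * i : 3 * i + 3]
        tier_dict = dict(tiers.tiers)
        tier_dict[outcome] = tier_dict.get("outcome", max(tier_dict.values()) + 1)
        bound_tiers = TierMap({k: v for k, v in tier_dict.items() if k != "outcome"})

        train = encode_missing_and_filter(train_raw, outcome, predictors)
        val = encode_missing_and_filter(val_raw, outcome, predictors)
        cats = _category_sets(train, val, predictors, outcome)

        fit_train = train
        if config.smote_enabled:
            fit_train = smote_categorical(train, outcome, k=config.smote_k, seed=smote_seed, feature_columns=predictors)

        # expert structure
        expert_dag, excluded = build_expert_dag(_bind_outcome(config.expert_arcs, outcome), bound_tiers)
        logger.info("%s: expert DAG %d arcs / %d variables (excluded: %s)", outcome, len(expert_dag.arcs), len(expert_dag.nodes), excluded)
        expert_bn = fit_parameters(expert_dag, fit_train, alpha=1.0, categories={n: cats[n] for n in expert_dag.nodes})

        # algorithmic structure (tier blacklist supplied)
        hc_nodes = predictors + [outcome]
        forbidden = {a for a in forbidden_arc_set(bound_tiers) if a[0] in hc_nodes and a[1] in hc_nodes}
        learned_dag = hill_climb(
            fit_train[hc_nodes], nodes=hc_nodes, forbidden=forbidden,
            restarts=config.hc_restarts, perturb=config.hc_perturb, seed=hc_seed,
        )
        learned_bn = fit_parameters(learned_dag, fit_train, alpha=1.0, categories=cats)

        networks[(outcome, "expert")] = expert_bn
        networks[(outcome, "algorithm")] = learned_bn
        dags[(outcome, "expert")] = expert_dag
        dags[(outcome, "algorithm")] = learned_dag
        diffs[outcome] = structure_diff(expert_dag, learned_dag, outcome)

        eval_train = fit_train if config.train_metrics_on_smote else train
        datasets = {"training": eval_train, "validation": val}
        probs: dict[tuple[str, str], np.ndarray] = {}
        for ds_name, ds in datasets.items():
            for s_name, bn in (("expert", expert_bn), ("algorithm", learned_bn)):
                p = predict_cohort(bn, ds, outcome)
                probs[(s_name, ds_name)] = p
                report.add(outcome, s_name, ds_name, p, ds[outcome], threshold=config.threshold)
                calibrations[(outcome, s_name, ds_name)] = calibration(
                    p, ds[outcome], bins=config.calibration_bins,
                    boot=config.calibration_boot, seed=cal_seed,
                )
        auc_comparisons[outcome] = {
            ds_name: compare_auc(probs[("expert", ds_name)], probs[("algorithm", ds_name)], datasets[ds_name][outcome])
            for ds_name in datasets
        }

    bundle = ReportBundle(
        config_fingerprint=config.fingerprint(),
        seed=config.seed,
        report=report,
        auc_comparisons=auc_comparisons,
        diffs=diffs,
        calibrations=calibrations,
        networks=networks,
        dags=dags,
    )
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle
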