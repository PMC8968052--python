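"""Model evaluation: risk prediction, discrimination, calibration, structure diff.

AUC uses the Mann-Whitney formulation (concordant pairs plus half ties);
confidence intervals and the paired AUC-difference test use DeLong's
variance components. Calibration uses equal-count bins with bootstrap
percentile intervals and optimism-corrected ("bias-corrected") estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .bn import BayesianNetwork, DAG
from .cpdag import shd
from .inference import posterior

logger = logging.getLogger(__name__)

__all__ = [
    "predict_cohort",
    "roc_auc",
    "auc_confidence_interval",
    "compare_auc",
    "confusion_metrics",
    "calibration",
    "CalibrationCurve",
    "structure_diff",
    "StructureDiff",
    "EvaluationReport",
]


# ----------------------------------------------------------------------
# prediction
# ----------------------------------------------------------------------

def _codes_or_raise(table: pd.DataFrame, column: str, categories) -> np.ndarray:
    codes = pd.Categorical(table[column], categories=list(categories)).codes
    if (codes < 0).any():
        row = int(np.nonzero(codes < 0)[0][0])
        raise ValueError(
            f"row {table.index[row]}: value {table[column].iloc[row]!r} of variable "
            f"{column!r} is not a category of the network ({list(categories)})"
        )
    return codes.astype(np.int64)


def predict_cohort(
    bn: BayesianNetwork,
    table: pd.DataFrame,
    outcome: str,
    positive: str = "True",
) -> np.ndarray:
    """Per-row posterior probability of ``outcome == positive``.

    Every non-outcome network variable must be present in ``table``; its
    value (including an ``Unknown`` label) is supplied as evidence. With
    complete evidence only the outcome's Markov-blanket factors matter, so
    the computation vectorizes over rows.
    """
    predictors = [n for n in bn.dag.nodes if n != outcome]
    missing = [n for n in predictors if n not in table.columns]
    if missing:
        raise ValueError(f"table lacks network variables: {missing}")
    cats = bn.categories(outcome)
    if positive not in cats:
        raise ValueError(f"positive label {positive!r} not a category of {outcome!r}")
    codes = {p: _codes_or_raise(table, p, bn.categories(p)) for p in predictors}

    r = len(cats)
    n = len(table)
    log_p = np.zeros((n, r))

    out_cpt = bn.cpts[outcome]
    idx = np.zeros(n, dtype=np.int64)
    for p, card in zip(out_cpt.parent_order, out_cpt.parent_cards):
        idx = idx * card + codes[p]
    with np.errstate(divide="ignore"):
        log_p += np.log(out_cpt.table[idx, :])

    for child in bn.dag.children(outcome):
        cpt = bn.cpts[child]
        for s in range(r):
            idx = np.zeros(n, dtype=np.int64)
            for p, card in zip(cpt.parent_order, cpt.parent_cards):
                idx = idx * card + (np.full(n, s, dtype=np.int64) if p == outcome else codes[p])
            with np.errstate(divide="ignore"):
                log_p[:, s] += np.log(cpt.table[idx, codes[child]])

    log_p -= log_p.max(axis=1, keepdims=True)
    probs = np.exp(log_p)
    totals = probs.sum(axis=1)
    if (totals <= 0).any() or not np.isfinite(totals).all():
        # zero-probability evidence under an ML-fit model: fall back to exact VE
        bad = np.nonzero(~np.isfinite(totals) | (totals <= 0))[0]
        for i in bad:
            ev = {p: str(table[p].iloc[i]) for p in predictors}
            probs[i] = [posterior(bn, outcome, ev)[c] for c in cats]
            totals[i] = 1.0
    return probs[:, cats.index(positive)] / totals


# ----------------------------------------------------------------------
# discrimination
# ----------------------------------------------------------------------

def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "OUSb":
        y = np.isin(y, ["True", "1", "true", True]).astype(int)
    else:
        y = (y > 0).astype(int)
    return y


def roc_auc(probs, labels) -> float:
    """Mann-Whitney AUC: P(score of random positive > random negative) + half ties."""
    y = _as_binary(labels)
    p = np.asarray(probs, dtype=float)
    m = int(y.sum())
    n = len(y) - m
    if m == 0 or n == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - m * (m + 1) / 2) / (m * n))


def _delong_components(probs: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus DeLong structural components (per positive, per negative)."""
    pos = probs[y == 1]
    neg = probs[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    v01 = (all_ranks[:m] - rankdata(pos)) / n  # per positive case
    v10 = 1.0 - (all_ranks[m:] - rankdata(neg)) / m  # per negative case
    auc = float(v01.mean())
    return auc, v01, v10


def auc_confidence_interval(probs, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong variance-based Wald interval for the AUC, clipped to [0, 1]."""
    y = _as_binary(labels)
    p = np.asarray(probs, dtype=float)
    m, n = int(y.sum()), int((1 - y).sum())
    if m < 2 or n < 2:
        raise ValueError("need at least two members of each class")
    auc, v01, v10 = _delong_components(p, y)
    var = v01.var(ddof=1) / m + v10.var(ddof=1) / n
    z = norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def compare_auc(probs_a, probs_b, labels) -> float:
    """Two-sided paired DeLong test for equality of two correlated AUCs."""
    pa = np.asarray(probs_a, dtype=float)
    pb = np.asarray(probs_b, dtype=float)
    y = _as_binary(labels)
    if len(pa) != len(pb) or len(pa) != len(y):
        raise ValueError("prediction vectors and labels must have equal length")
    auc_a, v01_a, v10_a = _delong_components(pa, y)
    auc_b, v01_b, v10_b = _delong_components(pb, y)
    m, n = len(v01_a), len(v10_a)
    var = (
        v01_a.var(ddof=1) / m + v01_b.var(ddof=1) / m
        - 2 * np.cov(v01_a, v01_b, ddof=1)[0, 1] / m
        + v10_a.var(ddof=1) / n + v10_b.var(ddof=1) / n
        - 2 * np.cov(v10_a, v10_b, ddof=1)[0, 1] / n
    )
    if var <= 0:
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2 * norm.sf(abs(z)))


def confusion_metrics(probs, labels, threshold: float = 0.5) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) at a probability cut.

    A row is called positive when its probability is >= threshold. With a
    single-class input the undefined rate is returned as NaN with a warning.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    y = _as_binary(labels)
    pred = (np.asarray(probs, dtype=float) >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    m, n = int(y.sum()), int((1 - y).sum())
    accuracy = (tp + tn) / len(y)
    sensitivity = tp / m if m else float("nan")
    specificity = tn / n if n else float("nan")
    if m == 0 or n == 0:
        logger.warning("confusion_metrics: single-class labels; some rates undefined")
    return float(accuracy), float(sensitivity), float(specificity)


# ----------------------------------------------------------------------
# calibration
# ----------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """Equal-count-bin calibration summary with bootstrap uncertainty."""

    mean_predicted: np.ndarray
    observed: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    bias_corrected: np.ndarray
    bins: int
    bootstrap: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_predicted": self.mean_predicted,
                "observed": self.observed,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "bias_corrected": self.bias_corrected,
            }
        )


def _bin_stats(p: np.ndarray, y: np.ndarray, edges: np.ndarray, bins: int):
    which = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, bins - 1)
    pred = np.full(bins, np.nan)
    obs = np.full(bins, np.nan)
    for b in range(bins):
        mask = which == b
        if mask.any():
            pred[b] = p[mask].mean()
            obs[b] = y[mask].mean()
    return pred, obs


def calibration(
    probs,
    labels,
    bins: int = 10,
    boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
) -> CalibrationCurve:
    """Calibration curve over equal-count probability bins.

    Per bin: mean predicted probability and observed event frequency, a
    bootstrap percentile interval, and an optimism-corrected estimate
    ``2 * apparent - mean(bootstrap)``.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if boot < 0:
        raise ValueError("boot must be >= 0")
    p = np.asarray(probs, dtype=float)
    y = _as_binary(labels)
    if len(p) < bins:
        raise ValueError(f"need at least {bins} rows for {bins} bins, got {len(p)}")
    # equal-count edges from the observed probability quantiles; heavy ties
    # collapse duplicate edges into fewer effective bins
    edges = np.unique(np.quantile(p, np.linspace(0, 1, bins + 1)))
    n_bins = max(len(edges) - 1, 1)
    edges = np.concatenate([[-np.inf], edges[1:-1], [np.inf]])
    pred, obs = _bin_stats(p, y, edges, n_bins)

    if boot == 0:
        return CalibrationCurve(pred, obs, obs.copy(), obs.copy(), obs.copy(), n_bins, 0)

    rng = np.random.default_rng(seed)
    boot_obs = np.full((boot, n_bins), np.nan)
    for b in range(boot):
        idx = rng.integers(0, len(p), size=len(p))
        _, boot_obs[b] = _bin_stats(p[idx], y[idx], edges, n_bins)
    alpha = (1 - level) / 2
    with warnings.catch_warnings():
        # a bootstrap replicate can leave a sparse bin empty; NaN-aware
        # aggregation over replicates is intended
        warnings.simplefilter("ignore", RuntimeWarning)
        ci_low = np.nanquantile(boot_obs, alpha, axis=0)
        ci_high = np.nanquantile(boot_obs, 1 - alpha, axis=0)
        bias_corrected = 2 * obs - np.nanmean(boot_obs, axis=0)
    return CalibrationCurve(pred, obs, ci_low, ci_high, bias_corrected, n_bins, boot)


# ----------------------------------------------------------------------
# structural comparison
# ----------------------------------------------------------------------

@dataclass
class StructureDiff:
    only_a: set[tuple[str, str]]
    only_b: set[tuple[str, str]]
    shared: set[tuple[str, str]]
    reversed_arcs: set[tuple[str, str]]  # orientation from A
    shd: int
    outcome_parents_a: tuple[str, ...] = ()
    outcome_children_a: tuple[str, ...] = ()
    outcome_parents_b: tuple[str, ...] = ()
    outcome_children_b: tuple[str, ...] = ()

    def summary(self) -> str:
        lines = [
            f"SHD: {self.shd}",
            f"shared (same direction): {sorted(self.shared)}",
            f"reversed: {sorted(self.reversed_arcs)}",
            f"only in A: {sorted(self.only_a)}",
            f"only in B: {sorted(self.only_b)}",
            f"outcome parents A: {list(self.outcome_parents_a)}; children A: {list(self.outcome_children_a)}",
            f"outcome parents B: {list(self.outcome_parents_b)}; children B: {list(self.outcome_children_b)}",
        ]
        return "\n".join(lines)


def structure_diff(dag_a: DAG, dag_b: DAG, outcome: str | None = None) -> StructureDiff:
    """Exact arc-level comparison of two DAGs over the union of their nodes."""
    a, b = set(dag_a.arcs), set(dag_b.arcs)
    shared = a & b
    reversed_arcs = {(u, v) for (u, v) in a if (v, u) in b}
    only_a = a - shared - reversed_arcs
    only_b = b - shared - {(v, u) for (u, v) in reversed_arcs}
    diff = StructureDiff(
        only_a=only_a,
        only_b=only_b,
        shared=shared,
        reversed_arcs=reversed_arcs,
        shd=shd(dag_a, dag_b),
    )
    if outcome is not None:
        if outcome in dag_a.nodes:
            diff.outcome_parents_a = dag_a.parents(outcome)
            diff.outcome_children_a = dag_a.children(outcome)
        if outcome in dag_b.nodes:
            diff.outcome_parents_b = dag_b.parents(outcome)
            diff.outcome_children_b = dag_b.children(outcome)
    return diff


# ----------------------------------------------------------------------
# report container
# ----------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per time point / structure / dataset metric rows (Table-style layout)."""

    rows: list[dict] = field(default_factory=list)

    def add(
        self,
        time_point: str,
        structure: str,
        dataset: str,
        probs,
        labels,
        threshold: float = 0.5,
    ) -> dict:
        auc = roc_auc(probs, labels)
        lo, hi = auc_confidence_interval(probs, labels)
        acc, sens, spec = confusion_metrics(probs, labels, threshold)
        row = {
            "time_point": time_point,
            "structure": structure,
            "dataset": dataset,
            "n": len(labels),
            "accuracy": acc,
            "auc": auc,
            "auc_ci_low": lo,
            "auc_ci_high": hi,
            "sensitivity": sens,
            "specificity": spec,
            "threshold": threshold,
        }
        self.rows.append(row)
        return row

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)
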