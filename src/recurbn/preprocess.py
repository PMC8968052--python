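"""Cohort preprocessing: categorize, encode missingness, filter, split, rebalance.

The analysis table convention: one pandas row per patient, a ``cohort`` label
column, categorical predictor columns, and optional binary outcome columns
(``"True"``/``"False"``). Missing values are ``NaN`` until
:func:`encode_missing_and_filter` turns predictor missingness into the
first-class category ``"Unknown"`` and drops rows whose outcome is missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "UNKNOWN",
    "CategorizationRules",
    "DEFAULT_RULES",
    "dichotomize_crm",
    "categorize",
    "encode_missing_and_filter",
    "stratified_split",
    "smote_categorical",
]

UNKNOWN = "Unknown"


def dichotomize_crm(margin_mm: float) -> str:
    """Dichotomize a circumferential resection margin distance.

    Positive iff the tumor lies within 1 mm of the margin (boundary
    included), Negative beyond 1 mm.
    """
    if margin_mm < 0:
        raise ValueError(f"margin distance must be nonnegative, got {margin_mm}")
    return "Positive" if margin_mm <= 1.0 else "Negative"


@dataclass
class BinRule:
    """Ordered cut points and labels for one continuous variable.

    ``len(labels) == len(cuts) + 1``; value v falls in bin i where
    ``cuts[i-1] < v <= cuts[i]`` (left-open, right-closed).
    """

    cuts: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.cuts = tuple(float(c) for c in self.cuts)
        self.labels = tuple(str(l) for l in self.labels)
        if list(self.cuts) != sorted(set(self.cuts)):
            raise ValueError("cut points must be strictly increasing")
        if len(self.labels) != len(self.cuts) + 1:
            raise ValueError("need exactly one more label than cut points")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("bin labels must be unique")

    def apply(self, value: float) -> str:
        for cut, label in zip(self.cuts, self.labels):
            if value <= cut:
                return label
        return self.labels[-1]


@dataclass
class CategorizationRules:
    """Per-variable binning rules plus the CRM distance threshold."""

    bins: dict[str, BinRule] = field(default_factory=dict)
    crm_column: str | None = None

    @classmethod
    def from_dict(cls, d: Mapping) -> "CategorizationRules":
        bins = {
            name: BinRule(tuple(r["cuts"]), tuple(r["labels"]))
            for name, r in (d.get("bins") or {}).items()
        }
        return cls(bins=bins, crm_column=d.get("crm_column"))


# Default cuts are configuration, not reconstructions of any published rule:
# age <50 / 50-65 / >65 y; dose <=45 / >45 Gy; distance <=5 / >5 cm;
# treatment time <=38 / >38 d; RT-surgery interval <=1 / >1 wk.
DEFAULT_RULES = CategorizationRules(
    bins={
        "age": BinRule((49.999, 65), ("<50", "50-65", ">65")),
        "rt_dose": BinRule((45,), ("<=45Gy", ">45Gy")),
        "tumor_distance": BinRule((5,), ("<=5cm", ">5cm")),
        "overall_treatment_time": BinRule((38,), ("<=38d", ">38d")),
        "rt_surgery_interval": BinRule((1,), ("<=1wk", ">1wk")),
    },
    crm_column="crm_margin_mm",
)


def categorize(cohort: pd.DataFrame, rules: CategorizationRules) -> pd.DataFrame:
    """Map continuous columns to category labels; idempotent on labels.

    Missing values stay missing. Values outside the rule range land in the
    nearest terminal bin (the rule's apply is total), logged when the column
    is numeric. Columns without a rule pass through unchanged.
    """
    out = cohort.copy()
    if rules.crm_column and rules.crm_column in out.columns:
        vals = out[rules.crm_column]
        out["crm"] = [
            np.nan if pd.isna(v) else dichotomize_crm(float(v)) for v in vals
        ]
        out = out.drop(columns=[rules.crm_column])
    for name, rule in rules.bins.items():
        if name not in out.columns:
            continue
        col = out[name]
        mapped = []
        n_converted = 0
        for v in col:
            if pd.isna(v):
                mapped.append(np.nan)
                continue
            if isinstance(v, str):
                try:
                    num = float(v)
                except ValueError:
                    mapped.append(v)  # already categorical: idempotent
                    continue
            else:
                num = float(v)
            mapped.append(rule.apply(num))
            n_converted += 1
        if n_converted:
            logger.info("categorize: %s -> %d values binned", name, n_converted)
        out[name] = mapped
    return out


def encode_missing_and_filter(
    cohort: pd.DataFrame,
    outcome: str,
    predictor_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Replace predictor missingness by ``"Unknown"``; drop missing-outcome rows."""
    if outcome not in cohort.columns:
        raise ValueError(f"outcome column {outcome!r} not present")
    keep = cohort[outcome].notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("encode_missing_and_filter: dropped %d rows with missing %r", dropped, outcome)
    out = cohort[keep].copy()
    if predictor_columns is None:
        predictor_columns = [c for c in out.columns if c not in ("cohort", outcome)]
    for c in predictor_columns:
        out[c] = out[c].astype(object).where(out[c].notna(), UNKNOWN)
    return out.reset_index(drop=True)


def stratified_split(
    cohort: pd.DataFrame,
    test_fraction: float = 0.2,
    stratify_key: str = "cohort",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/validation partition, stratified per cohort label.

    Within each label, ``round(n * test_fraction)`` rows go to validation.
    Labels with a single row go entirely to training (warned).
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    val_idx: list[np.ndarray] = []
    key = cohort[stratify_key] if stratify_key in cohort.columns else pd.Series("all", index=cohort.index)
    for label in sorted(key.unique()):
        idx = cohort.index[key == label].to_numpy()
        if len(idx) < 2:
            logger.warning("stratified_split: cohort %r has <2 rows; all to train", label)
            continue
        n_val = int(round(len(idx) * test_fraction))
        chosen = rng.choice(idx, size=n_val, replace=False)
        val_idx.append(chosen)
    val = np.sort(np.concatenate(val_idx)) if val_idx else np.array([], dtype=int)
    val_mask = cohort.index.isin(val)
    train = cohort[~val_mask].reset_index(drop=True)
    validation = cohort[val_mask].reset_index(drop=True)
    logger.info(
        "stratified_split: %d train / %d validation", len(train), len(validation)
    )
    return train, validation


def smote_categorical(
    train: pd.DataFrame,
    outcome: str,
    k: int = 5,
    seed: int = 0,
    feature_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Balance classes by synthesizing minority rows from nominal neighbours.

    An all-nominal SMOTE: each synthetic row takes, per feature, the majority
    value among a randomly chosen minority seed row and its ``k`` nearest
    minority neighbours under Hamming distance, ties broken by the seed
    row's value. Original rows are returned unchanged, synthetic rows are
    appended until both classes have equal counts.
    """
    if outcome not in train.columns:
        raise ValueError(f"outcome column {outcome!r} not present")
    counts = train[outcome].value_counts()
    if len(counts) < 2:
        raise ValueError("SMOTE requires both outcome classes present")
    if len(counts) > 2:
        raise ValueError(f"outcome {outcome!r} must be binary, saw {list(counts.index)}")
    minority = counts.idxmin()
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return train.copy()
    minority_rows = train[train[outcome] == minority].reset_index(drop=True)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(minority_rows) - 1:
        raise ValueError(
            f"k={k} exceeds minority count minus one ({len(minority_rows) - 1})"
        )
    if feature_columns is None:
        feature_columns = [c for c in train.columns if c not in ("cohort", outcome)]

    cats = {c: pd.Categorical(minority_rows[c]) for c in feature_columns}
    levels = {c: cats[c].categories for c in feature_columns}
    codes = np.column_stack([cats[c].codes for c in feature_columns])
    # pairwise Hamming distances between minority rows
    dist = (codes[:, None, :] != codes[None, :, :]).sum(axis=2)
    np.fill_diagonal(dist, np.iinfo(np.int64).max)
    neighbour_idx = np.argsort(dist, axis=1, kind="stable")[:, :k]

    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, len(minority_rows), size=n_needed)
    synth = []
    for s in seeds:
        group = np.concatenate(([s], neighbour_idx[s]))
        row = {}
        for j, col in enumerate(feature_columns):
            vals = codes[group, j]
            uniq, cnt = np.unique(vals, return_counts=True)
            top = cnt.max()
            winners = set(uniq[cnt == top])
            code = codes[s, j] if codes[s, j] in winners else int(uniq[cnt == top][0])
            row[col] = levels[col][code]
        row[outcome] = minority
        if "cohort" in train.columns:
            row["cohort"] = minority_rows.loc[s, "cohort"]
        synth.append(row)
    synth_df = pd.DataFrame(synth, columns=train.columns)
    out = pd.concat([train, synth_df], ignore_index=True)
    logger.info(
        "smote_categorical: appended %d synthetic %r rows (k=%d)", n_needed, minority, k
    )
    return out
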