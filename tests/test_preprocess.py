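import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recurbn.preprocess import (
    DEFAULT_RULES,
    UNKNOWN,
    BinRule,
    CategorizationRules,
    categorize,
    dichotomize_crm,
    encode_missing_and_filter,
    smote_categorical,
    stratified_split,
)


class TestDichotomizeCrm:
    @pytest.mark.parametrize(
        "mm,expected",
        [(0.5, "Positive"), (1.0, "Positive"), (2.0, "Negative"), (0.0, "Positive")],
    )
    def test_threshold(self, mm, expected):
        assert dichotomize_crm(mm) == expected

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_crm(-0.1)


class TestCategorize:
    def test_age_bin_lookup(self):
        df = pd.DataFrame({"age": [61.0]})
        out = categorize(df, DEFAULT_RULES)
        assert out["age"].iloc[0] == "50-65"

    def test_dose_above_cut(self):
        df = pd.DataFrame({"rt_dose": [47.7]})
        out = categorize(df, DEFAULT_RULES)
        assert out["rt_dose"].iloc[0] == ">45Gy"

    def test_missing_stays_missing(self):
        df = pd.DataFrame({"age": [np.nan]})
        out = categorize(df, DEFAULT_RULES)
        assert pd.isna(out["age"].iloc[0])

    def test_idempotent_on_categorical(self):
        df = pd.DataFrame({"age": [61.0, np.nan, 30.0]})
        once = categorize(df, DEFAULT_RULES)
        twice = categorize(once, DEFAULT_RULES)
        pd.testing.assert_frame_equal(once, twice)

    def test_crm_margin_mm_dichotomized(self):
        df = pd.DataFrame({"crm_margin_mm": [0.5, 3.0, np.nan]})
        out = categorize(df, DEFAULT_RULES)
        assert list(out["crm"][:2]) == ["Positive", "Negative"]
        assert pd.isna(out["crm"].iloc[2])
        assert "crm_margin_mm" not in out.columns

    def test_strictly_increasing_cuts_enforced(self):
        with pytest.raises(ValueError):
            BinRule((5, 5), ("a", "b", "c"))

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            BinRule((5,), ("a", "a"))

    def test_out_of_range_maps_to_terminal_bin(self):
        rule = CategorizationRules(bins={"x": BinRule((0, 10), ("lo", "mid", "hi"))})
        out = categorize(pd.DataFrame({"x": [-99.0, 99.0]}), rule)
        assert list(out["x"]) == ["lo", "hi"]


class TestEncodeMissingAndFilter:
    def test_no_missing_identity(self, toy_cohort):
        out = encode_missing_and_filter(toy_cohort, "outcome")
        pd.testing.assert_frame_equal(out, toy_cohort)

    def test_missing_outcome_rows_dropped(self, toy_cohort):
        df = toy_cohort.head(10).copy()
        df.loc[[1, 4, 7], "outcome"] = np.nan
        out = encode_missing_and_filter(df, "outcome")
        assert len(out) == 7

    def test_missing_predictor_becomes_unknown(self, toy_cohort):
        df = toy_cohort.head(5).copy()
        df.loc[2, "A"] = np.nan
        out = encode_missing_and_filter(df, "outcome")
        assert out["A"].iloc[2] == UNKNOWN

    def test_absent_outcome_column_rejected(self, toy_cohort):
        with pytest.raises(ValueError):
            encode_missing_and_filter(toy_cohort, "nope")


class TestStratifiedSplit:
    def test_single_cohort_80_20(self):
        df = pd.DataFrame({"cohort": ["c"] * 10, "x": range(10)})
        train, val = stratified_split(df, 0.2, seed=0)
        assert len(train) == 8 and len(val) == 2

    def test_partition_property(self, toy_cohort):
        train, val = stratified_split(toy_cohort, 0.2, seed=1)
        assert len(train) + len(val) == len(toy_cohort)
        merged = pd.concat([train, val]).sort_values("x" if "x" in toy_cohort else "A")
        assert len(pd.concat([train, val])) == len(toy_cohort)

    def test_study_scale_split_sizes(self):
        rng = np.random.default_rng(0)
        sizes = [1200, 900, 800, 700, 600, 500, 450, 400, 350, 300, 250, 150, 104, 50]
        df = pd.DataFrame(
            {
                "cohort": np.repeat([f"t{i}" for i in range(14)], sizes),
                "x": rng.integers(0, 2, 6754).astype(str),
            }
        )
        train, val = stratified_split(df, 0.2, seed=3)
        # ~5404 / 1350 with +-1 rounding per cohort
        assert abs(len(train) - 5404) <= 14
        assert abs(len(val) - 1350) <= 14

    def test_per_cohort_stratification(self):
        df = pd.DataFrame({"cohort": ["a"] * 50 + ["b"] * 100, "x": range(150)})
        train, val = stratified_split(df, 0.2, seed=5)
        assert (val["cohort"] == "a").sum() == 10
        assert (val["cohort"] == "b").sum() == 20

    def test_seed_determinism(self, toy_cohort):
        a = stratified_split(toy_cohort, 0.2, seed=7)
        b = stratified_split(toy_cohort, 0.2, seed=7)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_tiny_cohort_all_to_train(self):
        df = pd.DataFrame({"cohort": ["solo"], "x": [1]})
        train, val = stratified_split(df, 0.2, seed=0)
        assert len(train) == 1 and len(val) == 0

    def test_bad_fraction_rejected(self, toy_cohort):
        with pytest.raises(ValueError):
            stratified_split(toy_cohort, 1.5)

    @given(st.integers(0, 2**31 - 1), st.floats(0.05, 0.95))
    @settings(max_examples=25, deadline=None)
    def test_partition_invariant_property(self, seed, frac):
        df = pd.DataFrame({"cohort": ["a"] * 37 + ["b"] * 23, "x": [str(i) for i in range(60)]})
        train, val = stratified_split(df, frac, seed=seed)
        assert set(train["x"]) | set(val["x"]) == set(df["x"])
        assert not (set(train["x"]) & set(val["x"]))


def imbalanced_frame(n_major=90, n_minor=10, seed=0):
    rng = np.random.default_rng(seed)
    n = n_major + n_minor
    return pd.DataFrame(
        {
            "cohort": "c1",
            "A": rng.choice(["x", "y", "z"], n),
            "B": rng.choice(["u", "v"], n),
            "outcome": ["False"] * n_major + ["True"] * n_minor,
        }
    )


class TestSmoteCategorical:
    def test_balanced_input_unchanged(self):
        df = imbalanced_frame(10, 10)
        out = smote_categorical(df, "outcome", k=3, seed=0)
        pd.testing.assert_frame_equal(out, df)

    def test_balances_counts(self):
        out = smote_categorical(imbalanced_frame(), "outcome", k=5, seed=0)
        counts = out["outcome"].value_counts()
        assert counts["True"] == counts["False"] == 90

    def test_original_rows_unchanged(self):
        df = imbalanced_frame()
        out = smote_categorical(df, "outcome", k=5, seed=0)
        pd.testing.assert_frame_equal(out.head(len(df)), df)

    def test_no_unseen_categories(self):
        df = imbalanced_frame()
        out = smote_categorical(df, "outcome", k=5, seed=0)
        minority = df[df["outcome"] == "True"]
        for col in ("A", "B"):
            assert set(out[col]) <= set(df[col])
            synth = out.iloc[len(df):]
            assert set(synth[col]) <= set(minority[col])

    def test_values_from_neighbourhood(self):
        # brute-force membership: every synthetic value must occur among the
        # k+1 source rows for that feature; with k = minority-1 the source
        # pool is the whole minority class
        df = imbalanced_frame(n_major=40, n_minor=8)
        k = 7
        out = smote_categorical(df, "outcome", k=k, seed=3)
        minority = df[df["outcome"] == "True"]
        synth = out.iloc[len(df):]
        for col in ("A", "B"):
            assert set(synth[col]) <= set(minority[col])

    def test_single_class_rejected(self):
        df = imbalanced_frame(10, 0)
        df["outcome"] = "False"
        with pytest.raises(ValueError):
            smote_categorical(df, "outcome", k=3, seed=0)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            smote_categorical(imbalanced_frame(n_minor=5), "outcome", k=5, seed=0)

    def test_seed_determinism(self):
        df = imbalanced_frame()
        a = smote_categorical(df, "outcome", k=5, seed=11)
        b = smote_categorical(df, "outcome", k=5, seed=11)
        pd.testing.assert_frame_equal(a, b)
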