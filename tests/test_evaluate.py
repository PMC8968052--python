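import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recurbn.bn import DAG, fit_parameters
from recurbn.evaluate import (
    auc_confidence_interval,
    calibration,
    compare_auc,
    confusion_metrics,
    predict_cohort,
    roc_auc,
    structure_diff,
)

from conftest import brute_force_auc


class TestPredictCohort:
    def test_two_node_hand_bayes(self, two_node_bn):
        table = pd.DataFrame({"B": ["T", "F"]})
        probs = predict_cohort(two_node_bn, table, "A", positive="T")
        assert probs[0] == pytest.approx(0.27 / 0.41, abs=1e-12)
        assert probs[1] == pytest.approx(0.03 / 0.59, abs=1e-12)

    def test_independent_outcome_gets_prior(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(
            {
                "X": rng.integers(0, 2, 500).astype(str),
                "Y": np.where(rng.random(500) < 0.3, "True", "False"),
            }
        )
        bn = fit_parameters(DAG(("X", "Y")), data, alpha=0)
        probs = predict_cohort(bn, data, "Y")
        assert len(set(np.round(probs, 12))) == 1

    def test_identical_rows_identical_probs(self, two_node_bn):
        table = pd.DataFrame({"B": ["T", "T", "F"]})
        probs = predict_cohort(two_node_bn, table, "A", positive="T")
        assert probs[0] == probs[1]

    def test_unseen_category_raises(self, two_node_bn):
        with pytest.raises(ValueError, match="not a category"):
            predict_cohort(two_node_bn, pd.DataFrame({"B": ["nope"]}), "A", positive="T")

    def test_matches_exact_posterior_with_children(self):
        # network where outcome has children: fast path must equal VE
        from recurbn.inference import posterior
        from conftest import make_random_bn

        rng = np.random.default_rng(33)
        bn = make_random_bn(rng, 6, p_arc=0.5)
        outcome = bn.dag.nodes[2]  # interior node: has parents and children
        others = [n for n in bn.dag.nodes if n != outcome]
        from recurbn.bn import ancestral_sample

        table = ancestral_sample(bn, 50, seed=1)[others]
        probs = predict_cohort(bn, table, outcome, positive=bn.categories(outcome)[0])
        for i in range(len(table)):
            ev = {c: table[c].iloc[i] for c in others}
            want = posterior(bn, outcome, ev)[bn.categories(outcome)[0]]
            assert probs[i] == pytest.approx(want, abs=1e-9)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_hand_example(self):
        assert roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            y[0], y[1] = 0, 1
        p = np.round(rng.random(n), 2)  # coarse grid to exercise ties
        assert roc_auc(p, y) == pytest.approx(brute_force_auc(p, y), abs=1e-12)


class TestAucCI:
    def test_contains_point_estimate(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 200)
        p = y * 0.3 + rng.random(200) * 0.7
        lo, hi = auc_confidence_interval(p, y)
        assert lo <= roc_auc(p, y) <= hi

    def test_width_shrinks_with_n(self):
        rng = np.random.default_rng(2)

        def width(n):
            y = rng.integers(0, 2, n)
            p = np.clip(y * 0.4 + rng.normal(0.5, 0.2, n), 0, 1)
            lo, hi = auc_confidence_interval(p, y)
            return hi - lo

        assert width(10_000) < width(100)

    def test_perfect_auc_clipped_at_one(self):
        y = np.array([1] * 50 + [0] * 50)
        p = np.concatenate([np.linspace(0.6, 1, 50), np.linspace(0, 0.4, 50)])
        lo, hi = auc_confidence_interval(p, y)
        assert hi == 1.0

    def test_degenerate_class_rejected(self):
        with pytest.raises(ValueError):
            auc_confidence_interval([0.1, 0.9, 0.5], [1, 0, 0])


class TestCompareAuc:
    def test_identical_probs_p_one(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 100)
        p = rng.random(100)
        assert compare_auc(p, p, y) == 1.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_auc([0.1], [0.1, 0.2], [1, 0])

    def test_signal_vs_noise_detected(self):
        rng = np.random.default_rng(4)
        detected = 0
        sims = 40
        for _ in range(sims):
            n = 500
            signal = rng.normal(size=n)
            y = (signal + rng.normal(scale=0.7, size=n) > 0).astype(int)
            if y.sum() in (0, n):
                continue
            if compare_auc(signal, rng.normal(size=n), y) < 0.05:
                detected += 1
        assert detected >= 0.95 * sims

    def test_null_type_one_error(self):
        # two independent noisy copies of the same signal; nominal 5% level
        rng = np.random.default_rng(2024)
        rejections = 0
        sims = 200
        for _ in range(sims):
            n = 500
            signal = rng.normal(size=n)
            y = (signal + rng.normal(size=n) > 0).astype(int)
            pa = signal + rng.normal(size=n)
            pb = signal + rng.normal(size=n)
            rejections += compare_auc(pa, pb, y) < 0.05
        assert 0.03 <= rejections / sims <= 0.07


class TestConfusionMetrics:
    def test_perfect_predictor(self):
        acc, sens, spec = confusion_metrics([0.9, 0.9, 0.1, 0.1], [1, 1, 0, 0])
        assert (acc, sens, spec) == (1.0, 1.0, 1.0)

    def test_hand_two_by_two(self):
        acc, sens, spec = confusion_metrics([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0], 0.5)
        assert (acc, sens, spec) == (0.5, 0.5, 0.5)

    def test_threshold_zero_sensitivity_one(self):
        _, sens, _ = confusion_metrics([0.2, 0.8], [1, 0], threshold=0.0)
        assert sens == 1.0

    def test_single_class_flagged_nan(self):
        acc, sens, spec = confusion_metrics([0.9, 0.1], [1, 1])
        assert np.isnan(spec) and sens == 0.5


class TestCalibration:
    def test_constant_probs_single_bin(self):
        rng = np.random.default_rng(5)
        y = (rng.random(1000) < 0.3).astype(int)
        curve = calibration(np.full(1000, 0.3), y, bins=10, boot=50, seed=0)
        assert curve.bins == 1
        assert curve.mean_predicted[0] == pytest.approx(0.3)
        assert curve.observed[0] == pytest.approx(y.mean())

    def test_well_specified_model_near_diagonal(self):
        rng = np.random.default_rng(6)
        n = 10_000
        p = rng.beta(2, 5, n)
        y = (rng.random(n) < p).astype(int)
        curve = calibration(p, y, bins=10, boot=0, seed=0)
        assert np.nanmax(np.abs(curve.mean_predicted - curve.observed)) < 0.05

    def test_shuffled_labels_flat_at_prevalence(self):
        rng = np.random.default_rng(7)
        n = 10_000
        p = rng.beta(2, 5, n)
        y = rng.permutation((rng.random(n) < p).astype(int))
        curve = calibration(p, y, bins=10, boot=0, seed=0)
        assert np.nanmax(np.abs(curve.observed - y.mean())) < 0.05

    def test_ci_brackets_observed(self):
        rng = np.random.default_rng(8)
        n = 2000
        p = rng.random(n)
        y = (rng.random(n) < p).astype(int)
        curve = calibration(p, y, bins=5, boot=100, seed=1)
        assert (curve.ci_low <= curve.observed + 1e-12).all()
        assert (curve.ci_high >= curve.observed - 1e-12).all()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            calibration([0.5, 0.6], [1, 0], bins=10)


class TestStructureDiff:
    def test_identical_dags_zero(self):
        dag = DAG(("A", "B", "C"), [("A", "B"), ("B", "C")])
        diff = structure_diff(dag, dag)
        assert diff.shd == 0
        assert diff.only_a == diff.only_b == diff.reversed_arcs == set()
        assert diff.shared == set(dag.arcs)

    def test_one_reversed(self):
        a = DAG(("A", "B"), [("A", "B")])
        b = DAG(("A", "B"), [("B", "A")])
        diff = structure_diff(a, b)
        assert diff.reversed_arcs == {("A", "B")} and diff.shd == 1

    def test_extra_arc(self):
        a = DAG(("X", "Y", "Z"), [("X", "Y")])
        b = DAG(("X", "Y", "Z"), [("X", "Y"), ("Y", "Z")])
        diff = structure_diff(a, b)
        assert diff.shd == 1 and diff.shared == {("X", "Y")} and diff.only_b == {("Y", "Z")}

    def test_categories_partition_adjacencies(self):
        rng = np.random.default_rng(9)
        from conftest import make_random_bn

        a = make_random_bn(rng, 7).dag
        b = make_random_bn(rng, 7).dag
        diff = structure_diff(a, b)
        union = set(a.arcs) | set(b.arcs)
        covered = (
            diff.shared
            | diff.only_a
            | diff.only_b
            | diff.reversed_arcs
            | {(v, u) for (u, v) in diff.reversed_arcs}
        )
        assert covered == union

    def test_outcome_relations_listed(self):
        a = DAG(("P", "O"), [("P", "O")])
        b = DAG(("P", "O"), [("O", "P")])
        diff = structure_diff(a, b, outcome="O")
        assert diff.outcome_parents_a == ("P",)
        assert diff.outcome_children_b == ("P",)
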