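"""Split planning, logistic fitting, metrics, intervals and scheme runs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit
from sklearn.metrics import balanced_accuracy_score

from gmdclassify import (
    PipelineConfig,
    TrainedBinaryModel,
    assess_specificity,
    balanced_accuracy,
    outgroup_rate,
    percentile_interval,
    plan_splits,
    predict_evidence,
    run_scheme,
    train_binary_model,
)
from gmdclassify.classify import CONTROL_GROUP, IntervalEntry

from .conftest import cohort_features, make_cohort
from .oracles import logistic_fit_reference, percentile_interval_reference


def subject_table(biotype_sizes, diagnosis_sizes=None):
    rows = []
    for g, n in biotype_sizes.items():
        rows += [g] * n
    table = pd.DataFrame(
        {"subject_id": [f"S{i}" for i in range(len(rows))], "biotype": rows}
    )
    if diagnosis_sizes:
        diag = []
        for g, n in diagnosis_sizes.items():
            diag += [g] * n
        table["diagnosis"] = diag
    return table


REFERENCE_BIOTYPE_SIZES = {"B1": 150, "B2": 185, "B3": 222, "CON": 251}
REFERENCE_DIAGNOSIS_SIZES = {"SZ": 242, "SAD": 138, "BD": 177, "CON": 251}


class TestPlanSplits:
    def test_heldout_complement_counts_biotype(self):
        table = subject_table(REFERENCE_BIOTYPE_SIZES)
        config = PipelineConfig(n_train_per_group=88, n_iterations=3, master_seed=0)
        plan = plan_splits(table, "biotype", config)
        test_sizes = {g: len(plan.iterations[0][g][1]) for g in plan.iterations[0]}
        assert test_sizes == {"B1": 62, "B2": 97, "B3": 134, "CON": 163}

    def test_train_and_test_disjoint_and_balanced(self):
        table = subject_table(REFERENCE_BIOTYPE_SIZES)
        config = PipelineConfig(n_train_per_group=88, n_iterations=2, master_seed=1)
        plan = plan_splits(table, "biotype", config)
        for split in plan.iterations:
            for g, (train, test) in split.items():
                assert len(train) == 88
                assert np.intersect1d(train, test).size == 0
                assert len(train) + len(test) == REFERENCE_BIOTYPE_SIZES[g]

    def test_group_too_small_names_group(self):
        table = subject_table({"B1": 88, "B2": 185, "B3": 222, "CON": 251})
        with pytest.raises(ValueError, match="'B1'"):
            plan_splits(table, "biotype", PipelineConfig(n_iterations=1))

    def test_same_master_seed_reproduces_plan(self):
        table = subject_table(REFERENCE_BIOTYPE_SIZES)
        config = PipelineConfig(n_iterations=4, master_seed=9)
        a = plan_splits(table, "biotype", config)
        b = plan_splits(table, "biotype", config)
        for sa, sb in zip(a.iterations, b.iterations):
            for g in sa:
                np.testing.assert_array_equal(sa[g][0], sb[g][0])

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            plan_splits(subject_table(REFERENCE_BIOTYPE_SIZES), "dsm6", PipelineConfig())


class TestTrainBinaryModel:
    def test_separable_clusters_order_by_evidence(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (30, 4)), rng.normal(2, 0.3, (30, 4))])
        y = np.array(["CON"] * 30 + ["B1"] * 30)
        model = train_binary_model(X, y, PipelineConfig())
        ev = predict_evidence(model, X)
        assert ev[30:].min() > ev[:30].max()

    def test_permuted_labels_give_chance_heldout_accuracy(self, rng):
        X = rng.normal(0, 1, (400, 20))
        y = np.array(["B1", "CON"] * 200)
        model = train_binary_model(X[:200], y[:200], PipelineConfig())
        ev = predict_evidence(model, X[200:])
        pred = np.where(ev > 0.5, "B1", "CON")
        assert abs(balanced_accuracy(y[200:], pred) - 0.5) < 0.15

    def test_matches_generic_optimizer_oracle(self, rng):
        X = rng.normal(0, 1, (20, 5))
        y01 = (rng.random(20) < 0.5).astype(int)
        y01[:3], y01[3:6] = 1, 0  # ensure both classes
        y = np.where(y01 == 1, "B1", "CON")
        model = train_binary_model(X, y, PipelineConfig(solver_tol=1e-10))
        w_ref, b_ref = logistic_fit_reference(X, y01, cost=1.0)
        np.testing.assert_allclose(model.weights, w_ref, atol=1e-4)
        assert model.intercept == pytest.approx(b_ref, abs=1e-4)

    def test_constant_matrix_rejected(self):
        X = np.full((10, 3), 0.5)
        y = np.array(["B1"] * 5 + ["CON"] * 5)
        with pytest.raises(ValueError, match="constant"):
            train_binary_model(X, y, PipelineConfig())

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        with pytest.raises(ValueError, match="two classes"):
            train_binary_model(X, np.array(["B1"] * 6), PipelineConfig())


class TestPredictEvidence:
    def test_zero_model_gives_half_everywhere(self):
        model = TrainedBinaryModel(np.zeros(3), 0.0, "B1")
        np.testing.assert_array_equal(
            predict_evidence(model, np.ones((4, 3))), np.full(4, 0.5)
        )

    def test_large_intercept_saturates_to_one(self):
        model = TrainedBinaryModel(np.zeros(2), 50.0, "B1")
        assert predict_evidence(model, np.zeros((1, 2)))[0] == pytest.approx(1.0)

    def test_matches_hand_computed_logistic(self):
        model = TrainedBinaryModel(np.array([0.5, -1.0]), 0.25, "B1")
        x = np.array([[2.0, 1.0]])
        assert predict_evidence(model, x)[0] == pytest.approx(expit(0.5 * 2 - 1 + 0.25))

    def test_dimension_mismatch_rejected(self):
        model = TrainedBinaryModel(np.zeros(3), 0.0, "B1")
        with pytest.raises(ValueError, match="does not match"):
            predict_evidence(model, np.zeros((2, 4)))


class TestBalancedAccuracy:
    def test_perfect_predictions(self):
        y = np.array(["B1", "B1", "CON", "CON"])
        assert balanced_accuracy(y, y) == 1.0

    def test_constant_prediction_scores_half(self):
        truth = np.array(["B1", "B1", "CON"])
        pred = np.array(["B1", "B1", "B1"])
        assert balanced_accuracy(truth, pred) == 0.5

    def test_worked_example(self):
        truth = np.array(["P", "P", "P", "C", "C"])
        pred = np.array(["P", "P", "C", "C", "C"])
        assert balanced_accuracy(truth, pred, positive_class="P") == pytest.approx(
            (2 / 3 + 1.0) / 2
        )

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            balanced_accuracy(np.array(["B1", "B1"]), np.array(["B1", "CON"]))

    def test_agrees_with_sklearn(self, rng):
        truth = rng.choice(["B1", "CON"], size=200)
        truth[:2] = ["B1", "CON"]
        pred = rng.choice(["B1", "CON"], size=200)
        assert balanced_accuracy(truth, pred) == pytest.approx(
            balanced_accuracy_score(truth, pred)
        )


class TestOutgroupRate:
    @staticmethod
    def model_with_target_evidence(targets):
        # one feature, unit weight: evidence(x) = expit(x), so x = logit(target)
        return TrainedBinaryModel(np.array([1.0]), 0.0, "B1"), logit(
            np.asarray(targets)
        ).reshape(-1, 1)

    def test_always_confident_model_rates_one(self):
        model, X = self.model_with_target_evidence([0.9, 0.9, 0.9])
        assert outgroup_rate(model, X, PipelineConfig()) == 1.0

    def test_evidence_exactly_at_threshold_counts_as_control(self):
        model, X = self.model_with_target_evidence([0.5, 0.5])
        assert outgroup_rate(model, X, PipelineConfig()) == 0.0

    def test_worked_example(self):
        model, X = self.model_with_target_evidence([0.2, 0.6, 0.7, 0.4])
        assert outgroup_rate(model, X, PipelineConfig()) == 0.5

    def test_empty_outgroup_rejected(self):
        model = TrainedBinaryModel(np.array([1.0]), 0.0, "B1")
        with pytest.raises(ValueError, match="empty"):
            outgroup_rate(model, np.empty((0, 1)), PipelineConfig())


class TestPercentileInterval:
    def test_identical_values_collapse(self):
        assert percentile_interval([0.7] * 10, 0.9917) == (0.7, 0.7)

    def test_level_near_one_approaches_min_max(self):
        values = np.linspace(0.2, 0.8, 50)
        lo, hi = percentile_interval(values, 1 - 1e-9)
        assert lo == pytest.approx(0.2, abs=1e-6)
        assert hi == pytest.approx(0.8, abs=1e-6)

    def test_grid_matches_brute_force_oracle(self):
        values = np.arange(1, 1001) / 1000.0
        assert percentile_interval(values, 0.95) == pytest.approx(
            percentile_interval_reference(values, 0.95)
        )

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=50),
        st.floats(0.5, 0.999),
    )
    def test_matches_oracle_for_arbitrary_inputs(self, values, level):
        lo, hi = percentile_interval(values, level)
        rlo, rhi = percentile_interval_reference(values, level)
        assert lo == pytest.approx(rlo, abs=1e-12)
        assert hi == pytest.approx(rhi, abs=1e-12)

    @pytest.mark.parametrize("level", [0.0, 1.0, -0.5, 1.5])
    def test_invalid_level_rejected(self, level):
        with pytest.raises(ValueError, match="level"):
            percentile_interval([0.1, 0.2], level)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            percentile_interval([0.4], 0.95)


class TestAssessSpecificity:
    @staticmethod
    def entry(lo, above=None):
        return IntervalEntry(mean=lo + 0.02, lo=lo, hi=lo + 0.05, above_chance=lo > 0.5)

    def test_own_above_and_no_transfer_above_is_specific(self):
        assert assess_specificity(
            self.entry(0.55), {"t1": self.entry(0.45), "t2": self.entry(0.48)}
        )

    def test_one_transfer_above_chance_breaks_specificity(self):
        assert not assess_specificity(
            self.entry(0.55), {"t1": self.entry(0.52), "t2": self.entry(0.45)}
        )

    def test_own_group_at_chance_never_specific(self):
        assert not assess_specificity(
            self.entry(0.48), {"t1": self.entry(0.40), "t2": self.entry(0.40)}
        )

    def test_missing_entries_rejected(self):
        with pytest.raises(ValueError):
            assess_specificity(self.entry(0.55), {})


@pytest.fixture(scope="module")
def tiny_run():
    cohort = make_cohort(
        preset="paper_like",
        grid=10,
        seed=3,
        group_sizes={"B1": 30, "B2": 30, "B3": 30, "CON": 30},
    )
    mask, fm = cohort_features(cohort)
    config = PipelineConfig(
        n_train_per_group=20, n_iterations=8, master_seed=42, collect_weights=True
    )
    return cohort, fm, config


class TestRunScheme:
    def test_deterministic_given_seed(self, tiny_run):
        cohort, fm, config = tiny_run
        r1, _, w1 = run_scheme(fm, cohort.subjects, "biotype", config)
        r2, _, w2 = run_scheme(fm, cohort.subjects, "biotype", config)
        assert r1.to_json_dict() == r2.to_json_dict()
        for g in w1:
            np.testing.assert_array_equal(w1[g], w2[g])

    def test_pooled_accuracy_between_sensitivity_and_specificity(self, tiny_run):
        cohort, fm, config = tiny_run
        _, records, _ = run_scheme(fm, cohort.subjects, "biotype", config)
        for rec in records:
            for m in rec.metrics.values():
                lo = min(m["sensitivity"], m["specificity"])
                hi = max(m["sensitivity"], m["specificity"])
                assert lo - 1e-12 <= m["pooled"] <= hi + 1e-12
                assert m["balanced"] == pytest.approx(
                    0.5 * (m["sensitivity"] + m["specificity"])
                )

    def test_diagnosis_scheme_runs_with_own_labels(self, tiny_run):
        cohort, fm, config = tiny_run
        table = cohort.subjects.copy()
        # relabel psychosis cases with balanced diagnosis groups for this check
        psych = table["biotype"] != "CON"
        table.loc[psych, "diagnosis"] = np.tile(["SZ", "SAD", "BD"], 30)
        report, _, _ = run_scheme(fm, table, "diagnosis", config)
        assert set(report.models) == {"SZ", "SAD", "BD"}

    def test_evidence_recorded_for_every_test_subject(self, tiny_run):
        cohort, fm, config = tiny_run
        _, records, _ = run_scheme(fm, cohort.subjects, "biotype", config)
        n_test_total = 4 * (30 - config.n_train_per_group)
        for rec in records:
            for series in rec.evidence.values():
                assert len(series) == n_test_total
                assert series.between(0, 1).all()


def test_null_cohorts_rarely_declared_above_chance():
    """Type-I control: over 50 replicate no-effect cohorts the 99.17%
    interval test should almost never declare a model above chance."""
    false_positives = 0
    for seed in range(50):
        cohort = make_cohort(
            preset="null", grid=10, seed=seed,
            group_sizes={"B1": 30, "B2": 30, "B3": 30, "CON": 30},
        )
        mask, fm = cohort_features(cohort)
        config = PipelineConfig(
            n_train_per_group=20, n_iterations=40, master_seed=seed, collect_weights=False
        )
        report, _, _ = run_scheme(fm, cohort.subjects, "biotype", config, groups=["B1"])
        entry = report.models["B1"].entries["overall_balanced"]
        false_positives += int(entry.above_chance)
    assert false_positives <= 2  # binomial(50, 0.0083) upper tail
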