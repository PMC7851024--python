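import itertools
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import teushmm as tm
from teushmm import ValidationError
from teushmm.evaluate import _fold_seed


class TestLopoFolds:
    def test_one_fold_per_patient_sorted(self):
        cohort = tm.generate_cohort(tm.CohortSpec(n_patients=12, rois_per_patient_per_class=1, seed=0))
        plan = tm.lopo_folds(cohort)
        assert len(plan) == 12
        held = [h for h, _ in plan]
        assert held == sorted(held)

    def test_two_patients(self):
        cohort = tm.generate_cohort(tm.CohortSpec(n_patients=2, rois_per_patient_per_class=1, seed=0))
        plan = tm.lopo_folds(cohort)
        assert len(plan) == 2
        assert all(len(train) == 1 for _, train in plan)

    def test_partition_property(self):
        cohort = tm.generate_cohort(tm.CohortSpec(n_patients=5, rois_per_patient_per_class=1, seed=0))
        plan = tm.lopo_folds(cohort)
        held = {h for h, _ in plan}
        assert held == set(cohort.patient_ids())
        for h, train in plan:
            assert h not in train
            assert set(train) | {h} == held

    def test_single_patient_rejected(self):
        records = tm.generate_cohort(
            tm.CohortSpec(n_patients=2, rois_per_patient_per_class=1, seed=0)
        ).subset(["P01"])
        with pytest.raises(ValidationError):
            tm.lopo_folds(records)


class TestComputeMetrics:
    def test_hand_counted_example(self):
        truth = ["malignant", "malignant", "benign", "benign"]
        pred = ["malignant", "benign", "benign", "benign"]
        r = tm.compute_metrics(truth, pred)
        assert r.accuracy == 0.75
        assert r.sensitivity == 0.5
        assert r.specificity == 1.0
        assert (r.tp, r.tn, r.fp, r.fn) == (1, 2, 0, 1)

    def test_all_benign_has_missing_sensitivity(self):
        r = tm.compute_metrics(["benign"] * 4, ["benign", "malignant", "benign", "benign"])
        assert r.sensitivity is None
        assert r.specificity == r.accuracy == 0.75

    def test_perfect_prediction(self):
        truth = ["malignant", "benign"]
        r = tm.compute_metrics(truth, truth)
        assert (r.accuracy, r.sensitivity, r.specificity) == (1.0, 1.0, 1.0)

    def test_accuracy_identity(self):
        rng = np.random.default_rng(0)
        labels = ["malignant", "benign"]
        truth = [labels[i] for i in rng.integers(0, 2, 20)]
        pred = [labels[i] for i in rng.integers(0, 2, 20)]
        r = tm.compute_metrics(truth, pred)
        assert r.accuracy == (r.tp + r.tn) / (r.tp + r.tn + r.fp + r.fn)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            tm.compute_metrics(["benign"], [])


class TestNormalizeLogOr:
    def test_all_zero_maps_to_half(self):
        assert np.array_equal(tm.normalize_log_or([0.0, 0.0, 0.0]), [0.5, 0.5, 0.5])

    def test_stated_formula(self):
        assert np.allclose(tm.normalize_log_or([-2.0, 1.0]), [0.0, 0.75])

    def test_zero_always_maps_to_half(self):
        out = tm.normalize_log_or([-3.0, 0.0, 5.0])
        assert out[1] == 0.5
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_threshold_half_reproduces_hard_labels(self, small_pair, small_cohort):
        preds = tm.classify_cohort(small_pair, small_cohort)
        norm = tm.normalize_log_or(np.array([p.log_odds for p in preds]))
        relabeled = ["benign" if s > 0.5 else "malignant" for s in norm]
        assert relabeled == [p.label for p in preds]

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            tm.normalize_log_or([])


class TestRocCurve:
    def test_perfect_separation(self):
        roc = tm.roc_curve([0.9, 0.8, 0.2, 0.1], ["malignant", "malignant", "benign", "benign"])
        assert roc.auc == 1.0

    def test_constant_scores(self):
        roc = tm.roc_curve([0.5] * 6, ["malignant", "benign"] * 3)
        assert roc.auc == 0.5

    def test_three_point_example(self):
        roc = tm.roc_curve([0.9, 0.8, 0.3], ["malignant", "benign", "malignant"])
        assert roc.auc == 0.5

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(4)
        truth = ["malignant"] * 10 + ["benign"] * 15
        roc = tm.roc_curve(rng.random(25), truth)
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_auc_equals_pairwise_rank_statistic(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n_m, n_b = rng.integers(2, 8, size=2)
            scores = np.round(rng.random(n_m + n_b), 1)  # force some ties
            truth = ["malignant"] * n_m + ["benign"] * n_b
            roc = tm.roc_curve(scores, truth)
            mal, ben = scores[:n_m], scores[n_m:]
            wins = sum((m > b) + 0.5 * (m == b) for m in mal for b in ben)
            assert roc.auc == pytest.approx(wins / (n_m * n_b), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            tm.roc_curve([0.1, 0.2], ["benign", "benign"])


class TestRankSumTest:
    def test_hand_enumerated_example(self):
        u, p = tm.rank_sum_test([3, 4, 5], [1, 2])
        assert u == 6
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_not_significant(self):
        x = [1.0, 2.0, 3.0, 3.0]
        _, p = tm.rank_sum_test(x, list(x))
        assert p >= 0.5

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(1, 1, 6), rng.normal(0, 1, 7)
        u, p = tm.rank_sum_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="greater", method="exact")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_and_normal_branches_agree(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0.5, 1, 8), rng.normal(0, 1, 8)
        _, p_exact = tm.rank_sum_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        assert p_exact == pytest.approx(ref.pvalue, abs=0.02)

    def test_handles_ties_with_midranks(self):
        u, _ = tm.rank_sum_test([2, 2, 3], [1, 2])
        # midranks: [3, 3, 5] vs [1, 3]; U = 11 - 6 = 5
        assert u == 5.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            tm.rank_sum_test([], [1.0])


@pytest.fixture(scope="module")
def lopo_result(small_cohort, small_config):
    return tm.run_lopo(small_cohort, small_config)


class TestRunLopo:
    def test_record_per_patient_plus_average(self, lopo_result, small_cohort):
        records, _ = lopo_result
        assert [r.patient_id for r in records] == small_cohort.patient_ids() + ["average"]

    def test_every_roi_scored_exactly_once(self, lopo_result, small_cohort):
        _, preds = lopo_result
        assert sorted(p.roi_id for p in preds) == sorted(r.roi_id for r in small_cohort)

    def test_roi_order_within_patient_irrelevant(self, small_cohort, small_config):
        records, _ = tm.run_lopo(small_cohort, small_config)
        shuffled = tm.Cohort(list(small_cohort.records[::-1]))
        records2, _ = tm.run_lopo(shuffled, small_config)
        for a, b in zip(records, records2):
            assert a.patient_id == b.patient_id
            assert a.accuracy == b.accuracy
            assert a.auc == b.auc

    def test_held_out_data_cannot_leak_into_training(self, small_cohort, small_config):
        plan = tm.lopo_folds(small_cohort)
        held, train_ids = plan.folds[0]
        seed = _fold_seed(small_config.seed, small_config.n_states,
                          small_config.alphabet_size, 0)
        config = replace(small_config, seed=seed)
        pair_clean = tm.train_pair(small_cohort.subset(train_ids), config)
        corrupted = tm.Cohort([
            tm.RoiTimeSeries(r.patient_id, r.roi_id, r.label,
                             r.values + 100.0, r.frame_rate)
            if r.patient_id == held else r
            for r in small_cohort
        ])
        pair_corrupt = tm.train_pair(corrupted.subset(train_ids), config)
        assert pair_clean == pair_corrupt

    def test_benign_only_patient_gets_missing_sensitivity_and_auc(self):
        cohort = tm.generate_cohort(
            tm.CohortSpec(n_patients=3, rois_per_patient_per_class=4,
                          n_frames=64, benign_only_patients=1, seed=2)
        )
        config = tm.TrainConfig(n_states=2, alphabet_size=10, max_iter=15, seed=2)
        records, _ = tm.run_lopo(cohort, config)
        rec = {r.patient_id: r for r in records}["P03"]
        assert rec.sensitivity is None and rec.auc is None
        assert rec.specificity is not None

    def test_average_row_follows_partial_averaging_rule(self):
        cohort = tm.generate_cohort(
            tm.CohortSpec(n_patients=3, rois_per_patient_per_class=4,
                          n_frames=64, benign_only_patients=1, seed=2)
        )
        config = tm.TrainConfig(n_states=2, alphabet_size=10, max_iter=15, seed=2)
        records, _ = tm.run_lopo(cohort, config)
        per_patient = records[:-1]
        avg = records[-1]
        assert avg.accuracy == pytest.approx(np.mean([r.accuracy for r in per_patient]))
        with_mal = [r for r in per_patient if r.sensitivity is not None]
        assert avg.sensitivity == pytest.approx(np.mean([r.sensitivity for r in with_mal]))
        if all(r.auc is not None for r in with_mal):
            assert avg.auc == pytest.approx(np.mean([r.auc for r in with_mal]))


class TestGridSearch:
    def test_singleton_grid_matches_direct_run(self, small_cohort, small_config):
        result = tm.grid_search(small_cohort, states=[3], alphabets=[10],
                                base_config=small_config)
        assert len(result.table) == 1
        records, _ = tm.run_lopo(small_cohort, small_config)
        accs = [r.accuracy for r in records if r.patient_id != "average"]
        row = result.table.iloc[0]
        assert row.mean_accuracy == pytest.approx(np.mean(accs))
        assert row.sd_accuracy == pytest.approx(np.std(accs, ddof=1))

    def test_cells_independent_of_evaluation_order(self, small_cohort, small_config):
        a = tm.grid_search(small_cohort, states=[2, 3], alphabets=[10],
                           base_config=replace(small_config, max_iter=10))
        b = tm.grid_search(small_cohort, states=[3, 2], alphabets=[10],
                           base_config=replace(small_config, max_iter=10))
        assert a.table.equals(b.table)

    def test_empty_grid_rejected(self, small_cohort, small_config):
        with pytest.raises(ValidationError):
            tm.grid_search(small_cohort, states=[], alphabets=[10],
                           base_config=small_config)
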