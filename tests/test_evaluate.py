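import numpy as np
import pytest

from connmvpa.connectivity import FeatureDataset, EdgeIndexMap, build_dataset
from connmvpa.evaluate import (consensus_features, grid_select, loocv, metrics,
                               permutation_test, sweep_feature_number,
                               union_features)
from connmvpa.synth import SimulationConfig, simulate_null_cohort


class TestMetrics:
    def test_headline_worked_example(self):
        # 19/22 patients and 22/22 controls correct
        m = metrics(tp=19, tn=22, fp=0, fn=3)
        assert m.gr == pytest.approx(41 / 44)
        assert round(100 * m.gr, 1) == 93.2
        assert round(100 * m.ss, 1) == 86.4
        assert m.sc == 1.0

    def test_all_correct_and_all_wrong(self):
        assert metrics(5, 5, 0, 0).gr == 1.0
        assert metrics(0, 0, 5, 5).gr == 0.0

    def test_undefined_denominators_reported_missing(self):
        m = metrics(tp=0, tn=3, fp=1, fn=0)
        assert m.ss is None and m.sc is not None

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            metrics(0, 0, 0, 0)
        with pytest.raises(ValueError):
            metrics(-1, 2, 0, 0)


@pytest.fixture(scope="session")
def cv_small(small_planted_dataset):
    dataset, _ = small_planted_dataset
    return dataset, loocv(dataset, k=30, d=4, C=0.5)


class TestLoocv:
    def test_one_fold_per_subject(self, cv_small):
        dataset, cv = cv_small
        assert len(cv.folds) == dataset.n_subjects
        assert [f.subject_id for f in cv.folds] == dataset.subject_ids

    def test_aggregate_count_identity(self, cv_small):
        _, cv = cv_small
        assert cv.tp + cv.tn + cv.fp + cv.fn == len(cv.folds)
        assert cv.metrics.gr * len(cv.folds) == pytest.approx(cv.tp + cv.tn)

    def test_training_only_selection(self, cv_small):
        # corrupting the held-out subject must not change that fold's models
        dataset, cv = cv_small
        X = dataset.X.copy()
        X[0] += 100.0
        corrupted = FeatureDataset(X, dataset.y.copy(), dataset.edge_map,
                                   dataset.region_labels, dataset.subject_ids)
        cv2 = loocv(corrupted, k=30, d=4, C=0.5)
        f0, g0 = cv.folds[0], cv2.folds[0]
        assert np.array_equal(f0.selection.indices, g0.selection.indices)
        assert np.allclose(f0.pca.components, g0.pca.components)
        assert np.allclose(f0.svm.w, g0.svm.w) and f0.svm.b == g0.svm.b

    def test_fold_weights_live_on_selected_features(self, cv_small):
        _, cv = cv_small
        for f in cv.folds:
            off = np.setdiff1d(np.arange(len(f.weights)), f.selection.indices)
            assert np.all(f.weights[off] == 0.0)

    def test_planted_cohort_classified_above_chance(self, cv_small):
        _, cv = cv_small
        assert cv.metrics.gr >= 0.8

    def test_too_few_subjects_rejected(self, rng):
        emap = EdgeIndexMap(4)
        ds = FeatureDataset(rng.standard_normal((3, emap.n_edges)),
                            np.array([-1, 1, 1]), emap, [f"r{i}" for i in range(4)])
        with pytest.raises(ValueError):
            loocv(ds, k=3, d=1, C=1.0)


class TestFeatureSets:
    def test_consensus_subset_of_every_fold_subset_of_union(self, cv_small):
        _, cv = cv_small
        cons, union = set(consensus_features(cv)), set(union_features(cv))
        for f in cv.folds:
            sel = set(f.selection.indices.tolist())
            assert cons <= sel <= union
        assert len(cons) <= cv.k <= len(union)

    def test_identical_selections_collapse(self, rng):
        # perfectly separated planted feature set: same top features each fold
        emap = EdgeIndexMap(4)
        X = rng.standard_normal((10, emap.n_edges)) * 0.01
        y = np.array([-1] * 5 + [1] * 5)
        X[:, 2] = np.where(y == -1, -1.0, 1.0) + 0.01 * rng.standard_normal(10)
        cv = loocv(FeatureDataset(X, y, emap, [f"r{i}" for i in range(4)]),
                   k=1, d=1, C=1.0)
        assert np.array_equal(cv.consensus, cv.union)


class TestSweepAndGrid:
    def test_sweep_reports_smallest_best_k(self, cv_small):
        dataset, _ = cv_small
        table = sweep_feature_number(dataset, [10, 30, 50], d=4, C=0.5)
        assert list(table["k"]) == [10, 30, 50]
        best_gr = table["gr"].max()
        assert table.attrs["best_k"] == int(table[table["gr"] == best_gr]["k"].min())

    def test_singleton_grid_is_identity(self, cv_small):
        dataset, cv = cv_small
        (k, d, C), gr, _ = grid_select(dataset, [30], [4], [0.5])
        assert (k, d, C) == (30, 4, 0.5)
        assert gr == pytest.approx(cv.metrics.gr)


class TestPermutationTest:
    def test_identity_permutation_reproduces_observed_gr(self, cv_small):
        dataset, cv = cv_small
        gr_again = loocv(dataset, 30, 4, 0.5,
                         y_override=dataset.y.copy()).metrics.gr
        assert gr_again == cv.metrics.gr

    def test_p_value_bounds_and_reproducibility(self, cv_small):
        dataset, _ = cv_small
        a = permutation_test(dataset, k=30, d=4, C=0.5, n_perm=5, seed=7)
        b = permutation_test(dataset, k=30, d=4, C=0.5, n_perm=5, seed=7)
        assert 1 / 6 <= a.p_value <= 1.0
        assert np.array_equal(a.gr_permuted, b.gr_permuted)
        assert a.p_value == b.p_value

    def test_null_cohort_accuracy_near_chance(self):
        cfg = SimulationConfig(n_patients=8, n_controls=8, n_regions=15,
                               n_timepoints=120, seed=41)
        dataset = build_dataset(simulate_null_cohort(cfg))
        cv = loocv(dataset, k=20, d=3, C=0.5)
        assert 0.15 <= cv.metrics.gr <= 0.85  # binomial band for N=16
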