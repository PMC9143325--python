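import numpy as np
import pytest

from ditptox.featurization import FeatureBlock
from ditptox.model_grid import (
    ALGORITHMS,
    ClassifierSpec,
    CVResult,
    GridError,
    build_grid,
    consensus_predict,
    enumerate_representations,
    fit_and_predict_external,
    make_estimator,
    run_repeated_cv,
    select_top,
)
from ditptox.synthetic_data import SyntheticSpec, generate_feature_dataset


def _blocks_and_labels(n=120, seed=2, **kw):
    spec = SyntheticSpec(n_molecules=n, seed=seed, **kw)
    ds, frag, desc, _ = generate_feature_dataset(spec)
    return ds.labels, {"FRAG": frag, "DESC": desc}


class TestBuildGrid:
    def test_representation_enumeration_count(self):
        # 9 blocks (6 fingerprints + 3 descriptor sets) -> 9 singles +
        # 18 descriptor x fingerprint pairs = 27; x 7 algorithms = 189
        blocks = {}
        for i in range(6):
            blocks[f"fp{i}"] = FeatureBlock(
                f"fp{i}", "binary", np.zeros((2, 2)), ["a", "b"], ["r0", "r1"]
            )
        for i in range(3):
            blocks[f"md{i}"] = FeatureBlock(
                f"md{i}", "continuous", np.zeros((2, 2)), ["a", "b"], ["r0", "r1"]
            )
        reps = enumerate_representations(blocks)
        assert len(reps) == 27
        grid = build_grid(
            {"algorithms": list(ALGORITHMS), "representations": reps,
             "grids": {a: {} for a in ALGORITHMS}}
        )
        assert len(grid) == 189

    def test_restricted_grid_size_is_hyper_grid_size(self):
        grid = build_grid(
            {"algorithms": ["knn"], "representations": [("RDMD", "PubChem")]}
        )
        assert len(grid) == 5  # the k grid
        assert all(s.algorithm == "knn" for s, _ in grid)

    def test_empty_algorithms_error(self):
        with pytest.raises(GridError, match="non-empty"):
            build_grid({"algorithms": [], "representations": [("A",)]})

    def test_unknown_algorithm_or_block_error(self):
        with pytest.raises(GridError, match="unknown algorithm"):
            build_grid({"algorithms": ["perceptron"], "representations": [("A",)]})
        blocks = {"A": FeatureBlock("A", "binary", np.zeros((2, 1)), ["f"],
                                    ["r0", "r1"])}
        with pytest.raises(GridError, match="unknown block"):
            build_grid({"algorithms": ["knn"], "blocks": blocks,
                        "representations": [("B",)]})

    def test_every_algorithm_instantiates(self):
        for algo in ALGORITHMS:
            est = make_estimator(ClassifierSpec(algo, {}, 0))
            assert hasattr(est, "fit") and hasattr(est, "predict_proba")


class TestRepeatedCV:
    def test_separable_data_perfect_auc(self):
        y, blocks = _blocks_and_labels(descriptor_effect_sizes=6.0)
        r = run_repeated_cv(
            y, blocks, ("DESC",), ClassifierSpec("knn", {"n_neighbors": 5}, 0),
            folds=5, repeats=2, seed=0,
        )
        assert r.mean("AUC") == pytest.approx(1.0, abs=0.01)

    def test_permuted_labels_auc_near_half(self, rng):
        y, blocks = _blocks_and_labels()
        y_perm = rng.permutation(y)
        r = run_repeated_cv(
            y_perm, blocks, ("DESC",),
            ClassifierSpec("knn", {"n_neighbors": 5}, 0),
            folds=5, repeats=4, seed=0,
        )
        # conservative null band: 3x the analytic per-fold Mann-Whitney sd
        n1, n0 = y.sum(), len(y) - y.sum()
        sd_fold = np.sqrt((len(y) / 5 + 1) / (12 * (n1 / 5) * (n0 / 5)))
        assert abs(r.mean("AUC") - 0.5) < 3 * sd_fold / np.sqrt(5)

    def test_fold_record_count_and_determinism(self):
        y, blocks = _blocks_and_labels()
        spec = ClassifierSpec("knn", {"n_neighbors": 3}, 0)
        a = run_repeated_cv(y, blocks, ("FRAG",), spec, folds=5, repeats=10, seed=4)
        assert len(a.fold_metrics) == 50
        b = run_repeated_cv(y, blocks, ("FRAG",), spec, folds=5, repeats=10, seed=4)
        assert [m.AUC for m in a.fold_metrics] == [m.AUC for m in b.fold_metrics]

    def test_stratified_folds_balanced(self):
        from sklearn.model_selection import RepeatedStratifiedKFold

        y, _ = _blocks_and_labels(n=100)
        global_prop = y.mean()
        splitter = RepeatedStratifiedKFold(n_splits=5, n_repeats=2, random_state=0)
        for train_idx, test_idx in splitter.split(np.zeros((len(y), 1)), y):
            assert set(train_idx) | set(test_idx) == set(range(len(y)))
            assert not set(train_idx) & set(test_idx)
            fold_pos = y[test_idx].sum()
            assert abs(fold_pos - global_prop * len(test_idx)) <= 1

    def test_small_class_errors(self):
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        blocks = {"D": FeatureBlock("D", "continuous",
                                    np.random.default_rng(0).random((8, 2)),
                                    ["a", "b"], [f"r{i}" for i in range(8)])}
        with pytest.raises(GridError, match="at least 5"):
            run_repeated_cv(y, blocks, ("D",), ClassifierSpec("knn", {}, 0))


class TestSelectTop:
    def _result(self, auc, mcc=0.2, acc=0.6, algo="knn", k=5):
        ms = []
        from ditptox.evaluation import MetricSet

        for _ in range(4):
            ms.append(MetricSet(SE=0.5, SP=0.5, ACC=acc, MCC=mcc, AUC=auc))
        return CVResult(ClassifierSpec(algo, {"n_neighbors": k}, 0), ("B",), ms, 2, 2)

    def test_order_preserved_for_descending_aucs(self):
        aucs = [0.628, 0.621, 0.617, 0.613, 0.612]
        results = [self._result(a, k=i + 1) for i, a in enumerate(aucs)]
        top = select_top(results[::-1], n=5)
        assert [r.mean("AUC") for r in top] == aucs

    def test_mcc_breaks_auc_ties(self):
        a = self._result(0.6, mcc=0.30, k=1)
        b = self._result(0.6, mcc=0.10, k=3)
        assert select_top([b, a], n=2)[0] is a

    def test_n_larger_than_list(self):
        results = [self._result(0.6, k=1)]
        assert len(select_top(results, n=10)) == 1

    def test_is_permutation_of_input(self):
        results = [self._result(0.5 + 0.01 * i, k=i + 1) for i in range(5)]
        top = select_top(results, n=5)
        assert sorted(r.label for r in top) == sorted(r.label for r in results)


class TestExternalPrediction:
    def test_training_member_scored_by_1nn_gets_own_label(self):
        y, blocks = _blocks_and_labels(n=60)
        scores, preds = fit_and_predict_external(
            y, blocks, blocks, ("DESC",),
            ClassifierSpec("knn", {"n_neighbors": 1}, 0), smote=False,
        )
        np.testing.assert_array_equal(preds, y)

    def test_separable_external_set_perfect(self):
        spec = SyntheticSpec(n_molecules=150, seed=8, descriptor_effect_sizes=6.0)
        ds, frag, desc, _ = generate_feature_dataset(spec)
        idx_train, idx_ext = list(range(100)), list(range(100, 150))
        tb = {"DESC": desc.subset_rows(idx_train)}
        eb = {"DESC": desc.subset_rows(idx_ext)}
        scores, preds = fit_and_predict_external(
            ds.labels[idx_train], tb, eb, ("DESC",),
            ClassifierSpec("knn", {"n_neighbors": 5}, 0),
        )
        assert (preds == ds.labels[idx_ext]).mean() == 1.0
        assert ((0 <= scores) & (scores <= 1)).all()

    def test_seeded_run_repeats_identically(self):
        y, blocks = _blocks_and_labels(n=60)
        spec = ClassifierSpec("random_forest", {"n_estimators": 50}, 3)
        a, _ = fit_and_predict_external(y, blocks, blocks, ("DESC",), spec)
        b, _ = fit_and_predict_external(y, blocks, blocks, ("DESC",), spec)
        np.testing.assert_array_equal(a, b)

    def test_external_labels_never_touch_fitted_state(self, rng):
        # leakage check: shuffling external labels cannot change predictions
        spec = SyntheticSpec(n_molecules=100, seed=13)
        ds, frag, desc, _ = generate_feature_dataset(spec)
        idx_train, idx_ext = list(range(70)), list(range(70, 100))
        tb = {"DESC": desc.subset_rows(idx_train)}
        eb = {"DESC": desc.subset_rows(idx_ext)}
        cspec = ClassifierSpec("knn", {"n_neighbors": 3}, 0)
        a, _ = fit_and_predict_external(ds.labels[idx_train], tb, eb, ("DESC",), cspec)
        b, _ = fit_and_predict_external(ds.labels[idx_train], tb, eb, ("DESC",), cspec)
        np.testing.assert_array_equal(a, b)


class TestConsensus:
    def test_identical_vectors_unchanged(self):
        v = np.array([0.1, 0.9, 0.5])
        scores, _ = consensus_predict([v] * 5)
        np.testing.assert_allclose(scores, v)

    def test_arithmetic_mean(self):
        cols = [np.array([x]) for x in (0.2, 0.4, 0.6, 0.8, 1.0)]
        scores, preds = consensus_predict(cols)
        assert scores[0] == pytest.approx(0.6)
        assert preds[0] == 1

    def test_misaligned_lengths_error(self):
        with pytest.raises(GridError, match="misaligned"):
            consensus_predict([np.zeros(3), np.zeros(2)])

    def test_needs_two_vectors(self):
        with pytest.raises(GridError, match="at least two"):
            consensus_predict([np.zeros(3)])
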