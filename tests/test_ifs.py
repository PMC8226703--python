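import numpy as np
import pytest

from afpdomains import (
    ClassifierSpec,
    CVSpec,
    IFSRandomForest,
    evaluate_subset,
    ifs_search,
    load_model,
    make_folds,
    mrmr_rank,
    predict,
    save_model,
    train_final,
)
from afpdomains.mrmr import FeatureRanking

from conftest import make_matrix, random_binary_matrix

FAST_RF = ClassifierSpec(n_trees=25, seed=0)


def perfect_feature_matrix(rng, n_pos=12, n_neg=28, n_noise=6):
    """Column 0 equals the class indicator exactly; the rest is noise."""
    n = n_pos + n_neg
    y = np.array([1] * n_pos + [2] * n_neg)
    X = (rng.random((n, 1 + n_noise)) < 0.3).astype(np.int8)
    X[:, 0] = (y == 1).astype(np.int8)
    X[X.sum(axis=1) == 0, 1] = 1
    return make_matrix(X, y)


class TestMakeFolds:
    def test_small_stratified_example(self):
        # 20 samples, 4 positives, 10 folds: every fold holds 2 samples
        # and the positives land in 4 distinct folds
        y = np.array([1] * 4 + [2] * 16)
        folds = make_folds(y, CVSpec(k=10, seed=0))
        sizes = np.bincount(folds, minlength=10)
        assert (sizes == 2).all()
        assert len(set(folds[:4])) == 4

    def test_leave_one_out_boundary(self):
        y = np.array([1] * 3 + [2] * 7)
        folds = make_folds(y, CVSpec(k=10, seed=1))
        assert sorted(folds) == list(range(10))

    def test_fixed_seed_reproducible(self):
        y = np.array([1] * 10 + [2] * 40)
        a = make_folds(y, CVSpec(k=10, seed=7))
        b = make_folds(y, CVSpec(k=10, seed=7))
        assert np.array_equal(a, b)
        c = make_folds(y, CVSpec(k=10, seed=8))
        assert not np.array_equal(a, c)

    def test_every_sample_tested_exactly_once(self, rng):
        y = np.where(rng.random(73) < 0.2, 1, 2)
        folds = make_folds(y, CVSpec(k=10, seed=3))
        assert folds.shape == (73,)
        assert set(folds) <= set(range(10))

    def test_class_proportions_preserved_within_one(self, rng):
        y = np.array([1] * 30 + [2] * 170)
        folds = make_folds(y, CVSpec(k=10, seed=2))
        for f in range(10):
            pos = int((y[folds == f] == 1).sum())
            assert pos in (3,)  # 30 positives over 10 folds exactly
            assert (folds == f).sum() == 20

    def test_single_class_rejected_when_stratified(self):
        with pytest.raises(ValueError, match="both classes"):
            make_folds(np.full(20, 2), CVSpec(k=5, seed=0))

    def test_assignment_follows_row_ids_not_positions(self, rng):
        y = np.array([1] * 6 + [2] * 24)
        ids = [f"P{i:02d}" for i in range(30)]
        folds = make_folds(y, CVSpec(k=5, seed=4), row_ids=ids)
        perm = rng.permutation(30)
        folds_perm = make_folds(
            y[perm], CVSpec(k=5, seed=4), row_ids=[ids[i] for i in perm]
        )
        assert np.array_equal(folds_perm, folds[perm])


class TestEvaluateSubset:
    def test_perfectly_separating_feature_scores_ones(self, rng):
        matrix = perfect_feature_matrix(rng)
        ranking = mrmr_rank(matrix, top_n=3)
        assert ranking.indices[0] == 0
        ms = evaluate_subset(matrix, ranking, k=1, cspec=FAST_RF, vspec=CVSpec(k=10, seed=0))
        assert (ms.SN, ms.SP, ms.ACC, ms.MCC) == (1.0, 1.0, 1.0, 1.0)

    def test_zero_subset_size_rejected(self, rng):
        matrix = perfect_feature_matrix(rng)
        ranking = mrmr_rank(matrix, top_n=2)
        with pytest.raises(ValueError, match="k"):
            evaluate_subset(matrix, ranking, k=0)

    def test_label_permutation_destroys_signal(self):
        # Monte-Carlo null: with labels shuffled independently of the
        # features, cross-validated MCC hovers around 0.
        mccs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            matrix = random_binary_matrix(rng, 120, 8, density=0.25, pos_frac=0.25)
            perm = rng.permutation(matrix.n_proteins)
            shuffled = make_matrix(matrix.X.toarray(), matrix.labels[perm])
            ranking = mrmr_rank(shuffled, top_n=4)
            ms = evaluate_subset(
                shuffled, ranking, k=4, cspec=FAST_RF, vspec=CVSpec(k=10, seed=seed)
            )
            mccs.append(ms.MCC)
        assert abs(float(np.mean(mccs))) < 0.1
        assert max(np.abs(mccs)) < 0.45

    def test_per_fold_averaging_mode_runs(self, rng):
        matrix = perfect_feature_matrix(rng)
        ranking = mrmr_rank(matrix, top_n=1)
        ms = evaluate_subset(
            matrix, ranking, k=1, cspec=FAST_RF, vspec=CVSpec(k=5, seed=0),
            pooling="per_fold",
        )
        assert ms.MCC == pytest.approx(1.0)


class TestIFSSearch:
    def test_perfect_feature_gives_optimum_k_one(self, rng):
        matrix = perfect_feature_matrix(rng)
        ranking = mrmr_rank(matrix, top_n=5)
        result = ifs_search(matrix, ranking, k_max=5, cspec=FAST_RF, vspec=CVSpec(k=10, seed=0))
        assert result.optimum_k == 1
        assert result.optimum_metrics.MCC == 1.0
        assert len(result.optimum_features) == 1
        assert list(result.records["k"]) == [1, 2, 3, 4, 5]

    def test_monotone_redundant_curve_is_flat(self, rng):
        # columns 1..4 duplicate column 0 exactly: every subset presents
        # the forest with the same effective training view
        n = 50
        y = np.where(np.arange(n) % 5 == 0, 1, 2)
        base = ((y == 1) | (rng.random(n) < 0.1)).astype(np.int8)
        X = np.tile(base[:, None], (1, 5))
        matrix = make_matrix(X, y)
        ranking = FeatureRanking(
            indices=np.arange(5),
            accessions=[matrix.col_ids[i] for i in range(5)],
            scores=np.zeros(5),
            relevance=np.zeros(5),
            redundancy=np.zeros(5),
        )
        result = ifs_search(matrix, ranking, k_max=5, cspec=FAST_RF, vspec=CVSpec(k=5, seed=0))
        mcc = result.records["MCC"].to_numpy()
        assert np.ptp(mcc) < 0.15  # flat within CV noise

    def test_curve_invariant_to_row_order(self, rng):
        matrix = random_binary_matrix(rng, 60, 10, density=0.3, pos_frac=0.3)
        ranking = mrmr_rank(matrix, top_n=6)
        result = ifs_search(matrix, ranking, k_max=4, cspec=FAST_RF, vspec=CVSpec(k=5, seed=0))

        perm = rng.permutation(matrix.n_proteins)
        permuted = type(matrix)(
            matrix.X[perm],
            [matrix.row_ids[i] for i in perm],
            matrix.col_ids,
            matrix.labels[perm],
        )
        ranking_p = mrmr_rank(permuted, top_n=6)
        assert list(ranking_p.indices) == list(ranking.indices)
        result_p = ifs_search(permuted, ranking_p, k_max=4, cspec=FAST_RF, vspec=CVSpec(k=5, seed=0))
        assert result_p.records.equals(result.records)

    def test_k_max_validation(self, rng):
        matrix = perfect_feature_matrix(rng)
        ranking = mrmr_rank(matrix, top_n=3)
        with pytest.raises(ValueError, match="k_max"):
            ifs_search(matrix, ranking, k_max=4)


class TestFinalModel:
    def test_training_set_memorisation(self, rng):
        matrix = perfect_feature_matrix(rng)
        model = train_final(matrix, matrix.col_ids[:1], ClassifierSpec(n_trees=100, seed=0))
        pred = predict(model, matrix)
        assert np.array_equal(pred, matrix.labels)

    def test_save_load_round_trip(self, tmp_path, rng):
        matrix = random_binary_matrix(rng, 40, 8)
        model = train_final(matrix, matrix.col_ids[:3], FAST_RF)
        before = predict(model, matrix)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        after = predict(load_model(path), matrix)
        assert np.array_equal(before, after)

    def test_missing_feature_columns_listed(self, rng):
        matrix = random_binary_matrix(rng, 30, 4)
        model = train_final(matrix, matrix.col_ids[:2], FAST_RF)
        other = make_matrix(np.ones((3, 1), dtype=np.int8), [2, 2, 2], col_prefix="OTHER")
        with pytest.raises(ValueError, match=model.features[0]):
            predict(model, other)
        # permissive mode treats the missing domains as absent everywhere
        pred = predict(model, other, allow_missing=True)
        assert pred.shape == (3,)

    def test_all_zero_protein_prediction_deterministic(self, rng):
        matrix = perfect_feature_matrix(rng)
        model = train_final(matrix, matrix.col_ids[:2], FAST_RF)
        rows = make_matrix(
            np.array([[0, 0], [0, 0]], dtype=np.int8), [2, 2],
            col_prefix="X",
        )
        rows.col_ids = model.features[:2]
        a = predict(model, rows)
        b = predict(model, rows)
        assert np.array_equal(a, b)


class TestIFSRandomForestEstimator:
    def test_fit_predict_and_fitted_attributes(self, rng):
        matrix = perfect_feature_matrix(rng, n_pos=15, n_neg=45, n_noise=8)
        clf = IFSRandomForest(top_n=5, k_max=3, n_estimators=25, cv=5, random_state=0)
        clf.fit(matrix.X, matrix.labels)
        assert clf.optimum_k_ == 1
        assert clf.best_metrics_.MCC == 1.0
        assert set(clf.ifs_curve_.columns) == {"k", "SN", "SP", "ACC", "MCC"}
        pred = clf.predict(matrix.X)
        assert np.array_equal(pred, matrix.labels)
        proba = clf.predict_proba(matrix.X)
        assert proba.shape == (60, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        clf = IFSRandomForest(top_n=7, n_estimators=10)
        cloned = clone(clf)
        assert cloned.get_params()["top_n"] == 7
        cloned.set_params(top_n=3)
        assert cloned.top_n == 3

    def test_non_binary_labels_rejected(self, rng):
        X = (rng.random((30, 5)) < 0.5).astype(np.int8)
        X[X.sum(axis=1) == 0, 0] = 1
        y = rng.integers(0, 3, 30)
        with pytest.raises(ValueError, match="binary"):
            IFSRandomForest().fit(X, y)
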