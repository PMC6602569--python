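import numpy as np
import pytest

from allodriver.driver_model import (
    EnsembleConfig,
    LabeledDataset,
    ModelError,
    SmoteConfig,
    classify,
    cross_val_scores,
    load_model,
    save_model,
    score,
    score_components,
    smote_oversample,
    train,
    tune,
)
from allodriver.evaluation import roc_auc
from allodriver.synthetic_fixtures import SeparationSpec, gen_labeled_dataset


def _two_gaussians(n=40, sep=6.0, seed=0, d=4):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    X[: n // 2] += sep
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    return LabeledDataset(X, y)


def _imbalanced(n1=8, n0=40, seed=0, d=3):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(5.0, 1.0, size=(n1, d)), rng.normal(size=(n0, d))])
    y = np.array([1] * n1 + [0] * n0)
    return LabeledDataset(X, y)


class TestSmote:
    def test_noop_when_already_balanced(self):
        ds = _two_gaussians(20)
        out = smote_oversample(ds, SmoteConfig(seed=1))
        assert len(out.y) == len(ds.y)
        assert out.y.sum() == ds.y.sum()

    def test_two_point_minority_segment(self):
        X = np.vstack([np.zeros((10, 2)), [[0.0, 0.0], [1.0, 1.0]]])
        X[:10] += np.arange(10)[:, None] * 10 + 100  # majority far away
        y = np.array([0] * 10 + [1] * 2)
        out = smote_oversample(LabeledDataset(X, y), SmoteConfig(k_neighbors=1, seed=3))
        synth = out.X[12:]
        assert len(synth) == 8
        # every synthetic point lies on the segment between (0,0) and (1,1)
        residual = np.abs(synth[:, 0] - synth[:, 1])
        assert np.all(residual < 1e-9)
        assert np.all(synth >= 0.0) and np.all(synth <= 1.0)

    def test_counts_floor_of_target_ratio(self):
        ds = _imbalanced(n1=5, n0=23)
        out = smote_oversample(ds, SmoteConfig(target_ratio=0.7, seed=0))
        assert int(out.y.sum()) == int(np.floor(0.7 * 23))
        assert int((out.y == 0).sum()) == 23

    def test_majority_rows_bit_identical_and_first(self):
        ds = _imbalanced(seed=4)
        out = smote_oversample(ds, SmoteConfig(seed=4))
        maj = ds.X[ds.y == 0]
        assert np.array_equal(out.X[: len(maj)], maj)
        assert np.all(out.y[: len(maj)] == 0)

    def test_synthetic_points_in_minority_convex_hull_boxwise(self):
        ds = _imbalanced(n1=10, n0=60, seed=7)
        out = smote_oversample(ds, SmoteConfig(seed=7))
        minority = ds.X[ds.y == 1]
        synth = out.X[60 + 10 :]
        lo, hi = minority.min(axis=0), minority.max(axis=0)
        assert np.all(synth >= lo - 1e-12) and np.all(synth <= hi + 1e-12)

    def test_k_clipped_with_warning(self, caplog):
        ds = _imbalanced(n1=3, n0=20)
        with caplog.at_level("WARNING"):
            out = smote_oversample(ds, SmoteConfig(k_neighbors=10, seed=0))
        assert "clipped" in caplog.text
        assert int(out.y.sum()) == 20

    def test_minority_too_small_error(self):
        ds = LabeledDataset(np.zeros((5, 2)), np.array([1, 0, 0, 0, 0]))
        with pytest.raises(ModelError, match="minority"):
            smote_oversample(ds, SmoteConfig())

    def test_seeded_reproducible(self):
        ds = _imbalanced(seed=2)
        a = smote_oversample(ds, SmoteConfig(seed=9))
        b = smote_oversample(ds, SmoteConfig(seed=9))
        assert np.array_equal(a.X, b.X) and np.array_equal(a.y, b.y)


class TestTrainScore:
    def test_separable_training_auc_one(self):
        ds = _two_gaussians()
        model = train(ds, EnsembleConfig(seed=0), SmoteConfig(seed=0))
        assert roc_auc(score(model, ds.X), ds.y).auc == 1.0

    def test_same_seed_identical_serialized_model(self, tmp_path):
        ds = _imbalanced(seed=1)
        for i in (1, 2):
            m = train(ds, EnsembleConfig(seed=42), SmoteConfig(seed=42))
            save_model(m, tmp_path / f"m{i}.joblib")
        assert (tmp_path / "m1.joblib").read_bytes() == (tmp_path / "m2.joblib").read_bytes()

    def test_default_config_matches_published_hyperparameters(self):
        cfg = EnsembleConfig()
        assert (cfg.rf_max_depth, cfg.rf_n_trees, cfg.rf_feature_fraction) == (4, 130, 0.4)
        assert cfg.mlp_hidden == (20, 15)
        assert (cfg.mlp_lr, cfg.mlp_momentum) == (0.1, 0.8)
        assert cfg.threshold == 0.5

    def test_score_is_mean_of_branches(self):
        ds = _imbalanced(seed=3)
        model = train(ds, EnsembleConfig(seed=3), SmoteConfig(seed=3))
        rf_p, mlp_p = score_components(model, ds.X)
        assert np.allclose(score(model, ds.X), (rf_p + mlp_p) / 2.0, atol=0, rtol=0)

    def test_scores_bounded(self):
        ds = _imbalanced(seed=5)
        model = train(ds, EnsembleConfig(seed=5), SmoteConfig(seed=5))
        rng = np.random.default_rng(0)
        X = rng.normal(scale=10.0, size=(1000, ds.X.shape[1]))
        s = score(model, X)
        assert np.all((s >= 0.0) & (s <= 1.0))

    def test_single_class_error(self):
        ds = LabeledDataset(np.random.default_rng(0).normal(size=(10, 2)), np.ones(10, dtype=int))
        with pytest.raises(ModelError):
            train(ds)

    def test_non_finite_features_error(self):
        X = np.ones((6, 2))
        X[0, 0] = np.nan
        with pytest.raises(ModelError, match="finite"):
            train(LabeledDataset(X, np.array([1, 1, 1, 0, 0, 0])))

    def test_serialization_round_trip_bit_stable_scores(self, tmp_path):
        ds = _imbalanced(seed=6)
        model = train(ds, EnsembleConfig(seed=6), SmoteConfig(seed=6))
        path = tmp_path / "m.joblib"
        save_model(model, path)
        reloaded = load_model(path)
        assert np.array_equal(score(model, ds.X), score(reloaded, ds.X))

    def test_schema_mismatch_error(self):
        ds = _imbalanced(seed=0, d=3)
        model = train(ds, EnsembleConfig(seed=0), SmoteConfig(seed=0))
        with pytest.raises(ModelError, match="dimension"):
            score(model, np.zeros((1, 5)))


class TestClassify:
    @pytest.mark.parametrize("s,expected", [(0.51, True), (0.50, False), (0.0, False), (1.0, True)])
    def test_strict_threshold(self, s, expected):
        assert classify(s) is expected

    def test_out_of_range_error(self):
        with pytest.raises(ModelError):
            classify(1.2)


class TestCrossValidation:
    def test_fold_assignment_permutation_invariant(self):
        ds = _imbalanced(n1=10, n0=40, seed=8)
        cfg = EnsembleConfig(seed=2, rf_n_trees=20)
        s1, y1 = cross_val_scores(ds, cfg, SmoteConfig(seed=2), folds=5)
        perm = np.random.default_rng(1).permutation(len(ds.y))
        ds2 = LabeledDataset(ds.X[perm], ds.y[perm])
        s2, y2 = cross_val_scores(ds2, cfg, SmoteConfig(seed=2), folds=5)
        assert np.array_equal(s1, s2) and np.array_equal(y1, y2)

    def test_fewer_rows_than_folds_error(self):
        ds = _imbalanced(n1=2, n0=3)
        with pytest.raises(ModelError, match="folds"):
            cross_val_scores(ds, folds=10)


class TestTune:
    def test_degenerate_grid_returns_point(self):
        ds = _imbalanced(n1=6, n0=24, seed=9)
        grid = {"rf_max_depth": [3], "rf_n_trees": [15], "rf_feature_fraction": [0.5]}
        cfg = tune(ds, grid, folds=3, seed=1)
        assert (cfg.rf_max_depth, cfg.rf_n_trees, cfg.rf_feature_fraction) == (3, 15, 0.5)

    def test_argmax_over_grid(self):
        ds = gen_labeled_dataset(SeparationSpec(n_pos=12, n_neg=48, dprime=3.0, seed=2))
        grid = {"rf_n_trees": [10, 40]}
        best = tune(ds, grid, folds=3, seed=1)
        # the winner's CV AUC is >= every other grid point's, by recomputation
        aucs = {}
        for n in grid["rf_n_trees"]:
            cfg = EnsembleConfig(seed=1, rf_n_trees=n)
            s, y = cross_val_scores(ds, cfg, SmoteConfig(seed=1), folds=3)
            aucs[n] = roc_auc(s, y).auc
        assert aucs[best.rf_n_trees] == max(aucs.values())
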