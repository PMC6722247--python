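import numpy as np
import pytest

from metaborf import (ForestSpec, SyntheticConfig, cross_validate, generate_table,
                      train_forest)
from metaborf.forest import NEVER_OOB


def separable_data(n=30, p=8, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array(["resistant"] * (n // 2) + ["control"] * (n - n // 2))
    X = rng.normal(size=(n, p))
    X[:, 0] = np.where(y == "resistant", 2.0, -2.0)
    return X, y


class TestTrainForest:
    def test_separable_data_zero_oob_error_and_max_mda(self):
        X, y = separable_data()
        res = train_forest(X, y, ForestSpec(n_trees=300, seed=1))
        assert res.oob_error == 0.0
        assert res.mda.idxmax() == "f0"
        assert res.confusion.to_numpy().trace() == 30

    def test_deterministic_given_seed_and_distinct_across_seeds(self):
        X, y = separable_data(p=20, seed=3)
        X[:, 0] = np.random.default_rng(9).normal(size=30)  # remove the easy feature
        a = train_forest(X, y, ForestSpec(n_trees=100, seed=5))
        b = train_forest(X, y, ForestSpec(n_trees=100, seed=5))
        c = train_forest(X, y, ForestSpec(n_trees=100, seed=6))
        assert a.oob_error == b.oob_error
        assert (a.mda == b.mda).all()
        assert not (a.mda == c.mda).all()

    def test_input_validation(self):
        X, y = separable_data()
        with pytest.raises(ValueError, match="two classes"):
            train_forest(X, np.array(["a"] * 30), ForestSpec(n_trees=10))
        with pytest.raises(ValueError, match="n_trees"):
            train_forest(X, y, ForestSpec(n_trees=0))
        Xn = X.copy()
        Xn[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            train_forest(Xn, y, ForestSpec(n_trees=10))

    def test_never_oob_subjects_excluded_from_error(self):
        X, y = separable_data()
        res = train_forest(X, y, ForestSpec(n_trees=1, seed=2))
        # a single tree leaves most subjects in-bag, so some are never OOB
        assert NEVER_OOB in res.oob_predictions
        voted = sum(1 for p in res.oob_predictions if p != NEVER_OOB)
        assert 0 < voted < 30
        assert res.confusion.to_numpy().sum() == voted
        assert not np.isnan(res.oob_error)

    def test_oob_membership_fraction_near_theory(self):
        X, y = separable_data()
        n = len(y)
        res = train_forest(X, y, ForestSpec(n_trees=2000, seed=4),
                           compute_importance=False)
        expected = (1 - 1 / n) ** n  # -> e^-1 for large n
        observed = res.oob_counts.mean() / 2000
        assert abs(observed - expected) < 0.01

    def test_noise_feature_mda_near_zero(self):
        """Permutation importance of a feature unrelated to the labels is
        centred at zero across seeds."""
        vals = []
        for s in range(50):
            rng = np.random.default_rng(1500 + s)
            y = np.array(["a"] * 15 + ["b"] * 15)
            X = rng.normal(size=(30, 6))
            X[:, 0] = np.where(y == "a", 1.5, -1.5) + rng.normal(scale=0.5, size=30)
            res = train_forest(X, y, ForestSpec(n_trees=300, seed=s))
            vals.append(res.mda["f5"])
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) <= 3 * se

    def test_oob_error_converges_in_forest_size(self):
        cfg = SyntheticConfig(n_metabolites=30, n_informative=4, log2_fold_change=1.5,
                              n_blocks=0, missing_quantile=0.0, seed=11)
        table, _ = generate_table(cfg)
        X = np.log(table.matrix())
        y = table.group_labels.to_numpy()
        n = len(y)
        e4 = train_forest(X, y, ForestSpec(n_trees=10_000, seed=7),
                          compute_importance=False).oob_error
        e5 = train_forest(X, y, ForestSpec(n_trees=100_000, seed=8),
                          compute_importance=False).oob_error
        assert abs(e4 - e5) <= 0.5 / n

    def test_oob_error_matches_reference_forest(self):
        """Independent oracle: sklearn's random forest OOB score agrees
        within one subject on converged forests over 10 synthetic cohorts.
        Cohorts carry a decisive signal so per-subject vote margins are
        away from 50% — near-tied subjects measure tie-breaking luck,
        not implementation agreement."""
        from sklearn.ensemble import RandomForestClassifier

        for s in range(10):
            cfg = SyntheticConfig(n_metabolites=40, n_informative=8,
                                  log2_fold_change=2.0, n_blocks=0,
                                  missing_quantile=0.0, seed=100 + s)
            table, _ = generate_table(cfg)
            X = np.log(table.matrix())
            y = table.group_labels.to_numpy()
            ours = train_forest(X, y, ForestSpec(n_trees=20_000, seed=s),
                                compute_importance=False)
            ref = RandomForestClassifier(n_estimators=3000, oob_score=True,
                                         random_state=s, n_jobs=1)
            ref.fit(X, y)
            assert abs(ours.oob_accuracy - ref.oob_score_) <= 1 / len(y) + 1e-9

    def test_scaled_mda_preserves_strong_ranking(self):
        X, y = separable_data()
        res = train_forest(X, y, ForestSpec(n_trees=500, seed=1))
        assert res.mda_scaled.idxmax() == "f0"


class TestCrossValidate:
    def test_separable_data_perfect_accuracy(self):
        X, y = separable_data()
        # single separating feature: every tree reproduces the labels
        cv = cross_validate(X[:, :1], y, ForestSpec(n_trees=100, seed=1), folds=5, seed=3)
        assert cv.mean_accuracy == 1.0
        assert cv.fold_accuracies == [1.0] * 5

    def test_stratified_folds_hold_out_three_per_class(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.array(["a"] * 15 + ["b"] * 15)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        for _, te in skf.split(np.zeros((30, 1)), y):
            held = y[te]
            assert (held == "a").sum() == 3 and (held == "b").sum() == 3

    def test_too_many_folds_rejected(self):
        X, y = separable_data()
        with pytest.raises(ValueError, match="stratify"):
            cross_validate(X, y, ForestSpec(n_trees=10), folds=20, seed=0)

    def test_deterministic_given_seed(self):
        X, y = separable_data(p=20, seed=5)
        X[:, 0] = np.random.default_rng(2).normal(size=30)
        a = cross_validate(X, y, ForestSpec(n_trees=200, seed=1), folds=5, seed=9)
        b = cross_validate(X, y, ForestSpec(n_trees=200, seed=1), folds=5, seed=9)
        assert a.fold_accuracies == b.fold_accuracies
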