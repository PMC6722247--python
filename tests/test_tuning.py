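import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metaborf import (CvScan, choose_forest_size, cv_scan, forest_size_grid,
                      impute_minimum, profile_hamming, stability_scan)

from test_forest import separable_data


class TestForestSizeGrid:
    def test_canonical_grid(self):
        grid = forest_size_grid()
        assert list(grid) == [1, 3, 10, 32, 100, 316, 1000, 3162, 10000, 31623,
                              100000, 316228, 1000000]
        assert len(grid) == 13

    def test_truncation(self):
        grid = forest_size_grid(max_exponent=2.0)
        assert list(grid) == [1, 3, 10, 32, 100]

    def test_rejects_bad_grids(self):
        from metaborf import ForestSizeGrid

        with pytest.raises(ValueError):
            ForestSizeGrid(sizes=(10, 5))
        with pytest.raises(ValueError):
            ForestSizeGrid(sizes=())


class TestProfileHamming:
    universe = [f"m{j}" for j in range(100)]

    def test_examples(self):
        a = set(self.universe[:30])
        b = set(self.universe[30:60])
        shares25 = set(self.universe[:25]) | set(self.universe[60:65])
        assert profile_hamming(a, a, self.universe) == 0
        assert profile_hamming(a, b, self.universe) == 60
        assert profile_hamming(a, shares25, self.universe) == 10

    def test_member_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            profile_hamming({"m1"}, {"zzz"}, self.universe)

    @given(
        a=st.sets(st.integers(0, 30), max_size=20),
        b=st.sets(st.integers(0, 30), max_size=20),
        c=st.sets(st.integers(0, 30), max_size=20),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_metric_properties(self, a, b, c):
        uni = range(31)
        dab = profile_hamming(a, b, uni)
        assert dab == profile_hamming(b, a, uni)  # symmetry
        assert (dab == 0) == (a == b)  # identity of indiscernibles
        assert dab <= profile_hamming(a, c, uni) + profile_hamming(c, b, uni)


class TestStabilityScan:
    def test_degenerate_universe_forces_identical_profiles(self):
        X, y = separable_data(p=3)
        grid = forest_size_grid(max_exponent=1.0)
        scan = stability_scan(X, y, grid, n_replicates=4, top_fraction=1.0,
                              base_seed=0)
        assert (scan.records["mean_pairwise_hamming"] == 0).all()
        assert (scan.records["n_unique_members"] == 3).all()
        assert scan.profile_size == 3

    def test_pair_count_and_unique_equivalence(self, planted_table):
        table, _ = planted_table
        imp = impute_minimum(table)
        grid = forest_size_grid(max_exponent=1.0)
        scan = stability_scan(imp.abundances, table.group_labels, grid,
                              n_replicates=5, base_seed=3)
        for size in grid:
            assert len(scan.profiles[size]) == 5  # C(5,2)=10 pairwise distances
            rec = scan.records.loc[size]
            identical = rec["n_unique_members"] == scan.profile_size
            assert identical == (rec["mean_pairwise_hamming"] == 0)
            assert scan.profile_size <= rec["n_unique_members"] <= 5 * scan.profile_size

    def test_deterministic(self, planted_table):
        table, _ = planted_table
        imp = impute_minimum(table)
        grid = forest_size_grid(max_exponent=0.5)
        s1 = stability_scan(imp.abundances, table.group_labels, grid,
                            n_replicates=3, base_seed=1)
        s2 = stability_scan(imp.abundances, table.group_labels, grid,
                            n_replicates=3, base_seed=1)
        pd.testing.assert_frame_equal(s1.records, s2.records)


class TestCvScan:
    def test_separable_data_perfect_at_every_size(self):
        X, y = separable_data()
        grid = forest_size_grid(max_exponent=1.5)
        # single separating feature: even a 1-tree forest is perfect
        scan = cv_scan(X[:, :1], y, grid, n_replicates=3, base_seed=2)
        assert (scan.records["accuracy_mean"] == 1.0).all()
        assert (scan.records["accuracy_sd"] == 0.0).all()

    def test_deterministic(self):
        X, y = separable_data(p=10, seed=4)
        X[:, 0] = np.random.default_rng(0).normal(size=30)
        grid = forest_size_grid(max_exponent=1.0)
        a = cv_scan(X, y, grid, n_replicates=3, base_seed=5)
        b = cv_scan(X, y, grid, n_replicates=3, base_seed=5)
        pd.testing.assert_frame_equal(a.records, b.records)


class TestChooseForestSize:
    @staticmethod
    def _scan(rows, reps=None):
        records = pd.DataFrame(rows).set_index("size")
        return CvScan(records=records, replicate_accuracies=reps or {},
                      fold_accuracies={})

    def test_single_size(self):
        scan = self._scan([{"size": 10, "accuracy_mean": 0.8, "accuracy_sd": 0.1}])
        assert choose_forest_size(scan, tolerance=0.0) == 10

    def test_equal_means_pick_lower_sd(self):
        scan = self._scan([
            {"size": 10, "accuracy_mean": 0.90, "accuracy_sd": 0.05},
            {"size": 100, "accuracy_mean": 0.90, "accuracy_sd": 0.01},
        ])
        assert choose_forest_size(scan, tolerance=0.0) == 100

    def test_tolerance_admits_lower_sd_runner_up(self):
        scan = self._scan([
            {"size": 10, "accuracy_mean": 0.93, "accuracy_sd": 0.04},
            {"size": 100, "accuracy_mean": 0.92, "accuracy_sd": 0.01},
        ])
        assert choose_forest_size(scan, tolerance=0.02) == 100

    def test_remaining_tie_prefers_smaller_size(self):
        scan = self._scan([
            {"size": 10, "accuracy_mean": 0.9, "accuracy_sd": 0.02},
            {"size": 100, "accuracy_mean": 0.9, "accuracy_sd": 0.02},
        ])
        assert choose_forest_size(scan, tolerance=0.0) == 10

    def test_default_tolerance_uses_se_of_best(self):
        scan = self._scan(
            [
                {"size": 10, "accuracy_mean": 0.93, "accuracy_sd": 0.002},
                {"size": 100, "accuracy_mean": 0.931, "accuracy_sd": 0.02},
            ],
            reps={100: [0.91, 0.93, 0.95, 0.93]},
        )
        # SE of best (~0.008) admits size 10, whose SD is far smaller
        assert choose_forest_size(scan) == 10

    def test_empty_scan_rejected(self):
        scan = CvScan(records=pd.DataFrame(columns=["accuracy_mean", "accuracy_sd"]),
                      replicate_accuracies={}, fold_accuracies={})
        with pytest.raises(ValueError, match="empty"):
            choose_forest_size(scan)
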