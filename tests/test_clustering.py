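import itertools

import numpy as np
import pandas as pd
import pytest

from metaborf import (SyntheticConfig, average_linkage, cluster_both_axes,
                      correlation_distance_matrix, cut_at_threshold, cut_into_k,
                      generate_table, spearman_distance_matrix)


def naive_upgma(D):
    """Brute-force UPGMA oracle: clusters as explicit index sets, mean
    cross-pair distance recomputed from the original matrix at every step."""
    D = np.asarray(D, dtype=float)
    clusters = [frozenset([i]) for i in range(D.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = np.mean([D[i, j] for i in a for j in b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
        heights.append(d)
    return heights


class TestSpearmanDistance:
    def test_self_distance_zero(self):
        x = np.random.default_rng(0).normal(size=(4, 10))
        d = spearman_distance_matrix(x)
        assert np.allclose(np.diag(d), 0.0)

    def test_anti_monotone_pair_distance_two(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0], [8.0, 6.0, 4.0, 2.0]])
        d = spearman_distance_matrix(x)
        assert d.iloc[0, 1] == pytest.approx(2.0)

    def test_known_rank_correlation(self):
        x = np.array([[1.0, 2.0, 3.0], [10.0, 30.0, 20.0]])
        d = spearman_distance_matrix(x)
        assert d.iloc[0, 1] == pytest.approx(0.5)  # rho = 0.5 for (1,2,3) vs (1,3,2)

    def test_constant_item_named(self):
        x = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            spearman_distance_matrix(x)


class TestCorrelationDistance:
    def test_identical_profiles_distance_zero(self):
        base = np.random.default_rng(1).normal(size=10)
        x = np.vstack([base, base * 3.0 + 1.0, np.random.default_rng(2).normal(size=10)])
        d = correlation_distance_matrix(x, mode="profile")
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_sign_flipped_profiles_distance_two(self):
        base = np.random.default_rng(3).normal(size=12)
        x = np.vstack([base, -base])
        d = correlation_distance_matrix(x, mode="direct")
        assert d.iloc[0, 1] == pytest.approx(2.0)

    def test_planted_two_block_structure_separates(self):
        cfg = SyntheticConfig(n_metabolites=20, n_informative=0, n_blocks=2,
                              block_size=10, block_rho=0.9, missing_quantile=0.0,
                              n_case=30, n_control=30, seed=4)
        table, truth = generate_table(cfg)
        x = np.log(table.matrix()).T  # metabolites x subjects
        for mode in ("profile", "direct"):
            d = correlation_distance_matrix(x, mode=mode).to_numpy()
            blocks = np.array([truth.block_assignments[m] for m in table.metabolite_ids])
            same = d[np.ix_(blocks == 0, blocks == 0)]
            cross = d[np.ix_(blocks == 0, blocks == 1)]
            assert same[np.triu_indices_from(same, 1)].max() < cross.min()


class TestAverageLinkage:
    def test_two_items_single_merge(self):
        d = np.array([[0.0, 0.4], [0.4, 0.0]])
        dend = average_linkage(d)
        assert dend.merge_heights.tolist() == [0.4]

    def test_three_item_mean_merge(self):
        d = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
        dend = average_linkage(d)
        assert np.allclose(dend.merge_heights, [0.2, 0.6])

    def test_matches_naive_oracle_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for n in (3, 4, 5, 6):
            for _ in range(10):
                vals = rng.uniform(0.1, 1.0, size=n * (n - 1) // 2)
                from scipy.spatial.distance import squareform

                D = squareform(vals)
                dend = average_linkage(D)
                assert np.allclose(np.sort(dend.merge_heights), naive_upgma(D))

    def test_heights_monotone_nondecreasing(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            x = rng.normal(size=(10, 8))
            d = spearman_distance_matrix(x)
            dend = average_linkage(d)
            assert (np.diff(dend.merge_heights) >= -1e-12).all()

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            average_linkage(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="non-negative"):
            average_linkage(np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            average_linkage(np.array([[1.0, 1.0], [1.0, 0.0]]))


class TestCuts:
    @pytest.fixture
    def dend(self):
        x = np.random.default_rng(7).normal(size=(12, 15))
        return average_linkage(spearman_distance_matrix(x))

    def test_below_all_heights_all_singletons(self, dend):
        cut = cut_at_threshold(dend, dend.merge_heights.min() / 2)
        assert cut.n_clusters == dend.n_items
        assert cut.n_multimember == 0

    def test_above_root_single_cluster(self, dend):
        cut = cut_at_threshold(dend, dend.merge_heights.max() + 1)
        assert cut.n_clusters == 1
        assert cut.n_multimember == 1

    def test_count_non_increasing_in_threshold(self, dend):
        thresholds = np.linspace(0, dend.merge_heights.max() + 0.1, 20)
        counts = [cut_at_threshold(dend, t).n_clusters for t in thresholds]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_cophenetic_consistency(self, dend):
        t = float(np.median(dend.merge_heights))
        cut = cut_at_threshold(dend, t)
        coph = dend.cophenetic_matrix()
        for i in dend.item_ids:
            for j in dend.item_ids:
                if i == j:
                    continue
                same = cut.assignments[i] == cut.assignments[j]
                assert same == (coph.loc[i, j] <= t)


class TestBothAxesAndExport:
    def test_subject_permutation_invariance(self):
        cfg = SyntheticConfig(n_metabolites=15, n_informative=4, n_blocks=0,
                              missing_quantile=0.0, seed=8)
        table, _ = generate_table(cfg)
        x = np.log(table.abundances).T
        _, subj = cluster_both_axes(x)
        perm = list(reversed(x.columns))
        _, subj_p = cluster_both_axes(x.loc[:, perm])
        c1 = subj.cophenetic_matrix().loc[subj.item_ids, subj.item_ids]
        c2 = subj_p.cophenetic_matrix().loc[subj.item_ids, subj.item_ids]
        assert np.allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-10)

    def test_duplicate_item_merges_first_at_zero(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(5, 10))
        x = np.vstack([x, x[0]])  # item 5 duplicates item 0
        dend = average_linkage(spearman_distance_matrix(x))
        assert dend.merge_heights[0] == pytest.approx(0.0, abs=1e-12)
        first_merge = dend.linkage[0, :2].astype(int).tolist()
        assert sorted(first_merge) == [0, 5]

    def test_newick_round_trip_preserves_cophenetic_distances(self, tmp_path):
        import dendropy

        x = np.random.default_rng(10).normal(size=(6, 12))
        d = spearman_distance_matrix(
            pd.DataFrame(x, index=[f"item{i}" for i in range(6)]))
        dend = average_linkage(d)
        path = tmp_path / "tree.nwk"
        dend.to_newick(path)
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        coph = dend.cophenetic_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i in dend.item_ids:
            for j in dend.item_ids:
                if i < j:
                    assert pdm.patristic_distance(taxa[i], taxa[j]) == pytest.approx(
                        coph.loc[i, j], abs=1e-6)

    def test_subject_axis_two_cut_recovers_groups(self):
        from sklearn.metrics import adjusted_rand_score

        from metaborf import impute_minimum, log_transform

        cfg = SyntheticConfig(n_metabolites=60, n_informative=20, log2_fold_change=2.0,
                              n_blocks=0, missing_quantile=0.10, seed=11)
        table, truth = generate_table(cfg)
        logged = log_transform(impute_minimum(table))
        x_ref = logged.abundances.loc[:, sorted(truth.informative_ids)]
        _, subj = cluster_both_axes(x_ref.T)
        cut = cut_into_k(subj, 2)
        y = table.group_labels.loc[cut.assignments.index]
        assert adjusted_rand_score(y.to_numpy(), cut.assignments.to_numpy()) >= 0.8
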