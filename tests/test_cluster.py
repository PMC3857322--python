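"""Spearman distances, complete-linkage trees, cluster composition and maps."""

import numpy as np
import pytest
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

from reliacase import cluster as clu

from conftest import make_tiny_dataset


class TestSpearmanDistance:
    def test_monotone_transform_distance_zero(self):
        x = np.array([0.3, -1.2, 2.4, 0.9, -0.1, 1.1])
        X = np.vstack([x, np.exp(x)])  # strictly increasing transform
        d = clu.spearman_distance(X)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_anticorrelation_distance_two(self):
        x = np.arange(6.0)
        d = clu.spearman_distance(np.vstack([x, -x]))
        assert d[0] == pytest.approx(2.0, abs=1e-12)

    def test_hand_rank_example(self):
        # x=(1,2,3,4), y=(1,3,2,4): sum d^2 = 2 -> rho = 1 - 12/60 = 0.8
        d = clu.spearman_distance(np.array([[1.0, 2, 3, 4], [1.0, 3, 2, 4]]))
        assert d[0] == pytest.approx(0.2, abs=1e-12)

    def test_matches_scipy_spearmanr_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5, 40))
        d = clu.spearman_distance(X)
        rho_oracle, _ = stats.spearmanr(X.T)
        iu = np.triu_indices(5, k=1)
        assert np.allclose(d, 1.0 - rho_oracle[iu], atol=1e-12)

    def test_constant_subject_named(self):
        X = np.vstack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValueError, match="dd99"):
            clu.spearman_distance(X, subject_ids=["dd01", "dd99"])

    def test_monotone_invariance_per_subject(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((4, 30))
        transformed = np.vstack([np.tanh(X[0]), X[1] ** 3, 5 * X[2] + 1, np.exp(X[3])])
        assert np.allclose(clu.spearman_distance(X),
                           clu.spearman_distance(transformed), atol=1e-10)


class TestCompleteLinkage:
    def test_forced_merge_order(self):
        # AB closest -> first merge {A,B} at 0.1, final merge at max = 1.0
        dist = np.array([0.1, 1.0, 1.0])  # AB, AC, BC
        tree = clu.complete_linkage_tree(dist)
        assert tree[0, 2] == pytest.approx(0.1)
        assert tree[1, 2] == pytest.approx(1.0)
        assert {int(tree[0, 0]), int(tree[0, 1])} == {0, 1}

    def test_equidistant_points_equal_heights(self):
        n = 5
        dist = np.full(n * (n - 1) // 2, 0.7)
        tree = clu.complete_linkage_tree(dist)
        assert np.allclose(tree[:, 2], 0.7)

    def test_cophenetic_dominance(self):
        # complete linkage: cophenetic distances >= original, elementwise
        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 25))
        d = clu.spearman_distance(X)
        tree = clu.complete_linkage_tree(d)
        coph = hierarchy.cophenet(tree)
        assert np.all(coph >= d - 1e-12)


class TestCutAndCharacterize:
    def test_k_equals_n_singletons(self):
        ds = make_tiny_dataset(n_dd=3, n_td=3, dims=(4, 4, 4), seed=0)
        X = ds.averaged("comparison").reshape(6, -1)
        tree = clu.complete_linkage_tree(clu.spearman_distance(X))
        res = clu.cut_and_characterize(tree, 6, ds.subjects)
        assert len(res.composition) == 6
        assert (res.composition["n"] == 1).all()

    def test_k_one_full_sample_descriptives(self):
        ds = make_tiny_dataset(n_dd=3, n_td=3, dims=(4, 4, 4), seed=0)
        X = ds.averaged("comparison").reshape(6, -1)
        tree = clu.complete_linkage_tree(clu.spearman_distance(X))
        res = clu.cut_and_characterize(tree, 1, ds.subjects)
        row = res.composition.iloc[0]
        ages = np.array([s.age_months for s in ds.subjects]) / 12.0
        assert row["n"] == 6 and row["n_dd"] == 3
        assert row["age_mean_y"] == pytest.approx(ages.mean())

    def test_k_out_of_range(self):
        tree = clu.complete_linkage_tree(np.array([0.1, 0.2, 0.3]))
        with pytest.raises(ValueError, match="k must be"):
            clu.cut_and_characterize(tree, 4, [None] * 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_partition_recovered(self, seed):
        # two groups sharing distinct patterns: ARI > 0.9 at k = 2
        rng = np.random.default_rng(seed)
        n_half, n_vox = 8, 400
        pattern_a = rng.standard_normal(n_vox) * 2
        pattern_b = rng.standard_normal(n_vox) * 2
        X = np.vstack([pattern_a + rng.standard_normal(n_vox) for _ in range(n_half)]
                      + [pattern_b + rng.standard_normal(n_vox) for _ in range(n_half)])
        tree = clu.complete_linkage_tree(clu.spearman_distance(X))
        labels = hierarchy.fcluster(tree, t=2, criterion="maxclust")
        truth = [0] * n_half + [1] * n_half
        assert adjusted_rand_score(truth, labels) > 0.9

    def test_subject_permutation_permutes_assignments(self):
        ds = make_tiny_dataset(n_dd=4, n_td=4, dims=(5, 5, 5), seed=3)
        res1 = clu.cluster_subjects(ds, np.ones((5, 5, 5), bool), "comparison", 3)
        perm = np.random.default_rng(0).permutation(8)
        ds2 = make_tiny_dataset(n_dd=4, n_td=4, dims=(5, 5, 5), seed=3)
        ds2.betas = ds.betas[perm]
        ds2.subjects = [ds.subjects[i] for i in perm]
        res2 = clu.cluster_subjects(ds2, np.ones((5, 5, 5), bool), "comparison", 3)
        # same partition of subject ids regardless of row order
        def parts(res, ds_):
            return {frozenset(np.array(ds_.subject_ids)[res.assignments == c])
                    for c in set(res.assignments)}
        assert parts(res1, ds) == parts(res2, ds2)

    def test_identical_tasks_match_single_task_tree(self):
        ds = make_tiny_dataset(n_dd=4, n_td=4, dims=(5, 5, 5), seed=4)
        ds.betas[:, 1] = ds.betas[:, 0]  # calculation == comparison
        mask = np.ones((5, 5, 5), bool)
        single = clu.cluster_subjects(ds, mask, "comparison", 2)
        concat = clu.cluster_subjects(ds, mask, "concatenated", 2)
        assert np.allclose(single.tree, concat.tree)


class TestClusterGroupMaps:
    def test_direct_contrast_refused_without_override(self):
        ds = make_tiny_dataset(dims=(4, 4, 4))
        with pytest.raises(ValueError, match="circular"):
            clu.cluster_group_maps(ds, np.ones(6, dtype=int), "comparison",
                                   np.ones((4, 4, 4), bool), direct_contrast=True)

    def test_positive_subjects_give_positive_map(self):
        ds = make_tiny_dataset(n_dd=3, n_td=3, dims=(4, 4, 4), sigma_b=0.1,
                               sigma_e=0.1, seed=5)
        ds.betas += 10.0
        maps = clu.cluster_group_maps(ds, np.ones(6, dtype=int), "comparison",
                                      np.ones((4, 4, 4), bool))
        assert (maps[1].t > 0).all()

    def test_small_cluster_skipped(self, caplog):
        ds = make_tiny_dataset(n_dd=3, n_td=3, dims=(4, 4, 4), seed=6)
        assignments = np.array([1, 1, 1, 1, 2, 2])  # cluster 2 below min size
        maps = clu.cluster_group_maps(ds, assignments, "comparison",
                                      np.ones((4, 4, 4), bool))
        assert 1 in maps and 2 not in maps


def test_suggest_k_finds_big_gap():
    # three tight triplets far apart -> largest merge gap at k = 3
    rng = np.random.default_rng(7)
    # equilateral triangle of tight triplets: both top merges ~10 apart,
    # so the dominant height gap separates 3 clusters from the noise level
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 8.66]])
    pts = np.vstack([c + 0.1 * rng.standard_normal((3, 2)) for c in centers])
    from scipy.spatial.distance import pdist
    tree = clu.complete_linkage_tree(pdist(pts))
    assert clu.suggest_k(tree) == 3
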