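"""Variance partitioning: hand-worked examples, ANOVA identity, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist

from specvar import (
    CommunityGrid,
    FeatureMatrix,
    ValidationError,
    alpha_partition,
    beta_partition,
    fit_pca,
    gamma_partition,
    make_community_grid,
    merge_regions,
    partition_all,
    rarefied_partition,
    scaled_diversity_summary,
    transform_pca,
)


def two_by_two_grid():
    return CommunityGrid(assignment=np.array([0, 0, 1, 1]), q=2, m=2)


class TestCommunityGrid:
    def test_25x25_image_5px_plots(self):
        coords = np.argwhere(np.ones((25, 25), dtype=bool))
        grid, kept, counts = make_community_grid(coords, 5, (25, 25))
        assert grid.q == 25
        assert kept.all()
        assert (counts == 25).all()
        assert grid.m == 25

    def test_neon_scene_40px_plots(self):
        # 280 x 1000 px scene, 40 px plots -> 7 x 25 complete plots
        coords = np.array([[0, 0]])
        grid, _, _ = make_community_grid(coords, 40, (280, 1000))
        assert grid.q == 7 * 25 == 175

    def test_edge_strips_discarded(self):
        coords = np.argwhere(np.ones((10, 10), dtype=bool))
        grid, kept, counts = make_community_grid(coords, 3, (10, 10))
        assert grid.q == 9
        assert kept.sum() == 81  # 19 edge pixels dropped
        assert (counts == 9).all()

    def test_row_major_labeling(self):
        coords = np.array([[0, 0], [0, 3], [3, 0], [3, 3]])
        grid, kept, _ = make_community_grid(coords, 3, (6, 6))
        assert grid.assignment.tolist() == [0, 1, 2, 3]

    def test_image_smaller_than_plot_rejected(self):
        with pytest.raises(ValidationError):
            make_community_grid(np.array([[0, 0]]), 5, (4, 4))


class TestGammaPartition:
    def test_single_feature_hand_example(self):
        # {0, 2, 0, 2}: mean 1, every deviation 1 -> SS 4, each pixel 25%
        ss, sd, lcsd, fcsd, ss_j, ss_i = gamma_partition(
            np.array([[0.0], [2.0], [0.0], [2.0]])
        )
        assert ss == 4.0
        assert sd == pytest.approx(4 / 3)
        np.testing.assert_allclose(lcsd, 0.25)
        np.testing.assert_allclose(fcsd, [1.0])

    def test_identical_rows_zero_variance(self):
        ss, sd, lcsd, fcsd, _, _ = gamma_partition(np.ones((5, 3)))
        assert ss == 0.0 and sd == 0.0
        assert lcsd is None and fcsd is None

    def test_pairwise_distance_oracle(self, rng):
        # SS equals the mean squared pairwise Euclidean distance identity
        for n, p in [(20, 3), (100, 5), (200, 8)]:
            Y = rng.normal(size=(n, p))
            ss = gamma_partition(Y)[0]
            oracle = (pdist(Y) ** 2).sum() / n
            assert abs(ss - oracle) < 1e-9 * oracle

    def test_permutation_leaves_ss_exactly_unchanged(self, rng):
        Y = rng.normal(size=(60, 4))
        perm = rng.permutation(60)
        assert gamma_partition(Y)[0] == gamma_partition(Y[perm])[0]


class TestBetaAlphaPartition:
    def test_pure_between_groups(self):
        # {0,0,2,2} grouped {1,2},{3,4}: centroids 0 and 2, all SS among
        Y = np.array([[0.0], [0.0], [2.0], [2.0]])
        grid = two_by_two_grid()
        ss_b, sd_b, ss_beta_k, lcsd_b, fcsd_b, cents = beta_partition(Y, grid)
        assert ss_b == 4.0
        np.testing.assert_allclose(cents.means, [[0.0], [2.0]])
        np.testing.assert_allclose(lcsd_b, [0.5, 0.5])
        ss_a = alpha_partition(Y, grid, cents)[0]
        assert ss_a == 0.0

    def test_pure_within_groups(self):
        # {0,2,0,2} grouped {1,2},{3,4}: both centroids at the grand mean
        Y = np.array([[0.0], [2.0], [0.0], [2.0]])
        grid = two_by_two_grid()
        ss_b, _, _, lcsd_b, _, cents = beta_partition(Y, grid)
        assert ss_b == 0.0
        assert lcsd_b is None
        assert alpha_partition(Y, grid, cents)[0] == 4.0

    def test_identical_communities_zero_beta(self, rng):
        block = rng.normal(size=(5, 3))
        Y = np.vstack([block, block, block])
        grid = CommunityGrid(assignment=np.repeat([0, 1, 2], 5), q=3, m=5)
        assert beta_partition(Y, grid)[0] == pytest.approx(0.0, abs=1e-12)

    def test_unequal_m_instructs_rarefaction(self):
        Y = np.arange(5.0)[:, None]
        grid = CommunityGrid(assignment=np.array([0, 0, 0, 1, 1]), q=2)
        with pytest.raises(ValidationError, match="rarefied_partition"):
            beta_partition(Y, grid)

    def test_single_community_alpha(self):
        # {0,2} in one community: centroid 1, SS 2, SD 2
        Y = np.array([[0.0], [2.0]])
        grid = CommunityGrid(assignment=np.array([0, 0]), q=1, m=2)
        _, _, _, _, _, cents = beta_partition(Y, grid)
        ss_a, ss_alpha_k, sd_alpha_k, _, _ = alpha_partition(Y, grid, cents)
        assert ss_a == 2.0
        np.testing.assert_allclose(sd_alpha_k, [2.0])

    def test_identical_pixels_in_community_fcsd_undefined(self):
        Y = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0], [2.0, 1.0]])
        grid = two_by_two_grid()
        _, _, _, _, _, cents = beta_partition(Y, grid)
        ss_a, ss_alpha_k, sd_alpha_k, _, fcsd_a = alpha_partition(Y, grid, cents)
        assert ss_alpha_k[0] == 0.0 and sd_alpha_k[0] == 0.0
        assert np.isnan(fcsd_a[0]).all()
        np.testing.assert_allclose(fcsd_a[1].sum(), 1.0)


class TestPartitionAll:
    def test_combined_hand_example(self):
        Y = np.array([[0.0], [0.0], [2.0], [2.0]])
        part = partition_all(Y, two_by_two_grid())
        assert part.ss_gamma == 4.0
        assert part.ss_beta == 4.0
        assert part.ss_alpha == 0.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_additivity_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        q = rng.integers(2, 7)
        m = rng.integers(2, 11)
        p = rng.integers(1, 5)
        Y = rng.normal(size=(q * m, p)) * rng.uniform(0.1, 10)
        grid = CommunityGrid(
            assignment=rng.permutation(np.repeat(np.arange(q), m)), q=q, m=m
        )
        part = partition_all(Y, grid)
        assert abs(part.ss_gamma - (part.ss_beta + part.ss_alpha)) < (
            1e-9 * max(part.ss_gamma, 1.0)
        )

    def test_contribution_indices_sum_to_one(self, rng):
        Y = rng.normal(size=(60, 4))
        grid = CommunityGrid(assignment=np.repeat(np.arange(6), 10), q=6, m=10)
        part = partition_all(Y, grid)
        assert part.lcsd_gamma_i.sum() == pytest.approx(1.0, abs=1e-9)
        assert part.lcsd_beta_k.sum() == pytest.approx(1.0, abs=1e-9)
        assert part.fcsd_gamma_j.sum() == pytest.approx(1.0, abs=1e-9)
        assert part.fcsd_beta_j.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(part.fcsd_alpha_jk.sum(axis=1), 1.0, atol=1e-9)

    def test_scalar_scaling_law(self, rng):
        # c*Y scales every SS/SD by c^2 and leaves all shares unchanged
        Y = rng.normal(size=(30, 3))
        grid = CommunityGrid(assignment=np.repeat(np.arange(3), 10), q=3, m=10)
        p1 = partition_all(Y, grid)
        c = 3.7
        p2 = partition_all(c * Y, grid)
        for name in ("ss_gamma", "sd_gamma", "ss_beta", "sd_beta", "ss_alpha"):
            assert getattr(p2, name) == pytest.approx(
                c**2 * getattr(p1, name), rel=1e-12
            )
        np.testing.assert_allclose(p2.lcsd_gamma_i, p1.lcsd_gamma_i, atol=1e-12)
        np.testing.assert_allclose(p2.fcsd_gamma_j, p1.fcsd_gamma_j, atol=1e-12)

    def test_band_vs_pc_invariance(self, rng):
        # type-1 PCA preserves all SS/SD/LCSD quantities at full rank
        Y = rng.normal(size=(60, 5)) * rng.uniform(0.5, 4.0, size=5)
        grid = CommunityGrid(assignment=np.repeat(np.arange(6), 10), q=6, m=10)
        model = fit_pca(Y)
        scores = transform_pca(model, Y).values
        pb, ps = partition_all(Y, grid), partition_all(scores, grid)
        for name in ("ss_gamma", "sd_gamma", "ss_beta", "sd_beta", "ss_alpha"):
            assert getattr(ps, name) == pytest.approx(
                getattr(pb, name), rel=1e-9
            )
        np.testing.assert_allclose(ps.lcsd_gamma_i, pb.lcsd_gamma_i, atol=1e-9)
        np.testing.assert_allclose(ps.lcsd_beta_k, pb.lcsd_beta_k, atol=1e-9)
        # FCSD is basis-dependent by design; on PCs it matches eigenvalues
        np.testing.assert_allclose(
            ps.fcsd_gamma_j, model.relative_eigenvalues, atol=1e-9
        )


class TestRarefaction:
    def test_balanced_input_reproduces_plain_partition(self, rng):
        Y = rng.normal(size=(30, 3))
        labels = np.repeat(np.arange(3), 10)
        grid = CommunityGrid(assignment=labels, q=3, m=10)
        plain = partition_all(Y, grid)
        res = rarefied_partition(Y, labels, repeats=5, seed=1)
        assert res.m_min == 10
        assert res.aggregate.ss_gamma == pytest.approx(plain.ss_gamma, rel=1e-12)
        assert res.aggregate.ss_beta == pytest.approx(plain.ss_beta, rel=1e-12)

    def test_m_min_is_smallest_count(self, rng):
        counts = [40, 17, 40]
        labels = np.repeat(np.arange(3), counts)
        Y = rng.normal(size=(sum(counts), 2))
        res = rarefied_partition(Y, labels, repeats=2, seed=0)
        assert res.m_min == 17
        for part in res.per_repeat:
            assert part.n == 3 * 17 and part.m == 17

    def test_fixed_seed_bit_identical(self, rng):
        labels = np.repeat(np.arange(4), [9, 6, 8, 7])
        Y = rng.normal(size=(30, 3))
        r1 = rarefied_partition(Y, labels, repeats=6, seed=42)
        r2 = rarefied_partition(Y, labels, repeats=6, seed=42)
        assert r1.aggregate.ss_gamma == r2.aggregate.ss_gamma
        np.testing.assert_array_equal(
            r1.aggregate.lcsd_beta_k, r2.aggregate.lcsd_beta_k
        )
        np.testing.assert_array_equal(r1.lcsd_gamma_full, r2.lcsd_gamma_full)

    def test_median_aggregation(self, rng):
        labels = np.repeat(np.arange(3), [5, 4, 6])
        Y = rng.normal(size=(15, 2))
        res = rarefied_partition(Y, labels, repeats=7, seed=3, aggregation="median")
        ssg = [p.ss_gamma for p in res.per_repeat]
        assert res.aggregate.ss_gamma == np.median(ssg)

    def test_min_fraction_floor_drops_sparse_communities(self, rng):
        labels = np.repeat(np.arange(3), [20, 3, 20])
        Y = rng.normal(size=(43, 2))
        res = rarefied_partition(Y, labels, repeats=2, seed=0, min_fraction=0.5)
        assert res.kept_communities.tolist() == [0, 2]
        assert res.m_min == 20

    def test_too_small_community_rejected(self, rng):
        labels = np.array([0, 0, 0, 1])
        Y = rng.normal(size=(4, 2))
        with pytest.raises(ValidationError, match=r"\[1\]"):
            rarefied_partition(Y, labels, repeats=1, seed=0)


class TestMergeRegions:
    def test_single_region_identity(self):
        ss, sd = merge_regions([(4.0, 4)])
        assert ss == 4.0 and sd == pytest.approx(4 / 3)

    def test_two_copies(self):
        # deviations from the joint mean: SS add, SD divides by total n-1
        ss, sd = merge_regions([(4.0, 4), (4.0, 4)])
        assert ss == 8.0 and sd == pytest.approx(8 / 7)

    def test_exact_under_joint_centering(self, rng):
        Y = rng.normal(size=(40, 3))
        joint_mean = Y.mean(axis=0)
        halves = [Y[:25], Y[25:]]
        parts = [(((h - joint_mean) ** 2).sum(), len(h)) for h in halves]
        ss, sd = merge_regions(parts)
        assert ss == pytest.approx(gamma_partition(Y)[0], rel=1e-12)
        assert sd == pytest.approx(gamma_partition(Y)[1], rel=1e-12)

    def test_mismatched_feature_count_rejected(self, rng):
        g1 = CommunityGrid(assignment=np.repeat([0, 1], 5), q=2, m=5)
        p1 = partition_all(rng.normal(size=(10, 3)), g1)
        p2 = partition_all(rng.normal(size=(10, 4)), g1)
        with pytest.raises(ValidationError):
            merge_regions([p1, p2])

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            merge_regions([])


class TestScaledSummary:
    def test_definitions(self):
        s = scaled_diversity_summary(4.0, 3.0, 1.0, n=10, q=2, m=5)
        assert s["sd_gamma"] == pytest.approx(4 / 9)
        assert s["sd_beta"] == pytest.approx(3 / 9)
        assert s["sd_alpha_mean"] == pytest.approx(1 / 8)
        assert s["beta_pct"] == pytest.approx(75.0)
        assert s["alpha_pct"] == pytest.approx(25.0)

    def test_equals_partition_output(self, rng):
        Y = rng.normal(size=(40, 3))
        grid = CommunityGrid(assignment=np.repeat(np.arange(4), 10), q=4, m=10)
        part = partition_all(Y, grid)
        s = scaled_diversity_summary(
            part.ss_gamma, part.ss_beta, part.ss_alpha, part.n, part.q, part.m
        )
        assert s["sd_gamma"] == pytest.approx(part.sd_gamma, rel=1e-12)
        assert s["sd_beta"] == pytest.approx(part.sd_beta, rel=1e-12)
        # under equal m, SS_alpha/(q(m-1)) is exactly the mean of SD_alpha,k
        assert s["sd_alpha_mean"] == pytest.approx(part.sd_alpha_mean, rel=1e-12)
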