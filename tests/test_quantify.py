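"""Shape index, positive ratios, k-NN spot distances, pooled statistics."""

import numpy as np
import pytest
from scipy import stats

from luadmorph.quantify import (
    PooledStats,
    knn_mean_distances,
    mask_shape_index,
    perimeter_area,
    pooled_stats,
    positive_ratio,
    shape_index,
    shape_measures,
    two_sample_tests_from_totals,
)
from luadmorph.synthetic import (
    make_circle_mask,
    make_star_mask,
    make_uniform_spots,
)


class TestPerimeterArea:
    def test_filled_square_area_is_exact(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        P, A = perimeter_area(mask)
        assert A == 100.0

    def test_rasterized_circle_close_to_analytic(self):
        mask, _ = make_circle_mask(radius=50)
        P, A = perimeter_area(mask)
        assert abs(P - 2 * np.pi * 50) / (2 * np.pi * 50) < 0.03
        assert abs(A - np.pi * 50**2) / (np.pi * 50**2) < 0.02

    def test_mirror_invariance(self):
        mask, _ = make_star_mask(radius=30, n_arms=5)
        P1, A1 = perimeter_area(mask)
        P2, A2 = perimeter_area(mask[:, ::-1])
        assert P1 == pytest.approx(P2, abs=1e-9) and A1 == A2

    def test_pixel_size_scales_units(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 2:8] = True
        P1, A1 = perimeter_area(mask, pixel_size=1.0)
        P2, A2 = perimeter_area(mask, pixel_size=2.5)
        assert P2 == pytest.approx(2.5 * P1)
        assert A2 == pytest.approx(2.5**2 * A1)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            perimeter_area(np.zeros((5, 5), dtype=bool))

    def test_multi_component_takes_largest_with_warning(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[2:20, 2:20] = True
        mask[25:27, 25:27] = True
        with pytest.warns(UserWarning, match="largest"):
            P, A = perimeter_area(mask)
        assert A == 18 * 18


class TestShapeIndex:
    def test_ideal_circle_is_exactly_two(self):
        R = 7.3
        assert shape_index(2 * np.pi * R, np.pi * R**2) == pytest.approx(2.0)
        m = shape_measures(2 * np.pi * R, np.pi * R**2)
        assert m.nRa == 1.0
        assert m.nA == pytest.approx(np.pi)
        assert m.index == pytest.approx(2.0)

    def test_scale_invariance(self):
        assert shape_index(10.0, 4.0) == pytest.approx(shape_index(30.0, 36.0))

    def test_discretized_circles_converge_to_two(self):
        errors = []
        for radius, tol in ((20, 0.05), (50, 0.03), (100, 0.02)):
            mask, _ = make_circle_mask(radius=radius)
            idx = mask_shape_index(mask).index
            err = abs(idx - 2.0) / 2.0
            assert err < tol
            errors.append(err)
        # approach to the ideal value with radius (the estimator's error
        # fluctuates below the 0.5% level, so compare coarsest vs finest)
        assert errors[2] <= errors[0]

    def test_protrusions_raise_the_index(self):
        circle, _ = make_circle_mask(radius=50)
        star, _ = make_star_mask(radius=50, n_arms=8)
        assert mask_shape_index(star).index > mask_shape_index(circle).index

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            shape_index(0.0, 10.0)
        with pytest.raises(ValueError):
            shape_index(10.0, -1.0)


class TestPositiveRatio:
    def test_identical_masks_give_one(self):
        m = np.random.default_rng(0).random((20, 20)) > 0.5
        assert positive_ratio(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        region = np.zeros((10, 10), dtype=bool)
        region[:5] = True
        marker = ~region
        assert positive_ratio(marker, region) == 0.0

    def test_constructed_count_is_exact(self):
        region = np.zeros((40, 40), dtype=bool)
        region[:25, :40] = True  # 1000 px
        marker = np.zeros_like(region)
        marker.flat[:123] = True  # 123 px inside the region
        assert positive_ratio(marker, region) == pytest.approx(0.123)

    def test_additive_over_region_partition(self):
        rng = np.random.default_rng(1)
        marker = rng.random((30, 30)) > 0.6
        region = rng.random((30, 30)) > 0.2
        left = region.copy()
        left[:, 15:] = False
        right = region & ~left
        n_l, n_r = left.sum(), right.sum()
        combined = (
            positive_ratio(marker, left) * n_l + positive_ratio(marker, right) * n_r
        ) / (n_l + n_r)
        assert combined == pytest.approx(positive_ratio(marker, region))

    def test_errors(self):
        with pytest.raises(ValueError):
            positive_ratio(np.ones((3, 3)), np.ones((4, 4)))
        with pytest.raises(ValueError):
            positive_ratio(np.ones((3, 3)), np.zeros((3, 3)))


def brute_force_knn_means(points, k):
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return np.sort(d, axis=1)[:, :k].mean(axis=1)


class TestKnnDistances:
    def test_ten_points_on_a_line_hand_computed(self):
        pts = np.zeros((10, 3))
        pts[:, 0] = np.arange(10)
        means, flags = knn_mean_distances(pts, k=9)
        for i in range(10):
            expected = np.mean([abs(i - j) for j in range(10) if j != i])
            assert means[i] == pytest.approx(expected)
        assert not flags.any()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-100, 100, size=(200, 3))
        means, _ = knn_mean_distances(pts, k=9)
        assert np.allclose(means, brute_force_knn_means(pts, 9), atol=1e-9)

    def test_isometry_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(50, 3))
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = pts @ rot.T + np.array([5.0, -3.0, 2.0])
        a, _ = knn_mean_distances(pts, k=9)
        b, _ = knn_mean_distances(moved, k=9)
        assert np.allclose(a, b, atol=1e-9)

    def test_coincident_points_give_zero_means(self):
        pts = np.zeros((12, 3))
        means, _ = knn_mean_distances(pts, k=9)
        assert np.allclose(means, 0.0)

    def test_cutoff_flags_isolated_spots(self):
        pts = np.zeros((11, 3))
        pts[:10, 0] = np.arange(10)
        pts[10] = [500.0, 0, 0]
        means, flags = knn_mean_distances(pts, k=9, cutoff=60.0)
        assert flags[10]
        assert not flags[:10].any()

    def test_too_few_points_named_minimum(self):
        with pytest.raises(ValueError, match="10"):
            knn_mean_distances(np.zeros((5, 3)), k=9)


class TestPooledStats:
    def _sets(self, n_spheroids, seed=0, n=60):
        return [
            make_uniform_spots(n_points=n, seed=seed + i, label=f"s{i}", k=9)
            for i in range(n_spheroids)
        ]

    def test_single_spheroid_equals_own_stats(self):
        (s,) = self._sets(1)
        pooled = pooled_stats([s])
        d = s.per_spot_mean_distance
        assert pooled.total_mean == pytest.approx(d.mean())
        assert pooled.total_sd == pytest.approx(d.std(ddof=1))

    def test_equal_n_groups_average_their_means(self):
        a, b = self._sets(2)
        pooled = pooled_stats([a, b])
        m1 = a.per_spot_mean_distance.mean()
        m2 = b.per_spot_mean_distance.mean()
        assert pooled.total_mean == pytest.approx((m1 + m2) / 2)

    def test_eight_spheroids_match_concatenation_oracle(self):
        sets = self._sets(8, seed=10)
        pooled = pooled_stats(sets)
        cat = np.concatenate([s.per_spot_mean_distance for s in sets])
        assert pooled.total_n == len(cat)
        assert pooled.total_mean == pytest.approx(cat.mean(), abs=1e-12)
        assert pooled.total_sd == pytest.approx(cat.std(ddof=1), abs=1e-12)

    def test_permutation_invariance(self):
        sets = self._sets(5, seed=20)
        a = pooled_stats(sets)
        b = pooled_stats(sets[::-1])
        assert a.total_mean == pytest.approx(b.total_mean, abs=1e-12)
        assert a.total_sd == pytest.approx(b.total_sd, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pooled_stats([])


class TestTwoSampleTests:
    def test_identical_groups(self):
        a = PooledStats(total_n=20, total_mean=5.0, total_sd=1.0, per_spheroid=[])
        res = two_sample_tests_from_totals(a, a)
        assert res["t_statistic"] == pytest.approx(0.0)
        assert res["F_statistic"] == pytest.approx(1.0)

    def test_textbook_pooled_t(self):
        a = PooledStats(total_n=10, total_mean=5.0, total_sd=1.0, per_spheroid=[])
        b = PooledStats(total_n=10, total_mean=6.0, total_sd=1.0, per_spheroid=[])
        res = two_sample_tests_from_totals(a, b)
        assert res["t_statistic"] == pytest.approx(-2.2360679, abs=1e-6)

    def test_p_values_match_reference_library(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n1, n2 = int(rng.integers(5, 60)), int(rng.integers(5, 60))
            m1, m2 = rng.normal(0, 5, 2)
            s1, s2 = rng.uniform(0.5, 4.0, 2)
            a = PooledStats(n1, m1, s1, [])
            b = PooledStats(n2, m2, s2, [])
            res = two_sample_tests_from_totals(a, b)
            t_ref, p_ref = stats.ttest_ind_from_stats(
                m1, s1, n1, m2, s2, n2, equal_var=True
            )
            assert res["t_statistic"] == pytest.approx(t_ref, abs=1e-9)
            assert res["t_p"] == pytest.approx(p_ref, abs=1e-9)
            f = max(s1, s2) ** 2 / min(s1, s2) ** 2
            dfn = (n1 if s1 >= s2 else n2) - 1
            dfd = (n2 if s1 >= s2 else n1) - 1
            p_f = 2 * min(stats.f.cdf(f, dfn, dfd), stats.f.sf(f, dfn, dfd))
            assert res["F_p"] == pytest.approx(min(p_f, 1.0), abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        a = PooledStats(1, 0.0, 1.0, [])
        b = PooledStats(10, 0.0, 1.0, [])
        with pytest.raises(ValueError):
            two_sample_tests_from_totals(a, b)
        c = PooledStats(10, 0.0, 0.0, [])
        with pytest.raises(ValueError):
            two_sample_tests_from_totals(c, c)
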