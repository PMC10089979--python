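"""Registration, axis densities, KS/MANOVA, permutation null, view search."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tipm.core import NeuronRecord, Population
from tipm.topography import (
    ReferenceFrame,
    axis_distribution,
    compare_groups,
    ks_two_sample,
    manova_one_way,
    n_subdivisions,
    optimal_sagittal_view,
    permutation_null,
    register_neurons,
    rotation_matrix,
    topography_battery,
)


def make_population(coords: np.ndarray, subtypes) -> Population:
    neurons = [
        NeuronRecord(i, 0, "left", float(x), float(y), float(z), 30.0, "early", s)
        for i, ((x, y, z), s) in enumerate(zip(coords, subtypes))
    ]
    return Population(neurons)


class TestRegistration:
    def test_40_um_stack_gives_8_planes(self):
        assert n_subdivisions(40.0, 5.0) == 8

    def test_origin_maps_to_zero(self):
        frame = ReferenceFrame(origin_px=(100.0, 50.0))
        raw = pd.DataFrame({"x_px": [100.0], "y_px": [50.0], "z_um": [0.0]})
        out = register_neurons(raw, frame)
        assert out.loc[0, "x_rc_um"] == 0.0 and out.loc[0, "y_ml_um"] == 0.0
        assert out.loc[0, "subdivision"] == 0

    def test_48_px_offset_is_10_um(self):
        frame = ReferenceFrame()
        raw = pd.DataFrame({"x_px": [48.0], "y_px": [0.0], "z_um": [12.0]})
        out = register_neurons(raw, frame)
        assert out.loc[0, "x_rc_um"] == pytest.approx(10.0)
        assert out.loc[0, "subdivision"] == 2  # floor(12/5)

    def test_out_of_bounds_flagged_not_dropped(self):
        frame = ReferenceFrame(origin_px=(10.0, 10.0))
        raw = pd.DataFrame({"x_px": [5.0, 20.0], "y_px": [20.0, 20.0], "z_um": [1.0, 1.0]})
        out = register_neurons(raw, frame)
        assert list(out["out_of_bounds"]) == [True, False]
        assert len(out) == 2


class TestAxisDistribution:
    def test_point_mass_density(self):
        coords = np.tile([10.0, 5.0, 5.0], (6, 1))
        pop = make_population(coords, ["nose_up"] * 6)
        d = axis_distribution(pop, "x_rc_um", "subtype", bounds=(0.0, 40.0))
        assert d.mean["nose_up"].sum() == pytest.approx(1.0)
        hot = d.mean["nose_up"] == 1.0
        assert hot.sum() == 1 and d.sd["nose_up"][hot][0] == 0.0

    def test_jackknife_mean_approaches_full_density_at_large_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(20, 5, 5000).clip(0, 40)
        coords = np.column_stack([x, np.full(5000, 5.0), np.full(5000, 5.0)])
        pop = make_population(coords, ["nose_up"] * 5000)
        d = axis_distribution(pop, "x_rc_um", "subtype", bounds=(0.0, 40.0))
        full, _ = np.histogram(x, bins=d.bin_edges)
        full = full / full.sum()
        assert np.abs(d.mean["nose_up"] - full).max() < 0.01

    def test_median_of_symmetric_distribution_is_center(self):
        x = np.concatenate([np.linspace(10, 19, 30), np.linspace(21, 30, 30), [20.0]])
        coords = np.column_stack([x, np.ones_like(x), np.ones_like(x)])
        pop = make_population(coords, ["nose_up"] * len(x))
        d = axis_distribution(pop, "x_rc_um", "subtype", bounds=(0.0, 40.0))
        assert abs(d.medians["nose_up"] - 20.0) <= 2.0

    def test_small_group_rejected(self):
        pop = make_population(np.ones((4, 3)), ["a", "a", "b", "b"])
        with pytest.raises(ValueError):
            axis_distribution(pop, "x_rc_um", "subtype")


class TestKsTwoSample:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        d, p = ks_two_sample(a, a)
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports_give_d_1(self):
        d, _ = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == 1.0

    def test_one_sided_d_is_signed_sup(self):
        # a stochastically larger than b: F_a below F_b, so the 'greater'
        # statistic picks up sup(F_b - F_a)
        a = [5.0, 6.0, 7.0, 8.0]
        b = [1.0, 2.0, 3.0, 4.0]
        d_gt, p_gt = ks_two_sample(a, b, tail="greater")
        d_lt, p_lt = ks_two_sample(a, b, tail="less")
        assert d_gt == 1.0 and d_lt == 0.0
        assert p_gt < 0.05 < p_lt

    def test_small_n_one_sided_p_matches_exhaustive_permutation(self):
        # enumerate all label assignments of 5 vs 5 and compare the
        # asymptotic one-sided p with the exact permutation tail
        rng = np.random.default_rng(42)
        pooled = rng.normal(0, 1, 10)
        a, b = pooled[:5], pooled[5:]
        d_obs, p_asym = ks_two_sample(a, b, tail="greater")
        count = 0
        total = 0
        idx = np.arange(10)
        for comb in itertools.combinations(idx, 5):
            mask = np.zeros(10, bool)
            mask[list(comb)] = True
            d_perm, _ = ks_two_sample(pooled[mask], pooled[~mask], tail="greater")
            count += d_perm >= d_obs - 1e-12
            total += 1
        assert abs(p_asym - count / total) < 0.02 or p_asym >= count / total - 0.02

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([1.0], [2.0, 3.0])


class TestManova:
    def test_permuted_labels_give_lambda_near_1(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (100, 3))
        labels = rng.permutation(np.repeat(["a", "b"], 50))
        res = manova_one_way(X, labels)
        assert res.wilks_lambda > 0.9

    def test_two_group_equals_independent_hotelling_t2(self):
        # independent oracle: Hotelling's T^2 from pooled covariance,
        # F = (n1+n2-p-1) T^2 / ((n1+n2-2) p)
        rng = np.random.default_rng(1)
        X1 = rng.normal(0, 1, (30, 3))
        X2 = rng.normal(0.8, 1, (25, 3))
        X = np.vstack([X1, X2])
        labels = np.array(["a"] * 30 + ["b"] * 25)
        res = manova_one_way(X, labels)
        n1, n2, p = 30, 25, 3
        diff = X1.mean(0) - X2.mean(0)
        S = (
            (n1 - 1) * np.cov(X1, rowvar=False) + (n2 - 1) * np.cov(X2, rowvar=False)
        ) / (n1 + n2 - 2)
        t2 = (n1 * n2) / (n1 + n2) * diff @ np.linalg.solve(S, diff)
        f_oracle = (n1 + n2 - p - 1) * t2 / ((n1 + n2 - 2) * p)
        p_oracle = stats.f.sf(f_oracle, p, n1 + n2 - p - 1)
        assert res.F == pytest.approx(f_oracle, rel=1e-10)
        assert res.p == pytest.approx(p_oracle, rel=1e-10)

    def test_agrees_with_statsmodels(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (60, 3))
        X[30:] += [0.5, 0.0, 1.0]
        labels = np.repeat(["a", "b"], 30)
        res = manova_one_way(X, labels)
        df = pd.DataFrame(X, columns=["x", "y", "z"]).assign(g=labels)
        sm = MANOVA.from_formula("x + y + z ~ g", data=df).mv_test()
        table = sm.results["g"]["stat"]
        assert res.wilks_lambda == pytest.approx(table.loc["Wilks' lambda", "Value"], rel=1e-8)
        assert res.p == pytest.approx(table.loc["Wilks' lambda", "Pr > F"], rel=1e-6)

    def test_null_p_values_are_uniform(self):
        # both groups from the same distribution: p ~ U(0,1) over seeds
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, (60, 3))
            labels = np.repeat(["a", "b"], 30)
            ps.append(manova_one_way(X, labels).p)
        _, p_ks = stats.kstest(ps, "uniform")
        assert p_ks > 0.01

    def test_power_at_1p5_sd_separation(self):
        # centroids 1.5 pooled sd apart on the dorsoventral axis, n=100/group
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(10_000 + seed)
            X = rng.normal(0, 1, (200, 3))
            X[100:, 2] += 1.5
            labels = np.repeat(["a", "b"], 100)
            hits += manova_one_way(X, labels).p < 0.05
        assert hits / n_seeds >= 0.9

    def test_rank_deficiency_raises(self):
        X = np.zeros((20, 3))
        labels = np.repeat(["a", "b"], 10)
        with pytest.raises(np.linalg.LinAlgError):
            manova_one_way(X, labels)


class TestPermutationNull:
    def test_label_counts_preserved(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(20, 5, (50, 3))
        labels = np.array(["nose_up"] * 30 + ["nose_down"] * 20)
        pop = make_population(coords, labels)
        null = permutation_null(pop, "subtype", n_perm=10, seed=0)
        assert len(null.p_values) == 10
        # counts preserved by construction (permutation); observed battery present
        assert null.observed.manova.p >= 0.0

    def test_label_independent_population_mean_p_near_half(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(20, 6, (114, 3))
        labels = np.array(["nose_up"] * 74 + ["nose_down"] * 40)
        pop = make_population(coords, labels)
        null = permutation_null(pop, "subtype", n_perm=100, seed=1)
        assert null.mean_p == pytest.approx(0.5, abs=0.1)

    def test_separated_population_observed_beats_all_permutations(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(0, 1, (60, 3))
        coords[:30, 2] += 8.0
        labels = np.array(["nose_up"] * 30 + ["nose_down"] * 30)
        pop = make_population(coords, labels)
        null = permutation_null(pop, "subtype", n_perm=50, seed=2)
        assert null.observed.manova.p < null.p_values.min()

    def test_single_level_feature_rejected(self):
        pop = make_population(np.random.default_rng(0).normal(size=(10, 3)), ["a"] * 10)
        with pytest.raises(ValueError):
            permutation_null(pop, "subtype", n_perm=5)


class TestCompareGroups:
    def test_identical_groups_d_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        d, _ = compare_groups(a, a)
        assert d == 0.0

    def test_hand_computed_d(self):
        d, _ = compare_groups([2.0, 4.0], [1.0, 3.0])
        assert d == pytest.approx(1.0 / np.sqrt(2.0))

    def test_sign_flips_when_swapped(self):
        d1, _ = compare_groups([5.0, 6.0], [1.0, 2.0])
        d2, _ = compare_groups([1.0, 2.0], [5.0, 6.0])
        assert d1 == pytest.approx(-d2)

    def test_zero_pooled_sd_flagged(self):
        d, _ = compare_groups([1.0, 1.0], [1.0, 1.0])
        assert np.isnan(d)


class TestViewSearch:
    @pytest.mark.parametrize("az0, el0", [(0.0, 0.0), (30.0, -30.0)])
    def test_planted_view_angle_recovered(self, az0, el0):
        # The summed-KS score peaks when the subtype separation projects
        # equally onto all three viewing axes; planting the separation along
        # R(az0, el0)^T (1,1,1)/sqrt(3) therefore makes (az0, el0) the
        # optimal view, which the grid search must recover (up to score
        # ties from symmetry-equivalent rotations).
        rng = np.random.default_rng(3)
        u = rotation_matrix(az0, el0).T @ (np.ones(3) / np.sqrt(3.0))
        coords = rng.normal(0, 1, (400, 3))
        coords[:200] += 6.0 * u
        labels = np.array(["nose_up"] * 200 + ["nose_down"] * 200)
        pop = make_population(coords, labels)
        grid = np.arange(-60.0, 61.0, 30.0)
        res = optimal_sagittal_view(pop, grid, grid)
        planted = res.score_grid[list(grid).index(az0), list(grid).index(el0)]
        assert planted >= res.score - 0.02

    def test_isotropic_cloud_scores_are_flat(self):
        # label-independent isotropic cloud: score range over the grid small
        # relative to the Monte-Carlo spread of the score itself
        rng = np.random.default_rng(4)
        ranges, mc_scores = [], []
        grid = np.arange(-90.0, 91.0, 45.0)
        for seed in range(8):
            r = np.random.default_rng(seed)
            coords = r.normal(0, 1, (100, 3))
            labels = np.array(["nose_up"] * 50 + ["nose_down"] * 50)
            pop = make_population(coords, labels)
            res = optimal_sagittal_view(pop, grid, grid)
            ranges.append(res.score_grid.max() - res.score_grid.min())
            mc_scores.append(res.score_grid.mean())
        assert np.mean(ranges) < 2.0 * (np.std(mc_scores) + np.mean(mc_scores) * 0.5)

    def test_grid_shape(self, small_population):
        tuned = small_population.subset(small_population.labels("subtype") != "none")
        res = optimal_sagittal_view(tuned, np.arange(3, dtype=float), np.arange(4, dtype=float))
        assert res.score_grid.shape == (3, 4)
        i = list(res.azimuth_grid).index(res.azimuth_deg)
        j = list(res.elevation_grid).index(res.elevation_deg)
        assert res.score_grid[i, j] == res.score_grid.max() == res.score

    def test_statistics_never_use_transformed_coordinates(self, small_population):
        # battery results identical whether or not a view search ran
        tuned = small_population.subset(small_population.labels("subtype") != "none")
        before = topography_battery(tuned, tuned.labels("subtype"))
        optimal_sagittal_view(tuned, np.arange(3, dtype=float), np.arange(3, dtype=float))
        after = topography_battery(tuned, tuned.labels("subtype"))
        assert before.manova.p == after.manova.p
        assert before.ks_per_axis == after.ks_per_axis

    def test_rotation_matrix_orthonormal(self):
        R = rotation_matrix(-26.7, 51.9)
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0)


def test_type_i_error_of_battery_near_nominal():
    """MANOVA and per-axis KS reject ~5% of label-independent populations."""
    n_seeds = 400
    rej_manova = 0
    rej_ks = np.zeros(3)
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        X = rng.normal(20, 5, (40, 3))
        labels = np.repeat(["a", "b"], 20)
        rej_manova += manova_one_way(X, labels).p < 0.05
        for ax in range(3):
            _, p = ks_two_sample(X[:20, ax], X[20:, ax])
            rej_ks[ax] += p < 0.05
    assert rej_manova / n_seeds == pytest.approx(0.05, abs=0.02)
    # the exact KS p is conservative on small samples: rate at or below nominal
    assert (rej_ks / n_seeds <= 0.07).all()
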