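"""Distance maps, heterogeneity, shape tensors, volumes, Mann-Whitney."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import mannwhitneyu

from sbsfold.model_core import Conformation
from sbsfold.single_molecule import (
    distance_map,
    ensemble_shape_stats,
    gyration_shape,
    heterogeneity,
    inertia_shape,
    mann_whitney,
    molecule_volumes,
    shape_descriptors,
)
from sbsfold.synthetic_data import sample_baseline_chain, sample_ellipsoid_cloud


def _conf(coords):
    return Conformation(bead_coords=np.asarray(coords, dtype=float), box_edge=0.0)


class TestDistanceMap:
    def test_two_beads(self):
        dm = distance_map(_conf([[0, 0, 0], [3, 0, 0]]))
        assert np.array_equal(dm.matrix, [[0, 3], [3, 0]])

    def test_collinear(self):
        dm = distance_map(_conf([[0, 0, 0], [1, 0, 0], [2, 0, 0]]))
        assert dm.matrix[0, 2] == pytest.approx(2.0)

    def test_triangle_inequality_random_cloud(self):
        rng = np.random.default_rng(0)
        dm = distance_map(_conf(rng.normal(size=(15, 3)))).matrix
        for _ in range(300):
            i, j, k = rng.integers(0, 15, size=3)
            assert dm[i, k] <= dm[i, j] + dm[j, k] + 1e-12

    def test_wrapped_coordinates_rejected(self):
        coords = np.zeros((3, 3))
        coords[1, 0] = 9.0  # "bond" longer than half the box
        with pytest.raises(ValueError, match="unwrap"):
            distance_map(Conformation(bead_coords=coords, box_edge=10.0))


class TestHeterogeneity:
    def test_identical_maps_give_unit_correlations(self):
        conf = sample_baseline_chain(20, "ideal", seed=1)
        maps = [distance_map(conf)] * 4
        stats = heterogeneity(maps)
        assert np.allclose(stats.values, 1.0)
        assert stats.variance == pytest.approx(0.0, abs=1e-12)

    def test_independent_coils_near_zero(self):
        maps = [
            distance_map(sample_baseline_chain(60, "ideal", seed=s)) for s in range(30)
        ]
        stats = heterogeneity(maps)
        assert abs(stats.mean) < 0.05
        assert stats.values.size == 30 * 29 // 2

    def test_matches_brute_force_pairs(self):
        from sbsfold.ensemble_maps import distance_corrected_pearson

        maps = [
            distance_map(sample_baseline_chain(12, "ideal", seed=s)) for s in range(6)
        ]
        stats = heterogeneity(maps)
        brute = [
            distance_corrected_pearson(maps[i].matrix, maps[j].matrix)
            for i in range(6)
            for j in range(i + 1, 6)
        ]
        assert np.allclose(sorted(stats.values), sorted(brute), atol=1e-12)

    def test_degenerate_map_excluded_with_log(self, caplog):
        rod = distance_map(sample_baseline_chain(10, "rod"))  # pure |i-j| profile
        good = [distance_map(sample_baseline_chain(10, "ideal", seed=s)) for s in range(3)]
        with caplog.at_level("WARNING"):
            stats = heterogeneity([rod, *good])
        assert stats.n_excluded == 1
        assert stats.values.size == 3


class TestInertiaShape:
    def test_uniform_ball_semi_axes(self):
        cloud = sample_ellipsoid_cloud(2.0, 2.0, 2.0, 100_000, seed=1)
        sd = inertia_shape(cloud)
        assert np.allclose(sd.semi_axes, 2.0, rtol=0.02)

    def test_triaxial_ellipsoid_recovered(self):
        cloud = sample_ellipsoid_cloud(4.0, 2.0, 1.0, 100_000, seed=2)
        sd = inertia_shape(cloud)
        assert np.allclose(sd.semi_axes, [4.0, 2.0, 1.0], rtol=0.02)
        assert sd.ac_ratio == pytest.approx(4.0, rel=0.04)
        assert sd.bc_ratio == pytest.approx(2.0, rel=0.04)

    def test_collinear_cloud_flagged(self):
        coords = np.zeros((10, 3))
        coords[:, 0] = np.arange(10)
        sd = inertia_shape(_conf(coords))
        assert sd.degenerate
        assert sd.semi_axes[2] == pytest.approx(0.0, abs=1e-6)

    def test_moment_ordering_vs_axis_ordering(self):
        cloud = sample_ellipsoid_cloud(3.0, 1.5, 1.0, 20_000, seed=3)
        sd = inertia_shape(cloud)
        assert sd.inertia_moments[0] <= sd.inertia_moments[1] <= sd.inertia_moments[2]
        assert sd.semi_axes[0] >= sd.semi_axes[1] >= sd.semi_axes[2]

    def test_centering_makes_origin_irrelevant(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(500, 3))
        a = inertia_shape(_conf(pts))
        b = inertia_shape(_conf(pts + np.array([100.0, -50.0, 7.0])))
        assert np.allclose(a.semi_axes, b.semi_axes, atol=1e-8)


class TestGyrationShape:
    def test_uniform_ball_ellipticity_one(self):
        cloud = sample_ellipsoid_cloud(2.0, 2.0, 2.0, 100_000, seed=5)
        sd = gyration_shape(cloud)
        assert sd.ellipticity == pytest.approx(1.0, abs=0.02)

    def test_two_points_degenerate(self):
        sd = gyration_shape(_conf([[0, 0, 0], [2, 0, 0]]))
        assert sd.gyration_eigenvalues[1] == pytest.approx(0.0, abs=1e-12)
        assert sd.gyration_eigenvalues[2] == pytest.approx(0.0, abs=1e-12)
        assert sd.ellipticity == pytest.approx(0.0, abs=1e-12)

    def test_rg_squared_is_eigenvalue_sum(self):
        conf = sample_baseline_chain(50, "ideal", seed=6)
        sd = gyration_shape(conf)
        assert sd.rg**2 == pytest.approx(float(sd.gyration_eigenvalues.sum()), abs=1e-10)

    def test_inertia_gyration_eigen_identity(self):
        """Centered tensors satisfy I_k = N (tr T - lambda_k), pairing the
        smallest moment with the largest gyration eigenvalue."""
        conf = sample_baseline_chain(60, "ideal", seed=7)
        n = conf.n_beads
        ine = inertia_shape(conf)
        gyr = gyration_shape(conf)
        tr = float(gyr.gyration_eigenvalues.sum())
        expected = n * (tr - gyr.gyration_eigenvalues)  # descending lambda
        assert np.allclose(sorted(ine.inertia_moments), sorted(expected), rtol=1e-8)

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(80, 3)) * np.array([3.0, 1.5, 0.7])
        base = shape_descriptors(_conf(pts))
        rot = Rotation.random(random_state=1).as_matrix()
        moved = shape_descriptors(_conf(pts @ rot.T + np.array([5.0, -3.0, 11.0])))
        assert np.allclose(base.semi_axes, moved.semi_axes, atol=1e-8)
        assert np.allclose(
            base.gyration_eigenvalues, moved.gyration_eigenvalues, atol=1e-8
        )
        assert base.ellipticity == pytest.approx(moved.ellipticity, abs=1e-8)

    def test_rg_matches_engine_rg(self):
        from sbsfold.md_engine import radius_of_gyration

        conf = sample_baseline_chain(40, "ideal", seed=9)
        sd = gyration_shape(conf)
        assert sd.rg == pytest.approx(radius_of_gyration(conf.bead_coords), abs=1e-10)


class TestVolumes:
    def test_unit_sphere_volume(self):
        sd = shape_descriptors(sample_ellipsoid_cloud(1, 1, 1, 5000, seed=0))
        sd_exact = sd
        v_abc, v_rg = molecule_volumes(sd_exact)
        assert v_abc == pytest.approx(4 * math.pi / 3 * np.prod(sd.semi_axes), rel=1e-12)

    def test_rg_volume_closed_form(self):
        conf = sample_baseline_chain(30, "ideal", seed=1)
        sd = gyration_shape(conf)
        assert sd.v_rg == pytest.approx(4 / 3 * math.pi * sd.rg**3)
        # a 6.4 sigma gyration radius corresponds to ~1098 sigma^3
        class FakeRg:
            rg = 6.4
            v_rg = 4 / 3 * math.pi * 6.4**3
        assert FakeRg.v_rg == pytest.approx(1098, rel=0.001)

    def test_ensemble_stats_identical_spheres(self):
        confs = [sample_ellipsoid_cloud(2, 2, 2, 30_000, seed=s) for s in range(3)]
        _, summ = ensemble_shape_stats(confs)
        assert summ["mean_ac_ratio"] == pytest.approx(1.0, abs=0.03)
        assert summ["mean_bc_ratio"] == pytest.approx(1.0, abs=0.03)
        assert summ["mean_ellipticity"] == pytest.approx(1.0, abs=0.03)

    def test_ensemble_stats_prolate_clouds(self):
        confs = [sample_ellipsoid_cloud(2, 1, 1, 30_000, seed=s) for s in range(3)]
        _, summ = ensemble_shape_stats(confs)
        assert summ["mean_ac_ratio"] == pytest.approx(2.0, rel=0.05)
        assert summ["mean_bc_ratio"] == pytest.approx(1.0, abs=0.05)


class TestMannWhitney:
    def test_tied_pairs_exact(self):
        u, p = mann_whitney([1, 2], [1, 2])
        assert u == pytest.approx(2.0)
        assert p == pytest.approx(1.0)

    def test_fully_separated_exact(self):
        u, p = mann_whitney([4, 5, 6], [1, 2, 3])
        assert u == 9
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_antisymmetry_identity(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(8), rng.random(11)
        ux, _ = mann_whitney(x, y)
        uy, _ = mann_whitney(y, x)
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_exact_and_normal_agree_at_n15(self):
        """Exact DP p-value and the normal approximation agree within 0.01."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(size=15)
            y = rng.normal(loc=0.4, size=15)
            _, p_exact = mann_whitney(x, y)  # n*m = 225 <= 400: exact DP path
            p_norm = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            assert abs(p_exact - p_norm) < 0.01

    def test_matches_scipy_exact_no_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.normal(size=7)
            y = rng.normal(size=9)
            u, p = mann_whitney(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_all_tied_warns_p_one(self):
        with pytest.warns(UserWarning, match="tied"):
            _, p = mann_whitney([3, 3, 3], [3, 3])
        assert p == 1.0

    def test_large_sample_normal_path(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = rng.normal(loc=0.8, size=40)
        _, p = mann_whitney(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(ref, abs=0.01)
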