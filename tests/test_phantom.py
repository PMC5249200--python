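"""Phantom generator: geometry, wear model, oracles, voxelization,
weight-series simulation."""

import numpy as np
import pytest

import cupwear as cw
from cupwear.phantom import PhantomError, SoakParams, make_sphere_geometry


def lens_wear_volume(r: float, d: float) -> float:
    """Closed-form wear volume for a head of the cavity's own radius
    translated axially by d: the displaced sphere minus the two-sphere
    intersection (equal radii r, centre distance d)."""
    return 4.0 / 3.0 * np.pi * r**3 - np.pi / 12.0 * (4 * r + d) * (2 * r - d) ** 2


class TestCupGeometry:
    def test_analytic_shell_volume(self):
        spec = cw.CupSpec(32.0, 50.0)
        expected = 2.0 * np.pi / 3.0 * (25.0**3 - 16.0**3)
        assert spec.shell_volume == pytest.approx(expected, rel=1e-12)
        assert cw.make_cup_geometry(spec).analytic_volume == pytest.approx(expected)

    @pytest.mark.parametrize(
        "inner,outer,density",
        [(32.0, 32.0, 0.934), (50.0, 32.0, 0.934), (0.0, 50.0, 0.934),
         (32.0, 50.0, 0.0), (32.0, 50.0, -1.0)],
    )
    def test_invalid_spec_rejected(self, inner, outer, density):
        with pytest.raises(PhantomError):
            cw.CupSpec(inner, outer, density)

    def test_cavity_and_material_classification(self, cup_spec):
        solid = cw.make_cup_geometry(cup_spec)
        # centre of the inner sphere is in the cavity, not in material
        assert not solid.contains(np.array([[0.0, 0.0, 0.0]]))[0]
        # mid-shell point at the pole is material
        assert solid.contains(np.array([[0.0, 0.0, 20.5]]))[0]
        # below the rim plane there is no material
        assert not solid.contains(np.array([[20.0, 0.0, -1.0]]))[0]


class TestApplyWear:
    def test_zero_penetration_is_identity(self, cup_spec):
        solid = cw.make_cup_geometry(cup_spec)
        worn = cw.apply_wear(solid, cup_spec, cw.WearPattern(0.0))
        rng = np.random.default_rng(0)
        pts = rng.uniform(-26, 26, size=(5000, 3))
        np.testing.assert_allclose(worn.sdf(pts), solid.sdf(pts), atol=1e-12)

    def test_material_only_removed(self, cup_spec):
        solid = cw.make_cup_geometry(cup_spec)
        worn = cw.apply_wear(solid, cup_spec, cw.WearPattern(1.0))
        rng = np.random.default_rng(1)
        pts = rng.uniform(-26, 26, size=(20000, 3))
        inside_worn = worn.contains(pts)
        inside_orig = solid.contains(pts)
        assert np.all(inside_orig[inside_worn])  # worn solid subset of original

    def test_penetration_through_shell_rejected(self, cup_spec):
        solid = cw.make_cup_geometry(cup_spec)
        with pytest.raises(PhantomError, match="through the shell"):
            cw.apply_wear(solid, cup_spec, cw.WearPattern(9.5))

    def test_non_unit_load_direction_rejected(self):
        with pytest.raises(PhantomError, match="unit vector"):
            cw.WearPattern(0.5, load_direction=(0.0, 0.0, 2.0))


class TestTrueWearVolume:
    def test_zero_penetration_gives_zero(self, cup_spec):
        assert cw.true_wear_volume(cup_spec, cw.WearPattern(0.0)) == 0.0

    def test_oracles_agree_with_each_other_and_closed_form(self, cup_spec, wear_pattern, true_wear):
        """Grid and Monte-Carlo integrations of the boolean difference must
        agree with each other and with the closed-form lens volume to 0.1%."""
        closed = lens_wear_volume(cup_spec.inner_radius, wear_pattern.penetration_depth)
        v_mc = cw.true_wear_volume(
            cup_spec, wear_pattern, method="mc", n_samples=10_000_000, seed=123
        )
        assert true_wear == pytest.approx(closed, rel=1e-3)
        assert v_mc == pytest.approx(closed, rel=1e-3)
        assert v_mc == pytest.approx(true_wear, rel=1e-3)

    def test_monotone_in_penetration(self, cup_spec):
        vols = [
            cw.true_wear_volume(cup_spec, cw.WearPattern(d), grid_step=0.1)
            for d in (0.2, 0.4, 0.6)
        ]
        assert vols[0] < vols[1] < vols[2]

    def test_unknown_method_rejected(self, cup_spec):
        with pytest.raises(ValueError, match="unknown method"):
            cw.true_wear_volume(cup_spec, cw.WearPattern(0.3), method="magic")


class TestVoxelize:
    def test_sharp_render_levels(self):
        sph = make_sphere_geometry(3.0)
        vol = cw.voxelize(sph, 0.2, blur_sigma=0.0)
        assert vol.grid.max() == pytest.approx(100.0)
        assert vol.grid.min() == pytest.approx(0.0)
        centre = np.round(vol.physical_to_index([0, 0, 0])).astype(int)
        assert vol.grid[tuple(centre)] == pytest.approx(100.0)

    def test_gray_weighted_volume_matches_analytic_sphere(self):
        sph = make_sphere_geometry(5.0)
        vol = cw.voxelize(sph, 0.2, blur_sigma=0.0)
        assert vol.gray_weighted_volume() == pytest.approx(sph.analytic_volume, rel=0.01)

    def test_gray_weighted_volume_converges_with_resolution(self):
        sph = make_sphere_geometry(5.0)
        errs = []
        for h in (0.4, 0.3, 0.2):
            v = cw.voxelize(sph, h, blur_sigma=0.0, supersample=2)
            errs.append(abs(v.gray_weighted_volume() - sph.analytic_volume))
        assert errs[0] > errs[1] > errs[2]

    def test_deterministic_given_seed(self):
        sph = make_sphere_geometry(2.0)
        a = cw.voxelize(sph, 0.25, noise_sd=3.0, seed=99)
        b = cw.voxelize(sph, 0.25, noise_sd=3.0, seed=99)
        np.testing.assert_array_equal(a.grid, b.grid)
        c = cw.voxelize(sph, 0.25, noise_sd=3.0, seed=100)
        assert not np.array_equal(a.grid, c.grid)

    def test_invalid_voxel_size_rejected(self):
        with pytest.raises(PhantomError):
            cw.voxelize(make_sphere_geometry(1.0), 0.0)


class TestWeightSeriesSimulation:
    def test_linear_no_soak_no_noise(self):
        s = cw.simulate_weight_series(5.1, soak_params=None, balance_sd=0.0)
        losses = s.weights[0] - s.weights
        np.testing.assert_allclose(losses, [0, 2.04, 4.08, 6.12, 8.16, 10.2], atol=1e-10)

    def test_zero_rate_zero_noise_constant_weight(self):
        s = cw.simulate_weight_series(0.0, soak_params=None, balance_sd=0.0)
        assert np.ptp(s.weights) == 0.0

    def test_negative_rate_rejected(self):
        with pytest.raises(PhantomError):
            cw.simulate_weight_series(-1.0)

    def test_bad_grid_rejected(self):
        with pytest.raises(PhantomError):
            cw.simulate_weight_series(1.0, grid=(0.4, 0.8))
        with pytest.raises(PhantomError):
            cw.simulate_weight_series(1.0, grid=(0.0, 0.8, 0.4))

    def test_deterministic_given_seed(self):
        a = cw.simulate_weight_series(5.0, seed=7)
        b = cw.simulate_weight_series(5.0, seed=7)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_rate_recovered_across_seeds(self):
        """Soak-corrected regression recovers the generator's wear rate to
        within 3 standard errors over 50 simulations."""
        rate = 10.0
        slopes = []
        for seed in range(50):
            s = cw.simulate_weight_series(
                rate, soak_params=SoakParams(1.0, 0.3), balance_sd=0.01, seed=seed
            )
            res = cw.analyze_series(s)
            slopes.append(res.wear_rate)
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - rate) < 3 * max(se, 1e-12)
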