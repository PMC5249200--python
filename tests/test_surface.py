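"""Surface determination: ISO-50 threshold, adaptive refinement, mesh
volume, MPE utility."""

import numpy as np
import pytest
import trimesh
from skimage import measure

import cupwear as cw
from cupwear.phantom import make_sphere_geometry
from cupwear.surface import SurfaceError, SurfaceModel


def two_level_volume(lo, hi, n=12):
    rng = np.random.default_rng(5)
    grid = np.where(rng.random((n, n, n)) < 0.5, float(lo), float(hi))
    return cw.VoxelVolume(grid, voxel_size=1.0)


class TestIso50Threshold:
    @pytest.mark.parametrize("lo,hi", [(0, 100), (20, 80)])
    def test_midpoint_of_two_modes(self, lo, hi):
        thr = cw.iso50_threshold(two_level_volume(lo, hi))
        assert thr == pytest.approx((lo + hi) / 2, abs=1.0)

    def test_noisy_histogram_close_to_noiseless(self, sphere_volume):
        clean = cw.iso50_threshold(sphere_volume)
        noisy = cw.iso50_threshold(cw.add_noise(sphere_volume, 5.0, seed=42))
        assert noisy == pytest.approx(clean, abs=2.0)

    def test_unimodal_histogram_rejected(self):
        rng = np.random.default_rng(0)
        flat = cw.VoxelVolume(7.0 + rng.normal(0, 0.1, (12, 12, 12)), 1.0)
        with pytest.raises(SurfaceError, match="cannot separate material"):
            cw.iso50_threshold(flat)


class TestExtractSurface:
    def test_sphere_volume_within_one_percent(self, sphere_volume):
        mesh = cw.extract_surface(sphere_volume)
        true = 4.0 / 3.0 * np.pi * 125.0
        assert mesh.enclosed_volume == pytest.approx(true, rel=0.01)

    def test_adaptive_off_is_pure_isosurface(self, sphere_volume):
        """With the refinement disabled the mesh must coincide with a plain
        marching-cubes iso-surface at the same level."""
        thr = cw.iso50_threshold(sphere_volume)
        ours = cw.extract_surface(sphere_volume, threshold=thr, adaptive=False)
        verts, faces, _, _ = measure.marching_cubes(
            sphere_volume.grid.astype(float), level=thr
        )
        verts = sphere_volume.origin[None, :] + verts * sphere_volume.voxel_size
        oracle = trimesh.Trimesh(verts, faces, process=False)
        assert ours.enclosed_volume == pytest.approx(abs(oracle.volume), rel=1e-9)
        assert len(ours.vertices) == len(oracle.vertices)

    def test_adaptive_beats_global_under_gray_gradient(self, sphere_volume):
        """One-sided additive gray offset (background 0 -> 20 across the
        field): the local 50 % refinement must not be worse than the global
        threshold."""
        nx = sphere_volume.grid.shape[0]
        xs = np.arange(nx) / (nx - 1)
        offset = 20.0 * np.clip(2 * xs - 1, 0, 1)
        gvol = cw.VoxelVolume(
            sphere_volume.grid + offset[:, None, None],
            sphere_volume.voxel_size,
            sphere_volume.origin,
        )
        thr = cw.iso50_threshold(gvol)
        true = 4.0 / 3.0 * np.pi * 125.0
        err_global = abs(cw.extract_surface(gvol, thr, adaptive=False).enclosed_volume - true)
        err_adaptive = abs(cw.extract_surface(gvol, thr, adaptive=True).enclosed_volume - true)
        assert err_adaptive <= err_global

    def test_threshold_outside_gray_range_rejected(self, sphere_volume):
        with pytest.raises(SurfaceError, match="outside gray range"):
            cw.extract_surface(sphere_volume, threshold=1e4)

    def test_volume_converges_with_resolution(self):
        sph = make_sphere_geometry(5.0)
        errs = []
        for h in (0.4, 0.3, 0.2):
            vol = cw.voxelize(sph, h, blur_sigma=h)
            mesh = cw.extract_surface(vol, adaptive=False)
            errs.append(abs(mesh.enclosed_volume - sph.analytic_volume))
        assert errs[0] > errs[1] > errs[2]

    def test_mesh_and_gray_weighted_volumes_agree(self, sphere_volume):
        """Independent voxel-counting volume vs mesh volume: difference
        bounded by twice the single-voxel surface-shell volume."""
        mesh = cw.extract_surface(sphere_volume)
        voxel_shell = 4 * np.pi * 25.0 * sphere_volume.voxel_size  # A * h
        assert abs(
            mesh.enclosed_volume - sphere_volume.gray_weighted_volume()
        ) <= 2 * voxel_shell


class TestMeshVolume:
    def test_unit_cube(self):
        box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        model = SurfaceModel(box.vertices.view(np.ndarray), box.faces.view(np.ndarray))
        assert cw.mesh_volume(model) == pytest.approx(1.0, rel=1e-12)

    def test_icosphere_converges_to_analytic(self):
        errs = []
        for sub in (1, 2, 3):
            ico = trimesh.creation.icosphere(subdivisions=sub, radius=1.0)
            model = SurfaceModel(ico.vertices.view(np.ndarray), ico.faces.view(np.ndarray))
            errs.append(abs(cw.mesh_volume(model) - 4.0 / 3.0 * np.pi))
        assert errs[0] > errs[1] > errs[2]

    def test_inverted_orientation_same_volume(self):
        box = trimesh.creation.box(extents=(2.0, 1.0, 1.0))
        flipped = SurfaceModel(box.vertices.view(np.ndarray), box.faces[:, ::-1].copy())
        assert cw.mesh_volume(flipped) == pytest.approx(2.0, rel=1e-9)

    def test_open_mesh_rejected(self):
        box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        open_model = SurfaceModel(box.vertices.view(np.ndarray), box.faces[:-1].copy())
        with pytest.raises(SurfaceError, match="closed"):
            cw.mesh_volume(open_model)


class TestMPE:
    @pytest.mark.parametrize("L,expected", [(50.0, 10.0), (0.0, 9.0), (100.0, 11.0)])
    def test_formula(self, L, expected):
        assert cw.mpe_length(L) == pytest.approx(expected, rel=1e-12)

    def test_negative_length_rejected(self):
        with pytest.raises(SurfaceError):
            cw.mpe_length(-1.0)

    def test_predicate(self):
        assert cw.within_mpe(9.9, 50.0)
        assert not cw.within_mpe(10.1, 50.0)
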