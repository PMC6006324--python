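"""Volume MI registration, scaled ICP + TPS, value transfer, averaging."""

import dataclasses

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from jsmap import (ImageVolume, PhantomSpec, SimilarityTransform,
                   build_average_surface, fit_tps, generate_volume,
                   register_surfaces, register_volumes_mi, transfer_values)


def rotation_angle_deg(R1, R2):
    return np.degrees(np.arccos(np.clip(
        (np.trace(R1 @ R2.T) - 1) / 2, -1, 1)))


class TestSimilarityTransform:
    def test_compose_inverse_roundtrip(self):
        rng = np.random.default_rng(0)
        R = Rotation.from_rotvec(rng.normal(size=3) * 0.4).as_matrix()
        t = SimilarityTransform(R, rng.normal(size=3), 1.3)
        pts = rng.normal(size=(20, 3))
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts,
                                   atol=1e-10)

    def test_invalid_rotation_rejected(self):
        with pytest.raises(ValueError):
            SimilarityTransform(2 * np.eye(3), np.zeros(3), 1.0)


class TestSurfaceRegistration:
    def test_known_similarity_recovered(self, bumpy_cap):
        R = Rotation.from_euler("xyz", [10, 4, -6], degrees=True).as_matrix()
        true = SimilarityTransform(R, np.array([5.0, -2.0, 3.0]), 1.1)
        target = trimesh.Trimesh(true.apply(bumpy_cap.vertices),
                                 bumpy_cap.faces, process=False)
        sim, tps, info = register_surfaces(bumpy_cap, target)
        assert abs(sim.scale - 1.1) / 1.1 < 0.01
        assert rotation_angle_deg(sim.rotation, R) < 0.5
        assert np.linalg.norm(sim.translation - true.translation) < 0.2
        assert info["residual_tps"] <= info["residual_similarity"] + 1e-9

    def test_self_registration_identity(self, bumpy_cap):
        sim, tps, info = register_surfaces(bumpy_cap, bumpy_cap)
        assert abs(sim.scale - 1.0) < 1e-6
        assert rotation_angle_deg(sim.rotation, np.eye(3)) < 1e-3
        disp = np.linalg.norm(tps.apply(bumpy_cap.vertices)
                              - bumpy_cap.vertices, axis=1)
        assert disp.max() < 0.01


class TestTPS:
    def test_exact_interpolation_at_zero_lambda(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3)) * 10
        Y = X + rng.normal(size=(20, 3))
        tps = fit_tps(X, Y, lam=0.0)
        np.testing.assert_allclose(tps.apply(X), Y, atol=1e-9)

    def test_coplanar_control_points_rejected(self):
        rng = np.random.default_rng(2)
        X = np.c_[rng.normal(size=(12, 2)), np.zeros(12)]
        with pytest.raises(ValueError, match="coplanar"):
            fit_tps(X, rng.normal(size=(12, 3)))

    def test_bending_energy_non_increasing_in_lambda(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 3)) * 8
        Y = X + rng.normal(size=(30, 3)) * 1.5
        energies = [fit_tps(X, Y, lam=lam).bending_energy()
                    for lam in (0.0, 0.1, 1.0, 10.0)]
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_against_scipy_rbf_interpolator(self):
        # independent cross-check: at lambda 0 both interpolate exactly and
        # should agree closely away from the control points
        from scipy.interpolate import RBFInterpolator

        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3)) * 10
        Y = X + rng.normal(size=(40, 3))
        tps = fit_tps(X, Y, lam=0.0)
        rbf = RBFInterpolator(X, Y, kernel="linear", degree=1)
        Q = rng.normal(size=(50, 3)) * 8
        np.testing.assert_allclose(tps.apply(Q), rbf(Q), atol=1e-6)


class TestVolumeMI:
    @pytest.fixture(scope="class")
    def small_phantom(self):
        return PhantomSpec(geometry="ball_socket", femoral_radius=8.0,
                           gap=3.0, cortex_thickness=1.5,
                           spacing=(0.6, 0.6, 0.6), psf=(0.8, 0.8, 0.8),
                           psf_is_fwhm=False, noise_sd=10.0, margin=3.0,
                           supersample=2, seed=3)

    def test_self_registration(self, small_phantom):
        vol, _, _ = generate_volume(small_phantom)
        tr, info = register_volumes_mi(vol, vol)
        assert np.linalg.norm(tr.translation) < 0.05
        assert rotation_angle_deg(tr.rotation, np.eye(3)) < 0.1
        assert info["final_metric"] <= info["initial_metric"] + 1e-9

    def test_known_translation_recovered(self, small_phantom):
        fixed, _, _ = generate_volume(small_phantom)
        moved_spec = dataclasses.replace(small_phantom,
                                         center_offset=(2.0, -1.0, 3.0),
                                         seed=4)
        moving, _, _ = generate_volume(moved_spec)
        tr, _ = register_volumes_mi(fixed, moving)
        np.testing.assert_allclose(tr.translation, [2.0, -1.0, 3.0],
                                   atol=0.2)

    def test_constant_volumes_identity_with_warning(self):
        c = ImageVolume(np.full((12, 12, 12), 7.0), np.eye(4))
        with pytest.warns(UserWarning, match="constant"):
            tr, _ = register_volumes_mi(c, c)
        assert tr.scale == 1.0
        assert np.linalg.norm(tr.translation) == 0.0


class TestTransferValues:
    def test_identity_transfer_preserves_values(self, bumpy_cap):
        values = np.asarray(bumpy_cap.vertices)[:, 2].copy()
        out = transfer_values(np.asarray(bumpy_cap.vertices), values,
                              bumpy_cap, smooth_passes=0)
        np.testing.assert_array_equal(out, values)

    def test_constant_map_is_smoothing_fixed_point(self, bumpy_cap):
        values = np.full(len(bumpy_cap.vertices), 2.75)
        out = transfer_values(np.asarray(bumpy_cap.vertices), values,
                              bumpy_cap, smooth_passes=1)
        np.testing.assert_allclose(out, 2.75, atol=1e-12)

    def test_known_permutation(self, bumpy_cap):
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(bumpy_cap.vertices))
        values = rng.normal(size=len(perm))
        out = transfer_values(np.asarray(bumpy_cap.vertices)[perm],
                              values, bumpy_cap, smooth_passes=0)
        np.testing.assert_array_equal(out, values[np.argsort(perm)])

    def test_range_preserved_under_smoothing(self, bumpy_cap):
        rng = np.random.default_rng(6)
        values = rng.normal(3.0, 0.5, len(bumpy_cap.vertices))
        out = transfer_values(np.asarray(bumpy_cap.vertices), values,
                              bumpy_cap, smooth_passes=2)
        assert out.max() <= values.max() + 1e-12
        assert out.min() >= values.min() - 1e-12


class TestAverageSurface:
    def test_identical_copies_fixed_point(self, bumpy_cap):
        copies = [bumpy_cap.copy() for _ in range(4)]
        avg = build_average_surface(copies, register=False)
        d = np.linalg.norm(np.asarray(avg.mesh.vertices)
                           - np.asarray(bumpy_cap.vertices), axis=1)
        assert d.max() < 0.01

    def test_symmetric_offsets_average_to_midpoint(self, bumpy_cap):
        n = np.asarray(bumpy_cap.vertex_normals)
        up = trimesh.Trimesh(bumpy_cap.vertices + 1.0 * n, bumpy_cap.faces,
                             process=False)
        down = trimesh.Trimesh(bumpy_cap.vertices - 1.0 * n, bumpy_cap.faces,
                               process=False)
        avg = build_average_surface([up, down], register=False)
        from jsmap import SurfaceProjector

        d = SurfaceProjector(bumpy_cap).distance(
            np.asarray(avg.mesh.vertices))
        assert np.median(d) < 0.05

    def test_target_vertex_count(self, bumpy_cap):
        copies = [bumpy_cap.copy() for _ in range(2)]
        avg = build_average_surface(copies, register=False,
                                    target_vertex_count=2300)
        assert 0.9 * 2300 <= len(avg.mesh.vertices) <= 1.1 * 2300

    def test_single_surface_rejected(self, bumpy_cap):
        with pytest.raises(ValueError):
            build_average_surface([bumpy_cap])
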