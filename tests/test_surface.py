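"""Surface meshing, opposing-bone projection, patch cutting, remeshing."""

import numpy as np
import pytest
import trimesh

from jsmap import (ImageVolume, SurfaceProjector, cut_patch, mesh_from_mask,
                   project_opposing_bone, retriangulate)


@pytest.fixture(scope="module")
def ball_mask():
    # solid ball radius 10 mm on isotropic 0.5 mm voxels
    n = 50
    affine = np.eye(4) * 0.5
    affine[3, 3] = 1.0
    affine[:3, 3] = -0.5 * (n - 1) / 2
    idx = np.arange(n)
    i, j, k = np.meshgrid(idx, idx, idx, indexing="ij")
    world = np.stack([i, j, k], axis=-1) * 0.5 + affine[:3, 3]
    mask = (np.linalg.norm(world, axis=-1) <= 10.0).astype(np.uint8)
    return ImageVolume(mask, affine)


@pytest.fixture(scope="module")
def ball_surface(ball_mask):
    return mesh_from_mask(ball_mask)


def test_sphere_area_within_two_percent(ball_surface):
    assert abs(ball_surface.area - 4 * np.pi * 100) / (4 * np.pi * 100) < 0.02


def test_normals_point_outward(ball_surface):
    v = np.asarray(ball_surface.vertices)
    n = np.asarray(ball_surface.vertex_normals)
    dots = np.einsum("ij,ij->i", n, v - v.mean(axis=0))
    assert (dots > 0).all()


def test_empty_mask_raises():
    with pytest.raises(ValueError, match="empty"):
        mesh_from_mask(ImageVolume(np.zeros((8, 8, 8)), np.eye(4)))


class TestOpposingProjection:
    @pytest.fixture(scope="class")
    def plate_scene(self):
        # single square face at origin, normal +z, facing a bright plate
        mesh = trimesh.Trimesh(
            vertices=[[-1, -1, 0], [1, -1, 0], [1, 1, 0], [-1, 1, 0]],
            faces=[[0, 1, 2], [0, 2, 3]], process=False)

        def volume_with_plate(z_lo, z_hi):
            n = 40
            affine = np.eye(4) * 0.5
            affine[3, 3] = 1.0
            affine[:3, 3] = -10.0
            z = -10.0 + 0.5 * np.arange(n)
            data = np.full((n, n, n), 35.0, dtype=float)
            data[:, :, (z >= z_lo) & (z <= z_hi)] = 1500.0
            return ImageVolume(data, affine)

        return mesh, volume_with_plate

    def test_plate_within_reach(self, plate_scene):
        mesh, make = plate_scene
        vol = make(3.0, 4.0)
        values = project_opposing_bone(mesh, vol, search_depth=5.0)
        np.testing.assert_allclose(values, 1500.0, atol=1e-6)

    def test_background_only(self, plate_scene):
        mesh, make = plate_scene
        vol = make(100.0, 101.0)  # no plate inside the volume
        values = project_opposing_bone(mesh, vol, search_depth=5.0)
        np.testing.assert_allclose(values, 35.0, atol=1e-6)

    def test_plate_beyond_search_depth(self, plate_scene):
        mesh, make = plate_scene
        vol = make(6.0, 7.0)
        values = project_opposing_bone(mesh, vol, search_depth=5.0)
        np.testing.assert_allclose(values, 35.0, atol=1e-6)

    def test_monotone_in_search_depth(self, plate_scene):
        mesh, make = plate_scene
        vol = make(6.0, 7.0)
        shallow = project_opposing_bone(mesh, vol, search_depth=4.0)
        deep = project_opposing_bone(mesh, vol, search_depth=8.0)
        assert (deep >= shallow - 1e-9).all()
        assert deep.max() == pytest.approx(1500.0, abs=1e-6)


class TestCutPatch:
    def equator_loop(self, radius=10.0, n=72, z=0.0):
        phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
        r = np.sqrt(max(radius ** 2 - z ** 2, 0.0))
        pts = np.stack([r * np.cos(phi), r * np.sin(phi),
                        np.full(n, z)], axis=1)
        return np.vstack([pts, pts[:1]])

    def test_hemisphere_area(self, ball_surface):
        patch = cut_patch(ball_surface, self.equator_loop(),
                          seed_point=np.array([0.0, 0.0, 11.0]))
        hemisphere = 2 * np.pi * 100
        assert abs(patch.mesh.area - hemisphere) / hemisphere < 0.03

    def test_partition_property(self, ball_surface):
        patch_n = cut_patch(ball_surface, self.equator_loop(),
                            seed_point=np.array([0.0, 0.0, 11.0]))
        patch_s = cut_patch(ball_surface, self.equator_loop(),
                            seed_point=np.array([0.0, 0.0, -11.0]))
        assert patch_n.n_vertices + patch_s.n_vertices \
            == len(ball_surface.vertices) + len(np.unique(patch_n.boundary))

    def test_enclosing_loop_keeps_whole_mesh(self, ball_surface):
        # a loop that does not separate the surface encloses everything:
        # cutting an open hemisphere along its own rim returns it unchanged
        hemi = cut_patch(ball_surface, self.equator_loop(),
                         seed_point=np.array([0.0, 0.0, 11.0]))
        rim = np.asarray(hemi.mesh.vertices)[hemi.boundary]
        rim_loop = np.vstack([rim, rim[:1]])
        again = cut_patch(hemi.mesh, rim_loop,
                          seed_point=np.array([0.0, 0.0, 11.0]))
        assert again.n_vertices == hemi.n_vertices

    def test_open_polyline_rejected(self, ball_surface):
        loop = self.equator_loop()[:-1]  # drop the closing point
        with pytest.raises(ValueError, match="open"):
            cut_patch(ball_surface, loop,
                      seed_point=np.array([0.0, 0.0, 11.0]))

    def test_unsnappable_polyline_rejected(self, ball_surface):
        loop = self.equator_loop(radius=30.0)
        with pytest.raises(ValueError, match="snap"):
            cut_patch(ball_surface, loop,
                      seed_point=np.array([0.0, 0.0, 11.0]))

    def test_self_intersecting_polyline_rejected(self, ball_surface):
        # bowtie near the pole: two segments cross on the surface
        corners = np.array([[0.0, 0.0], [4.0, 4.0], [4.0, 0.0], [0.0, 4.0]])
        pts = []
        for (x0, y0), (x1, y1) in zip(corners, np.roll(corners, -1, axis=0)):
            for f in np.linspace(0, 1, 15, endpoint=False):
                x, y = x0 + f * (x1 - x0), y0 + f * (y1 - y0)
                pts.append([x, y, np.sqrt(100.0 - x * x - y * y)])
        pts.append(pts[0])
        with pytest.raises(ValueError, match="self-intersect"):
            cut_patch(ball_surface, np.asarray(pts),
                      seed_point=np.array([0, 0, 11.0]))

    def test_side_chosen_by_opposing_values(self, ball_surface):
        vals = (np.asarray(ball_surface.vertices)[:, 2] > 0) * 1500.0 + 35.0
        patch = cut_patch(ball_surface, self.equator_loop(),
                          opposing_values=vals)
        assert np.median(np.asarray(patch.mesh.vertices)[:, 2]) > 0


class TestRetriangulate:
    @pytest.fixture(scope="class")
    def hemisphere(self, ball_surface):
        phi = np.linspace(0, 2 * np.pi, 72, endpoint=False)
        pts = np.stack([10 * np.cos(phi), 10 * np.sin(phi),
                        np.zeros(72)], axis=1)
        loop = np.vstack([pts, pts[:1]])
        return cut_patch(ball_surface, loop,
                         seed_point=np.array([0.0, 0.0, 11.0]))

    @pytest.mark.parametrize("target", [600, 4000])
    def test_vertex_count_within_ten_percent(self, hemisphere, target):
        out = retriangulate(hemisphere, target)
        assert 0.9 * target <= out.n_vertices <= 1.1 * target

    def test_geometry_preserved(self, hemisphere):
        out = retriangulate(hemisphere, 4000)
        edges = np.asarray(hemisphere.mesh.edges_unique_length)
        tol = 0.5 * edges.mean()
        fwd = SurfaceProjector(hemisphere.mesh).distance(
            np.asarray(out.mesh.vertices)).max()
        bwd = SurfaceProjector(out.mesh).distance(
            np.asarray(hemisphere.mesh.vertices)).max()
        assert max(fwd, bwd) <= tol

    def test_area_against_analytic_hemisphere(self, hemisphere):
        out = retriangulate(hemisphere, 2000)
        hemisphere_area = 2 * np.pi * 100
        assert abs(out.mesh.area - hemisphere_area) / hemisphere_area < 0.03

    def test_normals_close_to_source(self, hemisphere):
        out = retriangulate(hemisphere, 2000)
        src = SurfaceProjector(hemisphere.mesh)
        ref = src.interpolate(np.asarray(out.mesh.vertices),
                              np.asarray(hemisphere.mesh.vertex_normals))
        ref /= np.linalg.norm(ref, axis=1, keepdims=True)
        dots = np.einsum("ij,ij->i", out.normals, ref)
        assert np.degrees(np.arccos(np.clip(dots, -1, 1))).max() < 15.0

    def test_minimum_target_enforced(self, hemisphere):
        with pytest.raises(ValueError):
            retriangulate(hemisphere, 50)
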