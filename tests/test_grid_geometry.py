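"""Grid interpolation, corner frames, dural surfaces, and ray projection."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from elecloc import (
    dural_surface,
    grid_frame,
    interp_grid,
    interp_line,
    project_electrodes,
)

SQUARE = np.array([[0.0, 0, 0], [0, 60, 0], [60, 0, 0], [60, 60, 0]])


class TestInterpGrid:
    def test_2x2_returns_corners(self, rng):
        corners = rng.normal(size=(4, 3)) * 10
        assert np.allclose(interp_grid(corners, 2, 2), corners)

    def test_unit_square_center(self):
        corners = np.array([[0.0, 0, 0], [0, 1, 0], [1, 0, 0], [1, 1, 0]])
        grid = interp_grid(corners, 3, 3)
        assert np.allclose(grid[4], (0.5, 0.5, 0))

    def test_256_channel_grid_4mm_pitch(self):
        """16x16 grid spanning 60 mm per side: 256 contacts at 4 mm spacing."""
        grid = interp_grid(SQUARE, 16, 16)
        assert grid.shape == (256, 3)
        d = np.linalg.norm(grid[:, None] - grid[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert np.allclose(d.min(axis=1), 4.0)

    def test_corner_channel_convention(self):
        """Corner 3 must be channel 241 of a 16x16 grid (1-indexed)."""
        grid = interp_grid(SQUARE, 16, 16)
        assert np.allclose(grid[0], SQUARE[0])        # channel 1
        assert np.allclose(grid[15], SQUARE[1])       # channel 16
        assert np.allclose(grid[240], SQUARE[2])      # channel 241
        assert np.allclose(grid[255], SQUARE[3])      # channel 256

    def test_affine_equivariance(self, rng):
        corners = rng.normal(size=(4, 3)) * 20
        A = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        b = rng.normal(size=3) * 5
        lhs = interp_grid(corners @ A.T + b, 5, 7)
        rhs = interp_grid(corners, 5, 7) @ A.T + b
        assert np.abs(lhs - rhs).max() < 1e-9

    def test_collinear_corners_rejected(self):
        bad = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            interp_grid(bad, 4, 4)


class TestGridFrame:
    def test_planar_square_normal(self):
        f = grid_frame(SQUARE, 16, 16)
        assert np.isclose(abs(f.mean_normal[2]), 1.0)
        assert np.isclose(np.linalg.norm(f.mean_normal), 1.0)
        assert np.allclose(np.linalg.norm(f.corner_normals, axis=1), 1.0)

    def test_bent_quad_normal_within_10_degrees(self):
        corners = SQUARE.copy()
        corners[3, 2] = 2.0  # lift one corner 2 mm
        f = grid_frame(corners, 16, 16)
        cos = abs(f.mean_normal @ np.array([0.0, 0, 1]))
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 10.0

    def test_nonconvex_ordering_normals_made_consistent(self):
        # one corner pulled inside the triangle of the others: naive
        # adjacent-edge cross products would flip sign at that corner
        corners = np.array([[0.0, 0, 0], [0, 10, 0], [10, 0, 0], [2.0, 2.0, 0]])
        f = grid_frame(corners, 4, 4)
        dots = f.corner_normals @ f.corner_normals[0]
        assert np.all(dots > 0)

    def test_orientation_away_from_reference(self):
        f = grid_frame(SQUARE + (0, 0, 50), 4, 4, orient_away_from=np.zeros(3))
        assert f.mean_normal[2] > 0

    def test_mean_normal_of_corner_normals(self):
        corners = SQUARE.copy()
        corners[0, 2] = 1.0
        f = grid_frame(corners, 8, 8)
        expected = f.corner_normals.mean(axis=0)
        expected /= np.linalg.norm(expected)
        assert np.allclose(np.abs(f.mean_normal @ expected), 1.0)


class TestDuralSurface:
    def test_hull_of_convex_mesh_matches_volume(self):
        from elecloc.fixtures import make_pial_fixture

        sphere = make_pial_fixture(bumpiness=0.0, seed=0)["pial"]
        hull = dural_surface(sphere, kind="convex_hull")
        assert hull.mesh.volume() >= sphere.volume() - 1e-6
        assert np.isclose(hull.mesh.volume(), sphere.volume(), rtol=1e-6)

    def test_hull_encloses_indented_pial(self, pial_fix):
        pial = pial_fix["pial"]  # has ~5 mm sulcal indentations
        hull = dural_surface(pial, kind="convex_hull")
        assert hull.mesh.volume() > pial.volume()
        # point-in-hull oracle: every pial vertex satisfies the hull's
        # facet inequalities
        h = ConvexHull(pial.vertices)
        slack = h.equations[:, :3] @ pial.vertices.T + h.equations[:, 3:]
        assert slack.max() <= 1e-9

    def test_zero_smoothing_equals_subdivided_hull(self, pial_fix):
        a = dural_surface(pial_fix["pial"], kind="smoothed_hull", smoothing_iters=0)
        b = dural_surface(pial_fix["pial"], kind="smoothed_hull", smoothing_iters=0)
        assert np.array_equal(a.mesh.vertices, b.mesh.vertices)
        # subdivision respected the 3 mm edge bound
        v, t = a.mesh.vertices, a.mesh.triangles
        e = np.linalg.norm(v[t[:, 0]] - v[t[:, 1]], axis=1)
        assert e.max() <= 3.0 + 1e-9

    def test_smoothed_hull_watertight_and_near_hull(self, pial_fix):
        import trimesh as tm

        surf = dural_surface(pial_fix["pial"], kind="smoothed_hull", smoothing_iters=30)
        mesh = tm.Trimesh(surf.mesh.vertices, surf.mesh.triangles, process=False)
        assert mesh.is_watertight
        hull = dural_surface(pial_fix["pial"], kind="convex_hull")
        assert abs(surf.mesh.volume() - hull.mesh.volume()) / hull.mesh.volume() < 0.05

    def test_ofc_submesh_excludes_labels(self, pial_fix):
        pial, sectors = pial_fix["pial"], pial_fix["sector_ids"]
        excl = {1}
        surf = dural_surface(pial, kind="ofc_submesh", annot=sectors, exclude_labels=excl)
        full = dural_surface(pial, kind="convex_hull")
        assert surf.mesh.volume() < full.mesh.volume()

    def test_too_few_vertices_rejected(self):
        from elecloc import TriMesh

        flat = TriMesh(np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]), np.array([[0, 1, 2]]))
        with pytest.raises(Exception):
            dural_surface(flat, kind="convex_hull")


@pytest.fixture(scope="module")
def unit_sphere_surface():
    from elecloc.fixtures import make_pial_fixture

    sphere = make_pial_fixture(n_subdiv=4, bumpiness=0.0, radius=1.0, seed=0)["pial"]
    return dural_surface(sphere, kind="convex_hull")


class TestProjectElectrodes:
    def test_point_on_surface_stays(self, unit_sphere_surface):
        v = unit_sphere_surface.mesh.vertices[10]
        res = project_electrodes(v[None, :], unit_sphere_surface, v / np.linalg.norm(v))
        assert res.displacement[0] < 1e-6

    def test_center_projects_to_radius_one(self, unit_sphere_surface):
        d = np.array([1.0, 2.0, 2.0]) / 3.0
        res = project_electrodes(np.zeros((1, 3)), unit_sphere_surface, d)
        r = np.linalg.norm(res.coords[0])
        # lands on the facet plane, within the chord sag of the fine mesh
        assert 0.99 < r <= 1.0 + 1e-9
        assert np.allclose(res.coords[0] / r, d, atol=1e-9)
        assert not res.missed[0]

    def test_idempotent(self, unit_sphere_surface):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(20, 3)) * 0.3
        d = np.array([0.0, 0, 1.0])
        once = project_electrodes(pts, unit_sphere_surface, d)
        twice = project_electrodes(once.coords, unit_sphere_surface, d)
        assert np.abs(twice.coords - once.coords).max() < 1e-6

    def test_buried_grid_lands_on_hull_order_preserved(self, pial_fix):
        """A 16x16 grid pushed 8 mm inside the hull (brain shift) projects
        onto the hull with no neighbor crossings and non-shrinking spacing."""
        pial = pial_fix["pial"]
        surf = dural_surface(pial, kind="convex_hull")
        direction = np.array([1.0, 0, 0])
        # grid on a plane at x = r - 8
        y = np.linspace(-25, 25, 16)
        grid = np.array([[40.0, yy, zz] for yy in y for zz in y])
        res = project_electrodes(grid, surf, direction)
        assert not res.missed.any()
        # on-hull within 1e-6 mm (hull facet inequalities)
        h = ConvexHull(pial.vertices)
        slack = h.equations[:, :3] @ res.coords.T + h.equations[:, 3:]
        assert np.abs(slack.max(axis=0)).max() < 1e-6
        # ray projection moves points only along `direction`: the
        # transverse layout (and hence row-major ordering) is unchanged
        perp = res.coords - np.outer(res.coords @ direction, direction)
        perp0 = grid - np.outer(grid @ direction, direction)
        assert np.abs(perp - perp0).max() < 1e-9
        # expansion property: pairwise spacing never decreases
        before = np.linalg.norm(grid[:-1] - grid[1:], axis=1)
        after = np.linalg.norm(res.coords[:-1] - res.coords[1:], axis=1)
        assert np.all(after >= before - 1e-9)

    def test_miss_falls_back_to_nearest_point(self, unit_sphere_surface):
        # pointing away from the surface from outside: the ray misses
        res = project_electrodes(
            np.array([[2.0, 0, 0]]), unit_sphere_surface, np.array([1.0, 0, 0])
        )
        assert res.missed[0]
        assert np.linalg.norm(res.coords[0]) <= 1.0 + 1e-6

    def test_agrees_with_independent_ray_caster(self, pial_fix):
        """Brute-force oracle: solve [-d, b-a, c-a] (t,u,v) = o-a for every
        triangle and take the smallest non-negative t."""
        surf = dural_surface(pial_fix["pial"], kind="smoothed_hull", smoothing_iters=10)
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(25, 3)) * 15
        d = np.array([0.0, 0.6, 0.8])
        res = project_electrodes(pts, surf, d)
        v, tris = surf.mesh.vertices, surf.mesh.triangles
        a, b, c = v[tris[:, 0]], v[tris[:, 1]], v[tris[:, 2]]
        M = np.stack([np.broadcast_to(-d, a.shape), b - a, c - a], axis=-1)
        for i, o in enumerate(pts):
            if res.missed[i]:
                continue
            sol = np.linalg.solve(M, (o[None, :] - a)[..., None])[..., 0]
            t, u, w = sol[:, 0], sol[:, 1], sol[:, 2]
            hit = (u >= -1e-9) & (w >= -1e-9) & (u + w <= 1 + 1e-9) & (t >= -1e-9)
            assert hit.any()
            t_first = t[hit].min()
            assert np.linalg.norm(res.coords[i] - (o + t_first * d)) < 1e-6


class TestInterpLine:
    def test_midpoint(self):
        pts = interp_line(np.array([[0.0, 0, 0], [0, 0, 10]]), 3)
        assert np.allclose(pts[1], (0, 0, 5))

    def test_two_points_are_endpoints(self):
        ends = np.array([[1.0, 2, 3], [4.0, 5, 6]])
        assert np.allclose(interp_line(ends, 2), ends)

    def test_depth_electrode_5mm_pitch(self):
        """10 contacts along a 45 mm trajectory sit at 5 mm spacing."""
        pts = interp_line(np.array([[0.0, 0, 0], [0, 45.0, 0]]), 10)
        gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert np.allclose(gaps, 5.0)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            interp_line(np.zeros((2, 3)), 1)
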