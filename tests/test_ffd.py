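"""Forward FFD: Bernstein weights, grid fitting, embedding, deformation."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

import ffdedit as fe
from ffdedit import ffd


def bernstein_scalar(degree: int, i: int, t: float) -> float:
    """Independent univariate oracle via direct binomial expansion."""
    from math import comb

    return comb(degree, i) * (1 - t) ** (degree - i) * t**i


class TestBernsteinWeights:
    def test_degree1_midpoint_all_equal(self):
        w = fe.bernstein_weights((1, 1, 1), (0.5, 0.5, 0.5))
        assert w.shape == (2, 2, 2)
        assert np.allclose(w, 0.125)

    def test_endpoint_concentrates_on_corner(self):
        w = fe.bernstein_weights((5, 5, 5), (0.0, 0.0, 0.0))
        assert w[0, 0, 0] == pytest.approx(1.0)
        assert np.sum(np.abs(w)) == pytest.approx(1.0)

    def test_outer_product_of_univariate_bases(self):
        # degrees (2,1,1) at (0.25, 0.5, 0.5): cross-check every entry
        # against independent scalar Bernstein evaluation per axis
        w = fe.bernstein_weights((2, 1, 1), (0.25, 0.5, 0.5))
        expect_i = [bernstein_scalar(2, i, 0.25) for i in range(3)]
        assert expect_i == pytest.approx([0.5625, 0.375, 0.0625])
        for i in range(3):
            for j in range(2):
                for k in range(2):
                    assert w[i, j, k] == pytest.approx(
                        expect_i[i]
                        * bernstein_scalar(1, j, 0.5)
                        * bernstein_scalar(1, k, 0.5)
                    )

    def test_partition_of_unity_1000_random_points(self):
        rng = np.random.default_rng(42)
        for stu in rng.random((1000, 3)):
            w = fe.bernstein_weights((5, 5, 5), tuple(stu))
            assert abs(w.sum() - 1.0) < 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(
        st.tuples(*[st.floats(0, 1) for _ in range(3)]),
        st.tuples(*[st.integers(1, 6) for _ in range(3)]),
    )
    def test_partition_of_unity_property(self, stu, degrees):
        w = fe.bernstein_weights(degrees, stu)
        assert abs(w.sum() - 1.0) < 1e-12
        assert np.all(w >= 0)

    def test_nan_rejected(self):
        with pytest.raises(fe.InputError):
            fe.bernstein_weights((2, 2, 2), (float("nan"), 0.5, 0.5))


class TestGridFitting:
    def test_unit_cube_no_padding(self, unit_cube):
        grid = fe.fit_global_grid(unit_cube, (2, 2, 2), padding=0.0)
        assert np.allclose(grid.origin, [0, 0, 0])
        assert np.allclose(np.linalg.norm(grid.axes, axis=1), 1.0)

    def test_unit_cube_padded(self, unit_cube):
        grid = fe.fit_global_grid(unit_cube, (2, 2, 2), padding=0.1)
        assert np.allclose(grid.origin, [-0.1, -0.1, -0.1])
        assert np.allclose(np.linalg.norm(grid.axes, axis=1), 1.2)

    def test_default_grid_has_216_control_points(self, unit_sphere):
        grid = fe.fit_global_grid(unit_sphere)
        assert grid.degrees == (5, 5, 5)
        assert grid.n_control_points == 216

    def test_all_vertices_embed_inside(self, unit_sphere):
        grid = fe.fit_global_grid(unit_sphere, padding=0.05)
        coords = fe.embed(unit_sphere, grid)
        assert coords.embedded.all()
        assert np.all(coords.stu >= 0) and np.all(coords.stu <= 1)

    def test_degenerate_mesh_names_axis(self):
        flat = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
            faces=[[0, 1, 2]],
            process=False,
        )
        with pytest.raises(fe.InputError, match="z axis"):
            fe.fit_global_grid(flat, (2, 2, 2))

    def test_local_grid_geometry_and_count(self):
        grid = fe.fit_local_grid((0, 0, 0), (2, 2, 2), (5, 5, 5))
        assert np.allclose(grid.origin, [-1, -1, -1])
        assert grid.n_control_points == 216

    def test_local_grid_matches_global_at_zero_padding(self, unit_sphere):
        g = fe.fit_global_grid(unit_sphere, (3, 3, 3), padding=0.0)
        v = np.asarray(unit_sphere.vertices)
        center = (v.min(0) + v.max(0)) / 2
        size = v.max(0) - v.min(0)
        loc = fe.fit_local_grid(center, size, (3, 3, 3))
        assert np.allclose(loc.origin, g.origin)
        assert np.allclose(loc.axes, g.axes)
        assert np.allclose(loc.control_points, g.control_points)

    def test_nonpositive_local_size_rejected(self):
        with pytest.raises(fe.InputError):
            fe.fit_local_grid((0, 0, 0), (1, 0, 1), (2, 2, 2))

    def test_undeformed_lattice_is_regular(self):
        grid = fe.fit_local_grid((0, 0, 0), (2, 4, 6), (2, 3, 4))
        l, m, n = grid.degrees
        for idx in [(0, 0, 0), (l, m, n), (1, 2, 3)]:
            i, j, k = idx
            expect = grid.origin + np.array([i / l, j / m, k / n]) @ grid.axes
            assert np.allclose(grid.control_points[i, j, k], expect)
        assert np.all(grid.displacements == 0)


class TestEmbedDeform:
    def test_frame_corners(self):
        grid = fe.fit_local_grid((0.5, 0.5, 0.5), (1, 1, 1), (2, 2, 2))
        mesh = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 1, 1]], faces=[[0, 1, 0]], process=False
        )
        coords = fe.embed(mesh, grid)
        assert np.allclose(coords.stu[0], [0, 0, 0])
        assert np.allclose(coords.stu[1], [1, 1, 1])

    @pytest.mark.parametrize("shear", [False, True])
    def test_embed_recomposition_round_trip(self, shear):
        rng = np.random.default_rng(7)
        axes = np.diag([2.0, 3.0, 4.0])
        if shear:
            axes = axes + rng.normal(scale=0.5, size=(3, 3))
        grid = fe.ControlGrid(origin=[1.0, -2.0, 0.5], axes=axes, degrees=(2, 2, 2))
        pts = grid.origin + rng.random((50, 3)) @ grid.axes
        mesh = trimesh.Trimesh(vertices=pts, faces=[[0, 1, 2]], process=False)
        coords = fe.embed(mesh, grid)
        recomposed = grid.origin + coords.stu @ grid.axes
        assert np.abs(recomposed - pts).max() < 1e-10

    def test_zero_displacement_is_identity(self, unit_sphere):
        grid = fe.fit_global_grid(unit_sphere)
        coords = fe.embed(unit_sphere, grid)
        out = fe.deform(unit_sphere, coords, grid)
        assert np.abs(
            np.asarray(out.vertices) - np.asarray(unit_sphere.vertices)
        ).max() < 1e-9
        assert np.array_equal(out.faces, unit_sphere.faces)

    def test_constant_displacement_translates(self, unit_sphere):
        grid = fe.fit_global_grid(unit_sphere)
        g = grid.copy()
        g.displacements[...] = [0.3, -0.2, 0.1]
        coords = fe.embed(unit_sphere, grid)
        out = fe.deform(unit_sphere, coords, g)
        assert np.abs(
            np.asarray(out.vertices)
            - (np.asarray(unit_sphere.vertices) + [0.3, -0.2, 0.1])
        ).max() < 1e-9

    def test_affine_map_reproduced_exactly(self, unit_sphere):
        # Bernstein polynomials reproduce affine functions: moving control
        # points by an affine map must move every vertex by the same map
        rng = np.random.default_rng(11)
        grid = fe.fit_global_grid(unit_sphere, (5, 5, 5), padding=0.05)
        for _ in range(5):
            A = np.eye(3) + rng.normal(scale=0.2, size=(3, 3))
            b = rng.normal(scale=1.0, size=3)
            g = grid.copy()
            p = grid.control_points.reshape(-1, 3)
            g.displacements = (p @ A.T + b - p).reshape(grid.displacements.shape)
            coords = fe.embed(unit_sphere, grid)
            out = fe.deform(unit_sphere, coords, g)
            direct = np.asarray(unit_sphere.vertices) @ A.T + b
            assert np.abs(np.asarray(out.vertices) - direct).max() < 1e-8

    def test_vertices_outside_local_grid_bitwise_unchanged(self, unit_sphere):
        grid = fe.fit_local_grid((0, 0, 1.0), (0.8, 0.8, 0.8), (3, 3, 3))
        coords = fe.embed(unit_sphere, grid)
        assert coords.embedded.any() and not coords.embedded.all()
        g = grid.copy()
        g.displacements[...] = [0.5, 0.5, 0.5]
        out = fe.deform(unit_sphere, coords, g)
        outside = ~coords.embedded
        assert np.array_equal(
            np.asarray(out.vertices)[outside],
            np.asarray(unit_sphere.vertices)[outside],
        )
        moved = np.linalg.norm(
            np.asarray(out.vertices)[coords.embedded]
            - np.asarray(unit_sphere.vertices)[coords.embedded],
            axis=1,
        )
        assert moved.max() > 0

    def test_mismatched_coords_grid_rejected(self, unit_sphere):
        grid = fe.fit_global_grid(unit_sphere)
        other = fe.fit_local_grid((0, 0, 0), (1, 1, 1), (5, 5, 5))
        coords = fe.embed(unit_sphere, grid)
        with pytest.raises(fe.InputError):
            fe.deform(unit_sphere, coords, other)

    def test_grid_json_round_trip(self, unit_sphere):
        grid = fe.fit_global_grid(unit_sphere)
        grid.displacements[2, 3, 1] = [0.1, 0.2, 0.3]
        back = fe.ControlGrid.from_dict(grid.to_dict())
        assert back.same_frame(grid)
        assert np.array_equal(back.control_points, grid.control_points)
        assert np.array_equal(back.displacements, grid.displacements)

    def test_singular_frame_rejected(self):
        with pytest.raises(fe.NumericalError):
            fe.ControlGrid(
                origin=[0, 0, 0],
                axes=[[1, 0, 0], [2, 0, 0], [0, 0, 1]],
                degrees=(2, 2, 2),
            )
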