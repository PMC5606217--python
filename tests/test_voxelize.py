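"""Bounds, grids, surface/solid voxelization and their oracles."""

import numpy as np
import pytest
import trimesh

from morphovox.errors import EmptyInput, OutOfBounds, ResolutionOverflow
from morphovox.neurites import MeshConfig
from morphovox.repair import repair
from morphovox.synthetic import MorphogenParams, generate_morphology, toy_mesh
from morphovox.volumes import AABB, BitVolume, make_grid
from morphovox.voxelize import (
    compute_bounds,
    solid_voxelize,
    surface_voxelize,
    voxelize_circuit,
    voxelize_circuit_per_neuron,
)

from oracles import ray_parity_inside


def rot(angle, axis):
    return trimesh.transformations.rotation_matrix(angle, axis)


class TestComputeBounds:
    def test_unit_cube(self):
        cube = trimesh.creation.box().apply_translation((0.5, 0.5, 0.5))
        b = compute_bounds([(cube, None)])
        assert np.allclose(b.min_corner, 0) and np.allclose(b.max_corner, 1)

    def test_two_cubes_union(self):
        c1 = trimesh.creation.box().apply_translation((0.5, 0.5, 0.5))
        c2 = trimesh.creation.box().apply_translation((10.5, 0.5, 0.5))
        b = compute_bounds([(c1, None), (c2, None)])
        assert np.allclose(b.min_corner, 0) and np.allclose(b.max_corner, (11, 1, 1))

    def test_random_rotation_matches_vertex_scan(self):
        rng = np.random.default_rng(0)
        mesh = toy_mesh("torus")
        T = rot(1.1, rng.normal(size=3))
        T[:3, 3] = rng.normal(scale=5, size=3)
        b = compute_bounds([(mesh, T)])
        v = mesh.vertices @ T[:3, :3].T + T[:3, 3]
        assert np.allclose(b.min_corner, v.min(axis=0))
        assert np.allclose(b.max_corner, v.max(axis=0))

    def test_empty_raises(self):
        with pytest.raises(EmptyInput):
            compute_bounds([])


class TestMakeGrid:
    def test_cube_resolution_eight_with_margin(self):
        b = AABB(np.zeros(3), np.ones(3))
        g = make_grid(b, 8)
        assert g.dims == (10, 10, 10)
        assert g.spacing == pytest.approx(1 / 8)
        assert np.allclose(g.origin, -g.spacing)
        assert g.count() == 0

    def test_degenerate_flat_bounds(self):
        b = AABB(np.zeros(3), np.array([4.0, 4.0, 0.0]))
        g = make_grid(b, 4)
        assert g.dims == (6, 6, 3)  # 1 voxel + margins on the flat axis

    def test_largest_axis_gets_resolution(self):
        b = AABB(np.zeros(3), np.array([521.0, 2081.0, 2864.0]))
        g = make_grid(b, 800)
        assert g.dims[2] == 800 + 2

    def test_resolution_overflow(self):
        b = AABB(np.zeros(3), np.ones(3))
        with pytest.raises(ResolutionOverflow):
            make_grid(b, 4096, memory_cap=1 << 20)


class TestBitPacking:
    @pytest.mark.parametrize("dims", [(3, 5, 7), (10, 10, 10), (64, 64, 64), (17, 1, 1)])
    def test_payload_is_one_bit_per_voxel(self, dims):
        vol = BitVolume(np.zeros(3), 1.0, dims)
        n = int(np.prod(dims))
        assert vol.payload.nbytes == (n + 7) // 8

    def test_flat_index_round_trip(self):
        vol = BitVolume(np.zeros(3), 1.0, (4, 5, 6))
        idx = vol.flat_index(3, 2, 5)
        vol.set_flat(np.array([idx]))
        arr = vol.as_array()
        assert arr[3, 2, 5] and arr.sum() == 1
        assert vol.count() == 1

    def test_set_is_idempotent(self):
        vol = BitVolume(np.zeros(3), 1.0, (8, 8, 8))
        idx = np.array([0, 5, 5, 100, 100, 100])
        vol.set_flat(idx)
        before = vol.payload.copy()
        vol.set_flat(idx)
        assert np.array_equal(vol.payload, before)
        assert vol.count() == 3

    def test_array_round_trip(self):
        rng = np.random.default_rng(3)
        arr = rng.random((9, 6, 11)) < 0.3
        vol = BitVolume.from_array(arr, np.zeros(3), 0.5)
        assert np.array_equal(vol.as_array(), arr)


class TestSurfaceVoxelize:
    def grid(self, size=8.0, res=8):
        return make_grid(AABB(np.zeros(3), np.full(3, size)), res)

    def test_triangle_inside_one_voxel(self):
        g = self.grid()
        tri = trimesh.Trimesh(
            vertices=np.array([[4.1, 4.1, 4.1], [4.6, 4.1, 4.1], [4.1, 4.6, 4.1]]),
            faces=[[0, 1, 2]],
            process=False,
        )
        surface_voxelize(g, tri)
        assert g.count() == 1

    def test_square_spans_k_by_k_patch(self):
        # unit spacing grid; square from 0.1..6.9 at z=3.5 covers 7×7 voxels
        g = make_grid(AABB(np.zeros(3), np.full(3, 8.0)), 8)
        a, b = 0.1, 6.9
        sq = trimesh.Trimesh(
            vertices=[[a, a, 3.5], [b, a, 3.5], [b, b, 3.5], [a, b, 3.5]],
            faces=[[0, 1, 2], [0, 2, 3]],
            process=False,
        )
        surface_voxelize(g, sq)
        assert g.count() == 7 * 7

    def test_idempotent(self):
        g = self.grid()
        mesh = toy_mesh("box").apply_translation((4, 4, 4))
        surface_voxelize(g, mesh)
        once = g.payload.copy()
        surface_voxelize(g, mesh)
        assert np.array_equal(g.payload, once)

    def test_out_of_bounds(self):
        g = self.grid(size=2.0, res=4)
        mesh = toy_mesh("box", extents=(50, 50, 50))
        with pytest.raises(OutOfBounds):
            surface_voxelize(g, mesh)

    def test_dense_sampling_oracle_on_rotated_square(self):
        """Conservative rasterization ⊇ dense point sampling of the surface."""
        g = make_grid(AABB(np.zeros(3), np.full(3, 8.0)), 16)
        sq = trimesh.Trimesh(
            vertices=[[1, 1, 1], [7, 2, 3], [6, 7, 6], [1, 5, 4]],
            faces=[[0, 1, 2], [0, 2, 3]],
            process=False,
        )
        surface_voxelize(g, sq)
        arr = g.as_array()
        rng = np.random.default_rng(1)
        for tri in sq.vertices[sq.faces]:
            u, v = rng.random((2, 4000))
            over = u + v > 1
            u[over], v[over] = 1 - u[over], 1 - v[over]
            pts = tri[0] + u[:, None] * (tri[1] - tri[0]) + v[:, None] * (tri[2] - tri[0])
            ijk = g.world_to_index(pts)
            assert arr[ijk[:, 0], ijk[:, 1], ijk[:, 2]].all()


class TestSolidVoxelize:
    def test_all_zero_stays_zero(self):
        g = make_grid(AABB(np.zeros(3), np.full(3, 4.0)), 8)
        assert solid_voxelize(g).count() == 0

    def test_shell_subset_of_solid(self):
        mesh = toy_mesh("icosphere", radius=6.0)
        g = make_grid(compute_bounds([(mesh, None)]), 24)
        surface_voxelize(g, mesh)
        solid = solid_voxelize(g)
        assert not np.any(g.as_array() & ~solid.as_array())

    @pytest.mark.parametrize(
        "shape,kwargs,transform",
        [
            ("box", dict(extents=(5, 3, 2)), None),
            ("icosphere", dict(radius=8.0, subdivisions=3), None),
            ("torus", dict(major_radius=10.0, minor_radius=3.0), rot(np.pi / 2, [1, 0, 0])),
        ],
    )
    def test_ray_parity_oracle_equivalence(self, shape, kwargs, transform):
        """Every non-shell voxel matches the crossing-parity classification
        of its center."""
        mesh = toy_mesh(shape, **kwargs)
        if transform is not None:
            mesh.apply_transform(transform)
        g = make_grid(compute_bounds([(mesh, None)]), 60)
        surface_voxelize(g, mesh)
        shell = g.as_array()
        solid = solid_voxelize(g).as_array()
        inside = ray_parity_inside(mesh, g)
        mismatch = (solid != inside) & ~shell
        assert mismatch.sum() == 0

    def test_axis_aligned_torus_hole_is_a_known_limitation(self):
        """A torus whose axis equals the slicing axis encloses its hole
        within every slice, so the per-slice fill claims it: documented
        behaviour of slice-based solid voxelization."""
        mesh = toy_mesh("torus", major_radius=10.0, minor_radius=3.0)
        g = make_grid(compute_bounds([(mesh, None)]), 40)
        surface_voxelize(g, mesh)
        solid = solid_voxelize(g).as_array()
        inside = ray_parity_inside(mesh, g)
        hole = inside.copy()
        hole[:] = False
        assert np.any(solid & ~inside & ~g.as_array())


class TestVoxelizeCircuit:
    def test_soma_only_neuron_is_a_ball(self):
        from conftest import soma_only

        vol = voxelize_circuit([(soma_only(5.0), None)], resolution=40)
        count = vol.count()
        analytic = 4 / 3 * np.pi * 5.0**3 / vol.spacing**3
        assert count == pytest.approx(analytic, rel=0.2)  # conservative shell inflates

    def test_two_disjoint_neurons_union(self):
        mesh_a = toy_mesh("box", extents=(4, 4, 4)).apply_translation((2, 2, 2))
        mesh_b = toy_mesh("box", extents=(4, 4, 4)).apply_translation((14, 2, 2))
        combined = voxelize_circuit([(mesh_a, None), (mesh_b, None)], resolution=32)
        per = voxelize_circuit_per_neuron(
            [(mesh_a, None), (mesh_b, None)], resolution=32
        )
        union = per[0] | per[1]
        assert np.array_equal(combined.payload, union.payload)

    def test_empty_circuit(self):
        with pytest.raises(EmptyInput):
            voxelize_circuit([], resolution=8)

    def test_worker_count_does_not_change_result(self):
        m = generate_morphology(MorphogenParams(seed=8))
        m, _ = repair(m)
        cfg = MeshConfig(sides=8)
        cfg.soma.subdivisions = 3
        cfg.soma.pull_steps = 20
        v1 = voxelize_circuit([(m, None)], resolution=48, workers=1, mesh_config=cfg)
        v4 = voxelize_circuit([(m, None)], resolution=48, workers=4, mesh_config=cfg)
        assert np.array_equal(v1.payload, v4.payload)
        assert v1.count() > 0
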