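"""Branch decomposition, tube sweeping and watertightness validation."""

import time

import numpy as np
import pytest
import trimesh

from morphovox.errors import InvalidSides
from morphovox.morphology import MorphSample, Structure
from morphovox.neurites import (
    Branch,
    MeshConfig,
    decompose_branches,
    mesh_neuron,
    sweep_branch,
)
from morphovox.repair import repair
from morphovox.synthetic import MorphogenParams, generate_morphology, toy_mesh
from morphovox.validate import validate_watertight

from conftest import chain_section, make_sample, soma_only
from oracles import stack_trace_branches

FAST_MESH = MeshConfig(sides=12)
FAST_MESH.soma.subdivisions = 3
FAST_MESH.soma.pull_steps = 20

_next_id = [10_000]


def attach(parent, positions, radii, order):
    from morphovox.morphology import Section

    samples = [parent.samples[-1]]
    for p, r in zip(positions, radii):
        samples.append(make_sample(_next_id[0], p, r))
        _next_id[0] += 1
    child = Section(samples=samples, order=order)
    parent.children.append(child)
    return child


def three_level_tree():
    """Binary tree of 7 sections with radii forcing a known partition."""
    root = chain_section([(5, 0, 0), (10, 0, 0)], [2.0, 2.0])
    a = attach(root, [(15, 3, 0)], [1.8], 2)      # thicker: continues branch 0
    b = attach(root, [(15, -3, 0)], [1.0], 2)
    attach(a, [(20, 6, 0)], [0.9], 3)
    aa = attach(a, [(20, 3, 0)], [1.5], 3)        # thicker: continues branch 0
    bb = attach(b, [(20, -3, 0)], [0.8], 3)       # thicker among b's children
    attach(b, [(20, -6, 0)], [0.5], 3)
    return root


class TestDecomposeBranches:
    def test_unbranched_single_branch(self):
        sec = chain_section([(5, 0, 0), (10, 0, 0), (15, 0, 0)], [1, 1, 1])
        branches = decompose_branches(sec)
        assert len(branches) == 1
        assert branches[0].is_root_branch
        assert branches[0].source_sections == [0]

    def test_largest_radius_child_continues(self):
        root = chain_section([(5, 0, 0), (10, 0, 0)], [2.0, 2.0])
        attach(root, [(15, 3, 0)], [2.0], 2)
        attach(root, [(15, -3, 0)], [1.0], 2)
        branches = decompose_branches(root)
        assert len(branches) == 2
        main = next(b for b in branches if b.is_root_branch)
        assert main.samples[-1].position[1] == 3  # followed the radius-2 child

    def test_three_level_tree_matches_stack_oracle(self):
        root = three_level_tree()
        got = {tuple(b.source_sections) for b in decompose_branches(root)}
        expected = {tuple(p) for p in stack_trace_branches(root)}
        assert got == expected
        assert len(got) == 4  # one branch per terminal section

    @pytest.mark.parametrize("seed", range(0, 20))
    def test_branch_count_equals_terminal_sections(self, seed):
        m = generate_morphology(MorphogenParams(seed=seed))
        for neurite in m.neurites:
            branches = decompose_branches(neurite)
            terminals = sum(1 for s in neurite.walk() if not s.children)
            assert len(branches) == terminals
            # partition property: every section in exactly one branch
            covered = sorted(i for b in branches for i in b.source_sections)
            assert covered == list(range(sum(1 for _ in neurite.walk())))


class TestSweepBranch:
    @pytest.mark.parametrize("sides", [3, 8, 16])
    def test_prism_volume_exact(self, sides):
        r, L = 1.7, 9.0
        b = Branch(
            samples=[
                MorphSample(1, Structure.AXON, (0, 0, 0), r),
                MorphSample(2, Structure.AXON, (0, 0, L), r),
            ],
            is_root_branch=False,
        )
        mesh = sweep_branch(b, sides=sides)
        exact = L * (sides / 2) * r**2 * np.sin(2 * np.pi / sides)
        assert mesh.volume == pytest.approx(exact, rel=1e-6)
        assert validate_watertight(mesh) == (0, 0, 0)

    def test_coincident_samples_dropped(self):
        b = Branch(
            samples=[
                MorphSample(1, Structure.AXON, (0, 0, 0), 1.0),
                MorphSample(2, Structure.AXON, (0, 0, 0), 1.0),
                MorphSample(3, Structure.AXON, (0, 0, 5), 1.0),
            ],
            is_root_branch=False,
        )
        assert validate_watertight(sweep_branch(b, sides=8)) == (0, 0, 0)

    def test_invalid_sides(self):
        b = Branch(
            samples=[
                MorphSample(1, Structure.AXON, (0, 0, 0), 1.0),
                MorphSample(2, Structure.AXON, (0, 0, 5), 1.0),
            ],
            is_root_branch=False,
        )
        with pytest.raises(InvalidSides):
            sweep_branch(b, sides=2)

    def test_root_branch_cone_starts_at_centroid(self):
        b = Branch(
            samples=[
                MorphSample(1, Structure.AXON, (6, 0, 0), 1.0),
                MorphSample(2, Structure.AXON, (12, 0, 0), 1.0),
            ],
            is_root_branch=True,
        )
        mesh = sweep_branch(b, sides=8, soma_centroid=np.zeros(3), root_taper=1.5)
        assert mesh.vertices[:, 0].min() == pytest.approx(0.0, abs=1e-9)
        assert validate_watertight(mesh) == (0, 0, 0)

    def test_curved_branch_watertight(self):
        pts = [(5, 0, 0), (9, 3, 1), (12, 7, 1), (13, 11, 4), (12, 15, 8)]
        b = Branch(
            samples=[
                MorphSample(i + 1, Structure.AXON, p, 1.0 - 0.1 * i)
                for i, p in enumerate(pts)
            ],
            is_root_branch=False,
        )
        assert validate_watertight(sweep_branch(b, sides=16)) == (0, 0, 0)


class TestMeshNeuron:
    def test_soma_only_single_component(self):
        pm = mesh_neuron(soma_only(), FAST_MESH)
        assert len(pm.components) == 1 and pm.components[0][1] == "soma"

    def test_soma_plus_unbranched_axon(self):
        m = soma_only()
        m.neurites.append(
            chain_section([(6, 0, 0), (12, 0, 0), (18, 0, 0)], [1.5, 1.4, 1.3],
                          structure=Structure.AXON)
        )
        pm = mesh_neuron(m, FAST_MESH)
        assert len(pm.components) == 2

    def test_component_count_matches_branches(self):
        m = generate_morphology(MorphogenParams(seed=6, branch_prob=1.0, max_order=3,
                                                n_neurites=2))
        m, _ = repair(m)
        pm = mesh_neuron(m, FAST_MESH)
        # 4 terminal sections per neurite × 2 neurites + soma
        assert len(pm.components) == 1 + 8

    def test_order_limit_prunes_axon(self):
        m = generate_morphology(MorphogenParams(seed=6, branch_prob=1.0, max_order=3))
        m, _ = repair(m)
        cfg = MeshConfig(sides=8, max_axon_order=1, max_dendrite_order=1)
        cfg.soma.subdivisions = 3
        cfg.soma.pull_steps = 20
        pm = mesh_neuron(m, cfg)
        assert len(pm.components) == 1 + len(m.neurites)

    def test_linear_runtime_in_sections(self):
        """Doubling the section count should not blow up meshing time
        (no soma: isolates the per-branch sweep)."""

        def tube_time(n_sections):
            m = soma_only()
            x = 6.0
            sec = chain_section([(x, 0, 0), (x + 4, 0, 0)], [1.0, 1.0])
            m.neurites.append(sec)
            cur = sec
            for k in range(n_sections - 1):
                x += 4
                cur = attach(cur, [(x + 4, (k % 3) - 1, 0)], [1.0], cur.order + 1)
            t0 = time.perf_counter()
            for neurite in m.neurites:
                for b in decompose_branches(neurite):
                    sweep_branch(b, sides=8, soma_centroid=m.soma.centroid)
            return time.perf_counter() - t0

        tube_time(50)  # warm-up
        t1, t2 = tube_time(100), tube_time(200)
        assert t2 <= 2.5 * t1 + 0.05


class TestValidateWatertight:
    def test_unit_cube(self):
        assert validate_watertight(trimesh.creation.box()) == (0, 0, 0)

    def test_single_triangle_boundary(self):
        tri = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]], faces=[[0, 1, 2]], process=False
        )
        assert validate_watertight(tri) == (0, 0, 3)

    def test_two_tetrahedra_sharing_edge(self):
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, -1, 0], [0, 0, -1]], float
        )
        faces = np.array(
            [[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2],
             [0, 1, 4], [0, 5, 1], [1, 5, 4], [0, 4, 5]]
        )
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        assert validate_watertight(mesh) == (1, 2, 0)

    def test_two_cubes_sharing_edge_fixture(self):
        assert validate_watertight(toy_mesh("two_cubes_shared_edge")) == (1, 2, 0)

    def test_cross_check_with_trimesh_watertight_flag(self):
        for shape in ("box", "cylinder", "torus"):
            mesh = toy_mesh(shape)
            ours = validate_watertight(mesh)
            assert (ours == (0, 0, 0)) == bool(mesh.is_watertight)
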