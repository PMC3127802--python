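"""Geometry: voxel counts, regions, volumes, couplings, focal region."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinerd.io import mesh_to_text
from spinerd.mesh import (
    Region,
    build_multi_spine_mesh,
    build_single_spine_mesh,
    focal_region,
)


class TestSingleSpineMesh:
    def test_default_voxel_counts(self, fine_mesh):
        regions = {}
        for v in fine_mesh.voxels:
            regions[v.region] = regions.get(v.region, 0) + 1
        assert fine_mesh.n_voxels == 206
        n_dend = regions[Region.DENDRITE_CYTOSOL] + regions[Region.DENDRITE_SUBMEMBRANE]
        assert n_dend == 200
        assert regions[Region.SPINE_NECK] == 3
        assert regions[Region.SPINE_HEAD] == 2
        assert regions[Region.PSD] == 1

    def test_submembrane_count_and_ratio(self, fine_mesh):
        # two outermost width columns x 40 axial slices
        sub = fine_mesh.region_indices(Region.DENDRITE_SUBMEMBRANE)
        assert len(sub) == 80
        # the 0.12 um submembrane columns with 0.36 um cytosol give nearly
        # the same submembrane/cytosol volume ratio as a 0.07 um shell on a
        # cylinder of the dendrite's 0.6 um diameter
        vol_sub = sum(fine_mesh.voxels[i].volume for i in sub)
        vol_cyt = sum(
            fine_mesh.voxels[i].volume
            for i in fine_mesh.region_indices(Region.DENDRITE_CYTOSOL)
        )
        r = 0.3
        shell = (r**2 - (r - 0.07) ** 2) / (r - 0.07) ** 2
        assert vol_sub / vol_cyt == pytest.approx(shell, rel=0.06)

    @pytest.mark.parametrize(
        "neck_length,n_neck", [(0.0, 0), (0.3, 3), (1.0, 10)]
    )
    def test_neck_variants(self, neck_length, n_neck):
        mesh = build_single_spine_mesh(neck_length=neck_length)
        assert len(mesh.region_indices(Region.SPINE_NECK)) == n_neck
        assert mesh.is_connected()

    def test_dendrite_volume_matches_cuboid(self, fine_mesh):
        dend = sum(fine_mesh.voxels[i].volume for i in fine_mesh.dendrite_indices())
        assert dend == pytest.approx(5.0 * 0.6 * 0.4, rel=1e-9)

    def test_voxel_dimensions(self, fine_mesh):
        v = fine_mesh.voxels[0]
        assert v.volume == pytest.approx(0.12 * 0.125 * 0.4)

    def test_head_compartment_volume_formula(self, fine_mesh):
        head = fine_mesh.voxel_set("spine_head_compartment")
        vol = sum(fine_mesh.voxels[i].volume for i in head)
        assert vol == pytest.approx(3 * math.pi * 0.3**2 * 0.1)

    def test_interior_degree_and_corners(self, fine_mesh):
        adj = fine_mesh.adjacency()
        spine = set(fine_mesh.spine_indices())
        degrees = {}
        for i in fine_mesh.dendrite_indices():
            # exclude spine attachment links for the grid-degree check
            degrees[i] = sum(1 for j in adj[i] if j not in spine)
        # 5x40 grid: interior degree 4, corner degree 2
        assert sorted(degrees.values())[:4] == [2, 2, 2, 2]
        n_interior = sum(1 for d in degrees.values() if d == 4)
        assert n_interior == 3 * 38  # inner columns x inner slices

    def test_removing_neck_coupling_disconnects_spine(self, fine_mesh):
        spine = set(fine_mesh.spine_indices())
        attach = fine_mesh.voxel_set("attachment")[0]
        adj = fine_mesh.adjacency()
        # BFS from voxel 0 without crossing the attachment-spine coupling
        seen = {0}
        stack = [0]
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if cur == attach and nb in spine:
                    continue
                if nb == attach and cur in spine:
                    continue
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        assert seen == set(range(206)) - spine

    def test_rejects_non_multiple_lengths(self):
        with pytest.raises(ValueError, match="dendrite_length"):
            build_single_spine_mesh(dendrite_length=5.03)
        with pytest.raises(ValueError, match="neck_length"):
            build_single_spine_mesh(neck_length=0.25)

    def test_reproducible_serialization(self):
        a = mesh_to_text(build_single_spine_mesh())
        b = mesh_to_text(build_single_spine_mesh())
        assert a == b

    @settings(max_examples=10, deadline=None)
    @given(
        n_neck=st.integers(min_value=0, max_value=12),
        n_len=st.integers(min_value=8, max_value=48),
    )
    def test_invariants_over_parameters(self, n_neck, n_len):
        mesh = build_single_spine_mesh(
            dendrite_length=n_len * 0.125, neck_length=n_neck * 0.1
        )
        assert mesh.is_connected()
        assert all(v.volume > 0 for v in mesh.voxels)
        assert mesh.n_voxels == 5 * n_len + n_neck + 3
        dend = sum(mesh.voxels[i].volume for i in mesh.dendrite_indices())
        assert dend == pytest.approx(n_len * 0.125 * 0.6 * 0.4, rel=1e-9)
        # couplings are unique unordered pairs between distinct voxels
        pairs = {frozenset((c.voxel_i, c.voxel_j)) for c in mesh.couplings}
        assert len(pairs) == len(mesh.couplings)


class TestMultiSpineMesh:
    def test_default_counts(self, multi_mesh):
        dend = multi_mesh.dendrite_indices()
        assert len(dend) == 300
        spines = {v.spine_id for v in multi_mesh.voxels if v.spine_id is not None}
        assert len(spines) == 11
        assert len(multi_mesh.spine_indices()) == 66

    def test_voxel_volume(self, multi_mesh):
        assert multi_mesh.voxels[0].volume == pytest.approx(0.2 * 0.2 * 0.4)

    def test_stimulated_spines_at_one_end(self, multi_mesh):
        stim = multi_mesh.metadata["stimulated_spine_ids"]
        assert len(stim) == 2
        xs = [
            multi_mesh.voxels[i].center[0]
            for s in stim
            for i in multi_mesh.spine_indices(s)
        ]
        assert max(xs) < 5.0  # both within the first quarter of the 20 um dendrite

    def test_rejects_overcrowded_spines(self):
        with pytest.raises(ValueError, match="same voxel"):
            build_multi_spine_mesh(dendrite_length=2.0, n_spines=11, axial_step=0.2)


class TestFocalRegion:
    def test_deterministic_and_contiguous(self, fine_mesh):
        head = fine_mesh.voxel_set("spine_head_compartment")
        target = sum(fine_mesh.voxels[i].volume for i in head)
        a = focal_region(fine_mesh, target)
        b = focal_region(fine_mesh, target)
        assert a == b
        # all in one submembrane column, axially contiguous
        ys = {fine_mesh.voxels[i].center[1] for i in a}
        assert len(ys) == 1
        xs = sorted(fine_mesh.voxels[i].center[0] for i in a)
        steps = np.diff(xs)
        assert np.allclose(steps, 0.125)

    def test_head_volume_gives_fourteen_voxels(self, fine_mesh):
        # head compartment 3*pi*0.3^2*0.1 ~= 0.0848 um^3; voxels are 0.006
        target = 3 * math.pi * 0.3**2 * 0.1
        assert len(focal_region(fine_mesh, target)) == round(target / 0.006)

    def test_single_voxel_target(self, fine_mesh):
        target = fine_mesh.voxels[0].volume
        assert len(focal_region(fine_mesh, target)) == 1

    def test_volume_error_minimized(self, fine_mesh):
        target = 0.02
        sel = focal_region(fine_mesh, target)
        vol = sum(fine_mesh.voxels[i].volume for i in sel)
        assert abs(vol - target) <= 0.006 / 2 + 1e-12

    def test_rejects_oversized_target(self, fine_mesh):
        with pytest.raises(ValueError, match="submembrane"):
            focal_region(fine_mesh, 1e3)
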