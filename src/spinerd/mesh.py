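"""Voxelized dendrite-plus-spine geometries.

The dendrite is a rectangular cuboid approximating a cylinder (correct
surface-to-volume ratio), discretized into a 2-D grid of single-depth
cuboid subvolumes: ``n_width`` columns across the 0.6 um width and
``dendrite_length / axial_step`` slices along the axis.  The two outermost
width columns are the submembrane region.  Diffusion is therefore
2-dimensional in the dendrite.

Each spine is a 1-D chain of 0.1 um slices: cylindrical neck slices
(0.2 um diameter), two head slices and one PSD slice (0.6 um diameter
cylinders), attached to a submembrane voxel; diffusion in the spine is
1-dimensional.  Boundaries are reflective: couplings exist only between
geometrically adjacent interior voxels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence


class Region(str, Enum):
    DENDRITE_CYTOSOL = "dendrite_cytosol"
    DENDRITE_SUBMEMBRANE = "dendrite_submembrane"
    DENDRITE_FOCAL = "dendrite_focal"
    SPINE_NECK = "spine_neck"
    SPINE_HEAD = "spine_head"
    PSD = "psd"


# canonical geometry constants (um)
DENDRITE_WIDTH = 0.6
DENDRITE_DEPTH = 0.4
SPINE_HEAD_DIAMETER = 0.6
SPINE_NECK_DIAMETER = 0.2
SPINE_SLICE = 0.1  # default spine slice thickness
N_HEAD_SLICES = 2  # plus 1 PSD slice


@dataclass(frozen=True)
class Voxel:
    index: int
    center: tuple[float, float, float]  # (x axial, y width, z depth/spine axis), um
    volume: float  # um^3
    region: Region
    spine_id: int | None = None
    membrane_area: float = 0.0  # um^2 of plasma membrane adjacent to this voxel

    def __post_init__(self):
        if not self.volume > 0:
            raise ValueError(f"voxel {self.index}: volume must be > 0")
        if self.region is Region.PSD and self.spine_id is None:
            raise ValueError(f"voxel {self.index}: psd voxels need a spine_id")


@dataclass(frozen=True)
class Coupling:
    """Diffusive face between two adjacent voxels (each unordered pair once)."""

    voxel_i: int
    voxel_j: int
    face_area: float  # um^2
    center_distance: float  # um

    def __post_init__(self):
        if self.face_area <= 0 or self.center_distance <= 0:
            raise ValueError("coupling face_area and center_distance must be > 0")
        if self.voxel_i == self.voxel_j:
            raise ValueError("coupling must join two distinct voxels")


@dataclass
class Mesh:
    voxels: list[Voxel]
    couplings: list[Coupling]
    metadata: dict = field(default_factory=dict)  # named voxel sets + geometry notes

    # -- basic queries ---------------------------------------------------
    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def volumes(self):
        import numpy as np

        return np.array([v.volume for v in self.voxels])

    def region_indices(self, region: Region | str) -> list[int]:
        region = Region(region)
        return [v.index for v in self.voxels if v.region is region]

    def voxel_set(self, name: str) -> list[int]:
        sets = self.metadata.get("sets", {})
        if name not in sets:
            raise KeyError(f"mesh has no voxel set named {name!r}")
        return list(sets[name])

    def total_volume(self) -> float:
        return sum(v.volume for v in self.voxels)

    def dendrite_indices(self) -> list[int]:
        return [
            v.index
            for v in self.voxels
            if v.region
            in (Region.DENDRITE_CYTOSOL, Region.DENDRITE_SUBMEMBRANE, Region.DENDRITE_FOCAL)
        ]

    def spine_indices(self, spine_id: int | None = None) -> list[int]:
        out = []
        for v in self.voxels:
            if v.spine_id is None:
                continue
            if spine_id is None or v.spine_id == spine_id:
                out.append(v.index)
        return out

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {v.index: [] for v in self.voxels}
        for c in self.couplings:
            adj[c.voxel_i].append(c.voxel_j)
            adj[c.voxel_j].append(c.voxel_i)
        return adj

    def is_connected(self) -> bool:
        if not self.voxels:
            return True
        adj = self.adjacency()
        seen = {self.voxels[0].index}
        stack = [self.voxels[0].index]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == self.n_voxels


def _is_multiple(value: float, step: float) -> bool:
    if value < 0:
        return False
    n = round(value / step)
    return abs(value - n * step) < 1e-9


def _spine_chain(
    spine_id: int,
    attach_voxel: Voxel,
    neck_length: float,
    slice_thickness: float,
    start_index: int,
) -> tuple[list[Voxel], list[Coupling]]:
    """Build the 1-D spine chain sitting on top of ``attach_voxel``.

    Neck slices are 0.2 um diameter cylinders, the two head slices and the
    PSD slice are 0.6 um diameter cylinders of ``slice_thickness`` height
    (simplest geometry consistent with the stated diameters; head-compartment
    volume = 3 * pi * 0.3^2 * 0.1 ~= 0.0848 um^3).
    """
    neck_r = SPINE_NECK_DIAMETER / 2.0
    head_r = SPINE_HEAD_DIAMETER / 2.0
    neck_area = math.pi * neck_r**2
    head_area = math.pi * head_r**2
    neck_vol = neck_area * slice_thickness
    head_vol = head_area * slice_thickness
    n_neck = round(neck_length / slice_thickness)

    x0, y0, z0 = attach_voxel.center
    # spine grows in +z from the top membrane face of the attachment voxel
    z_base = z0 + DENDRITE_DEPTH / 2.0 if attach_voxel.region != Region.SPINE_HEAD else z0

    voxels: list[Voxel] = []
    couplings: list[Coupling] = []
    idx = start_index
    prev_idx = attach_voxel.index
    prev_center_z = z0
    prev_is_dendrite = True

    def add_slice(kind: Region, z_center: float, vol: float, lateral_area: float):
        nonlocal idx, prev_idx, prev_center_z, prev_is_dendrite
        v = Voxel(
            index=idx,
            center=(x0, y0, z_center),
            volume=vol,
            region=kind,
            spine_id=spine_id,
            membrane_area=lateral_area,
        )
        voxels.append(v)
        # coupling face to the previous element: the neck cross-section when
        # entering from the dendrite or within the neck, otherwise the head
        # cross-section between head/PSD slices.
        if prev_is_dendrite or kind is Region.SPINE_NECK or (
            n_neck > 0 and len(voxels) == n_neck + 1
        ):
            face = neck_area
        else:
            face = head_area
        couplings.append(
            Coupling(
                voxel_i=prev_idx,
                voxel_j=idx,
                face_area=face,
                center_distance=z_center - prev_center_z,
            )
        )
        prev_idx = idx
        prev_center_z = z_center
        prev_is_dendrite = False
        idx += 1

    z = z_base
    for _ in range(n_neck):
        add_slice(
            Region.SPINE_NECK,
            z + slice_thickness / 2.0,
            neck_vol,
            math.pi * SPINE_NECK_DIAMETER * slice_thickness,
        )
        z += slice_thickness
    for k in range(N_HEAD_SLICES):
        add_slice(
            Region.SPINE_HEAD,
            z + slice_thickness / 2.0,
            head_vol,
            math.pi * SPINE_HEAD_DIAMETER * slice_thickness,
        )
        z += slice_thickness
    # PSD slice caps the head; its top disc faces the synaptic membrane
    add_slice(
        Region.PSD,
        z + slice_thickness / 2.0,
        head_vol,
        math.pi * SPINE_HEAD_DIAMETER * slice_thickness + head_area,
    )
    return voxels, couplings


def _build_dendrite_grid(
    dendrite_length: float,
    axial_step: float,
    n_width: int,
) -> tuple[list[Voxel], list[Coupling]]:
    """2-D grid of single-depth cuboids; outer width columns are submembrane."""
    n_len = round(dendrite_length / axial_step)
    col_w = DENDRITE_WIDTH / n_width
    vol = col_w * axial_step * DENDRITE_DEPTH
    voxels = []
    for i in range(n_len):  # axial
        for j in range(n_width):  # width
            region = (
                Region.DENDRITE_SUBMEMBRANE
                if j in (0, n_width - 1)
                else Region.DENDRITE_CYTOSOL
            )
            # membrane face of a submembrane voxel: axial_step x depth
            marea = axial_step * DENDRITE_DEPTH if region is Region.DENDRITE_SUBMEMBRANE else 0.0
            voxels.append(
                Voxel(
                    index=i * n_width + j,
                    center=(
                        (i + 0.5) * axial_step,
                        (j + 0.5) * col_w - DENDRITE_WIDTH / 2.0,
                        0.0,
                    ),
                    volume=vol,
                    region=region,
                    membrane_area=marea,
                )
            )
    couplings = []
    for i in range(n_len):
        for j in range(n_width):
            a = i * n_width + j
            if i + 1 < n_len:  # axial neighbour
                couplings.append(
                    Coupling(a, (i + 1) * n_width + j, col_w * DENDRITE_DEPTH, axial_step)
                )
            if j + 1 < n_width:  # width neighbour
                couplings.append(
                    Coupling(a, i * n_width + j + 1, axial_step * DENDRITE_DEPTH, col_w)
                )
    return voxels, couplings


def _attach_columns(n_width: int) -> int:
    """Width column index used for spine attachment (a top submembrane column)."""
    return n_width - 1


def build_single_spine_mesh(
    dendrite_length: float = 5.0,
    neck_length: float = 0.3,
    slice_thickness: float = SPINE_SLICE,
    axial_step: float = 0.125,
    n_width: int = 5,
) -> Mesh:
    """Default: 5 x 40 grid of 0.12 x 0.125 x 0.4 um^3 dendrite subvolumes (200)
    plus a spine of 3 neck, 2 head and 1 PSD slice (206 voxels total).

    ``axial_step``/``n_width`` allow a coarser dendrite grid for desk-scale
    simulation; the spine discretization is unchanged.
    """
    if not _is_multiple(dendrite_length, axial_step):
        raise ValueError(
            f"dendrite_length={dendrite_length} is not an integer multiple of "
            f"axial_step={axial_step}"
        )
    if not _is_multiple(neck_length, slice_thickness):
        raise ValueError(
            f"neck_length={neck_length} is not an integer multiple of "
            f"slice_thickness={slice_thickness}"
        )
    voxels, couplings = _build_dendrite_grid(dendrite_length, axial_step, n_width)
    n_len = round(dendrite_length / axial_step)
    # attachment: top-face submembrane voxel whose center is nearest the midpoint
    attach_slice = (n_len - 1) // 2 if n_len % 2 == 0 else n_len // 2
    attach = voxels[attach_slice * n_width + _attach_columns(n_width)]
    sv, sc = _spine_chain(0, attach, neck_length, slice_thickness, len(voxels))
    voxels += sv
    couplings += sc

    mesh = Mesh(voxels=voxels, couplings=couplings)
    head_comp = [v.index for v in sv if v.region in (Region.SPINE_HEAD, Region.PSD)]
    mesh.metadata = {
        "kind": "single_spine",
        "params": {
            "dendrite_length": dendrite_length,
            "neck_length": neck_length,
            "slice_thickness": slice_thickness,
            "axial_step": axial_step,
            "n_width": n_width,
        },
        "head_volume_formula": "3*pi*(0.3**2)*slice_thickness",
        "sets": {
            "psd": [v.index for v in sv if v.region is Region.PSD],
            "spine_head_compartment": head_comp,
            "spine": [v.index for v in sv],
            "attachment": [attach.index],
        },
    }
    head_volume = sum(mesh.voxels[i].volume for i in head_comp)
    focal = focal_region(mesh, head_volume)
    mesh.metadata["sets"]["focal_dendrite"] = focal
    mesh.metadata["sets"]["dendrite_ca_influx"] = list(focal)
    return mesh


def build_multi_spine_mesh(
    dendrite_length: float = 20.0,
    n_spines: int = 11,
    axial_step: float = 0.2,
    n_width: int = 3,
    neck_length: float = 0.3,
    slice_thickness: float = SPINE_SLICE,
) -> Mesh:
    """Default: 3 x 100 grid of 0.2 x 0.2 x 0.4 um^3 dendrite subvolumes (300)
    with 11 evenly spaced spines (default single-spine discretization, 6 voxels
    each); the two spines nearest x=0 are named "stimulated_spines".
    """
    if n_spines < 1:
        raise ValueError("n_spines must be >= 1")
    if not _is_multiple(dendrite_length, axial_step):
        raise ValueError(
            f"dendrite_length={dendrite_length} is not an integer multiple of "
            f"axial_step={axial_step}"
        )
    voxels, couplings = _build_dendrite_grid(dendrite_length, axial_step, n_width)
    n_len = round(dendrite_length / axial_step)
    col = _attach_columns(n_width)

    # evenly spaced axial positions, one attachment voxel per spine
    attach_slices = []
    for s in range(n_spines):
        x = (s + 0.5) * dendrite_length / n_spines
        attach_slices.append(min(n_len - 1, int(x / axial_step)))
    if len(set(attach_slices)) != n_spines:
        raise ValueError("spine spacing would attach two spines to the same voxel")

    sets: dict[str, list[int]] = {"psd": [], "spine_head_compartment": [], "spine": []}
    spine_sets: dict[int, list[int]] = {}
    for s, isl in enumerate(attach_slices):
        attach = voxels[isl * n_width + col]
        sv, sc = _spine_chain(s, attach, neck_length, slice_thickness, len(voxels))
        voxels = voxels + sv
        couplings = couplings + sc
        spine_sets[s] = [v.index for v in sv]
        sets["spine"] += [v.index for v in sv]
        sets["psd"] += [v.index for v in sv if v.region is Region.PSD]
        sets["spine_head_compartment"] += [
            v.index for v in sv if v.region in (Region.SPINE_HEAD, Region.PSD)
        ]

    mesh = Mesh(voxels=voxels, couplings=couplings)
    mesh.metadata = {
        "kind": "multi_spine",
        "params": {
            "dendrite_length": dendrite_length,
            "n_spines": n_spines,
            "axial_step": axial_step,
            "n_width": n_width,
            "neck_length": neck_length,
            "slice_thickness": slice_thickness,
        },
        "head_volume_formula": "3*pi*(0.3**2)*slice_thickness",
        "sets": sets,
    }
    for s, idxs in spine_sets.items():
        mesh.metadata["sets"][f"spine_{s}"] = idxs

    # two spines nearest the x=0 end are the stimulated ones
    order = sorted(range(n_spines), key=lambda s: attach_slices[s])
    stim = order[:2] if n_spines >= 2 else order
    mesh.metadata["sets"]["stimulated_spines"] = sorted(
        i for s in stim for i in spine_sets[s]
    )
    mesh.metadata["stimulated_spine_ids"] = stim

    # per-stimulated-spine PSD and focal dendritic influx regions
    head_volume = 3 * math.pi * (SPINE_HEAD_DIAMETER / 2) ** 2 * slice_thickness
    stim_psd: list[int] = []
    influx: list[int] = []
    for s in stim:
        stim_psd += [
            i for i in spine_sets[s] if mesh.voxels[i].region is Region.PSD
        ]
        influx += focal_region(mesh, head_volume, spine_id=s)
    mesh.metadata["sets"]["stimulated_psd"] = sorted(stim_psd)
    mesh.metadata["sets"]["dendrite_ca_influx"] = sorted(set(influx))
    mesh.metadata["sets"]["focal_dendrite"] = sorted(set(influx))
    return mesh


def focal_region(mesh: Mesh, target_volume: float, spine_id: int = 0) -> list[int]:
    """Contiguous set of submembrane voxels beneath the spine whose summed
    volume best approximates ``target_volume``.

    Grows symmetrically (alternating +axial/-axial) from the attachment
    column, preferring the lower voxel index on ties; deterministic.
    """
    if not mesh.voxels:
        raise ValueError("empty mesh")
    sub = [v for v in mesh.voxels if v.region is Region.DENDRITE_SUBMEMBRANE]
    total_sub = sum(v.volume for v in sub)
    if target_volume > total_sub + 1e-12:
        raise ValueError("target_volume exceeds total dendrite submembrane volume")

    # locate the attachment voxel of the requested spine
    attach_idx = None
    for c in mesh.couplings:
        vi, vj = mesh.voxels[c.voxel_i], mesh.voxels[c.voxel_j]
        if vi.spine_id == spine_id and vj.spine_id is None:
            attach_idx = vj.index
        elif vj.spine_id == spine_id and vi.spine_id is None:
            attach_idx = vi.index
        if attach_idx is not None:
            break
    if attach_idx is None:
        raise ValueError(f"mesh has no spine {spine_id}")

    attach = mesh.voxels[attach_idx]
    # submembrane voxels in the same width column, ordered by |x - x_attach|
    column = sorted(
        (v for v in sub if abs(v.center[1] - attach.center[1]) < 1e-9),
        key=lambda v: (round(abs(v.center[0] - attach.center[0]), 9), v.index),
    )
    chosen: list[int] = []
    vol = 0.0
    best_err = abs(target_volume)
    for v in column:
        new_vol = vol + v.volume
        if abs(new_vol - target_volume) <= best_err + 1e-12:
            chosen.append(v.index)
            vol = new_vol
            best_err = abs(vol - target_volume)
        else:
            break
    if not chosen:  # target smaller than half a voxel: take the attachment voxel
        chosen = [attach_idx]
    return sorted(chosen)
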