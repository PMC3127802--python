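import numpy as np
import pytest

from spinerd.mesh import build_multi_spine_mesh, build_single_spine_mesh
from spinerd.model import (
    AnchoringConfig,
    ModelSpec,
    ReactionSpec,
    SpeciesSpec,
    apply_anchoring,
    build_model,
)


@pytest.fixture(scope="session")
def model() -> ModelSpec:
    return build_model()


@pytest.fixture(scope="session")
def fine_mesh():
    return build_single_spine_mesh()


@pytest.fixture(scope="session")
def coarse_mesh():
    return build_single_spine_mesh(axial_step=0.25, n_width=3)


@pytest.fixture(scope="session")
def multi_mesh():
    return build_multi_spine_mesh()


@pytest.fixture(scope="session")
def anchored_model(model, coarse_mesh):
    return apply_anchoring(model, coarse_mesh, AnchoringConfig("spine", "spine"))


def toy_two_voxel_model(reactions, species, initial_counts_v0, initial_counts_v1,
                        volumes=(0.01, 0.02)):
    """Build a minimal (model, mesh) pair for engine-oracle comparisons.

    ``species``: list of (name, D); ``reactions``: list of ReactionSpec;
    initial counts are exact per-voxel molecule numbers.
    """
    from spinerd.mesh import Coupling, Mesh, Region, Voxel

    v0 = Voxel(0, (0.0, 0.0, 0.0), volumes[0], Region.DENDRITE_CYTOSOL)
    v1 = Voxel(1, (1.0, 0.0, 0.0), volumes[1], Region.DENDRITE_CYTOSOL)
    mesh = Mesh(
        voxels=[v0, v1],
        couplings=[Coupling(0, 1, face_area=0.04, center_distance=0.5)],
        metadata={"kind": "toy", "params": {}, "sets": {
            "v0": [0], "v1": [1], "psd": [1], "spine_head_compartment": [1],
        }},
    )
    specs = [SpeciesSpec(name=n, diffusion_constant=d) for n, d in species]
    m = ModelSpec(
        species=specs,
        rows=[],
        initial_conditions_nM={},
        anchored_molecules={},
        pump_density_per_um2={},
    )
    m._toy_reactions = reactions  # type: ignore[attr-defined]
    # bypass the YAML row expansion: patch elementary()
    m.elementary = lambda: list(reactions)  # type: ignore[method-assign]
    counts = {0: initial_counts_v0, 1: initial_counts_v1}
    anchored = {}
    for name, _ in species:
        per_vox = np.array([counts[0].get(name, 0), counts[1].get(name, 0)], dtype=float)
        anchored[name] = per_vox
    m.anchored_counts = anchored
    return m, mesh


@pytest.fixture
def toy_factory():
    return toy_two_voxel_model
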