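"""Serialization and reproducibility plumbing.

Plain-text formats with stable ordering throughout: meshes as a sectioned
text file (voxels / couplings / sets), models as YAML, schedules as YAML,
trajectories and metrics as long-format CSV, run manifests as JSON with
content hashes of every input.  parse(serialize(x)) is a fixed point.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import EngineConfig, InjectionEvent, Trajectory
from .mesh import Coupling, Mesh, Region, Voxel
from .model import ModelSpec, model_from_dict
from .protocols import StimulusSchedule

_FLOAT_FMT = "%.12g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


# --------------------------------------------------------------------------
# mesh
# --------------------------------------------------------------------------

def mesh_to_text(mesh: Mesh) -> str:
    lines = ["# spinerd mesh v1"]
    lines.append("[params]")
    lines.append(json.dumps({"kind": mesh.metadata.get("kind", ""),
                             **mesh.metadata.get("params", {})}, sort_keys=True))
    lines.append("[voxels]  # index x y z volume region spine_id membrane_area")
    for v in mesh.voxels:
        sid = "-" if v.spine_id is None else str(v.spine_id)
        lines.append(
            f"{v.index} {_fmt(v.center[0])} {_fmt(v.center[1])} {_fmt(v.center[2])} "
            f"{_fmt(v.volume)} {v.region.value} {sid} {_fmt(v.membrane_area)}"
        )
    lines.append("[couplings]  # i j face_area center_distance")
    for c in mesh.couplings:
        lines.append(f"{c.voxel_i} {c.voxel_j} {_fmt(c.face_area)} {_fmt(c.center_distance)}")
    lines.append("[sets]")
    sets = mesh.metadata.get("sets", {})
    for name in sorted(sets):
        lines.append(f"{name}: {' '.join(str(i) for i in sets[name])}")
    extra = {
        k: v
        for k, v in mesh.metadata.items()
        if k not in ("sets", "params", "kind")
    }
    lines.append("[meta]")
    lines.append(json.dumps(extra, sort_keys=True, default=str))
    return "\n".join(lines) + "\n"


def mesh_from_text(text: str) -> Mesh:
    section = None
    voxels: list[Voxel] = []
    couplings: list[Coupling] = []
    sets: dict[str, list[int]] = {}
    params: dict = {}
    meta_extra: dict = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip() if not raw.startswith("#") else ""
        if raw.startswith("["):
            section = raw.split("]")[0][1:]
            continue
        if not line:
            continue
        if section == "params":
            params = json.loads(line)
        elif section == "voxels":
            parts = line.split()
            voxels.append(
                Voxel(
                    index=int(parts[0]),
                    center=(float(parts[1]), float(parts[2]), float(parts[3])),
                    volume=float(parts[4]),
                    region=Region(parts[5]),
                    spine_id=None if parts[6] == "-" else int(parts[6]),
                    membrane_area=float(parts[7]),
                )
            )
        elif section == "couplings":
            i, j, a, d = line.split()
            couplings.append(Coupling(int(i), int(j), float(a), float(d)))
        elif section == "sets":
            name, _, rest = line.partition(":")
            sets[name.strip()] = [int(x) for x in rest.split()]
        elif section == "meta":
            meta_extra = json.loads(line)
    kind = params.pop("kind", "")
    mesh = Mesh(voxels=voxels, couplings=couplings)
    mesh.metadata = {"kind": kind, "params": params, "sets": sets, **meta_extra}
    return mesh


def save_mesh(mesh: Mesh, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(mesh_to_text(mesh))
    return path


def load_mesh(path: str | Path) -> Mesh:
    return mesh_from_text(Path(path).read_text())


# --------------------------------------------------------------------------
# model / schedule
# --------------------------------------------------------------------------

def save_model(model: ModelSpec, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(model.to_dict(), sort_keys=True))
    return path


def load_model(path: str | Path) -> ModelSpec:
    return model_from_dict(yaml.safe_load(Path(path).read_text()))


def schedule_to_dict(sched: StimulusSchedule) -> dict:
    return {
        "label": sched.label,
        "events": [
            {
                "species": e.species,
                "voxel_set": e.voxel_set,
                "rate_molecules_per_ms": e.rate,
                "onset_s": e.onset,
                "duration_s": e.duration,
            }
            for e in sched.events
        ],
    }


def schedule_from_dict(d: dict) -> StimulusSchedule:
    return StimulusSchedule(
        [
            InjectionEvent(
                species=e["species"],
                voxel_set=e["voxel_set"],
                rate=float(e["rate_molecules_per_ms"]),
                onset=float(e["onset_s"]),
                duration=float(e["duration_s"]),
            )
            for e in d["events"]
        ],
        label=d.get("label", ""),
    )


def save_schedule(sched: StimulusSchedule, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(schedule_to_dict(sched), sort_keys=True))
    return path


def load_schedule(path: str | Path) -> StimulusSchedule:
    return schedule_from_dict(yaml.safe_load(Path(path).read_text()))


# --------------------------------------------------------------------------
# trajectory / metrics
# --------------------------------------------------------------------------

def save_trajectory_csv(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    traj.to_frame().to_csv(path, index=False, float_format="%.10g")
    return path


def save_metrics_csv(metrics: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    metrics.to_csv(path, index=False, float_format="%.12g")
    return path


def load_metrics_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# --------------------------------------------------------------------------
# manifests
# --------------------------------------------------------------------------

def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def run_manifest(
    model: ModelSpec,
    mesh: Mesh,
    schedule: StimulusSchedule,
    config: EngineConfig,
    extra: dict | None = None,
) -> dict:
    return {
        "model_hash": model.content_hash(),
        "mesh_hash": sha256_text(mesh_to_text(mesh)),
        "schedule_hash": sha256_text(
            yaml.safe_dump(schedule_to_dict(schedule), sort_keys=True)
        ),
        "engine": {
            "dt": config.dt,
            "t_end": config.t_end,
            "seed": config.rng_seed,
            "sample_interval": config.sample_interval,
            "mode": config.mode,
        },
        "software_version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        **(extra or {}),
    }


def save_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
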