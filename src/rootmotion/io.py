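"""Subject-bundle I/O: meshes, displacement CSVs, landmark JSON, manifests.

A subject bundle is
  * a surface mesh (STL or PLY, ASCII or binary — read/written via trimesh),
  * a displacement CSV with header ``vertex_index,dx,dy,dz`` in mm,
  * a landmarks JSON with named 3D points / point lists in mm.

All writers are deterministic: identical inputs produce identical bytes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .geometry import Centerline, TriSurfaceMesh
from .metrics import RootMotionMetrics, VertexDisplacementField

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_displacement_csv",
    "write_displacement_csv",
    "read_landmarks",
    "write_landmarks",
    "write_phantom_bundle",
    "metrics_to_row",
]

_MESH_SUFFIXES = {".stl", ".ply"}


def read_mesh(path) -> TriSurfaceMesh:
    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise ValueError(f"unsupported mesh format '{path.suffix}' (use STL or PLY)")
    tm = trimesh.load(path, force="mesh", process=False)
    return TriSurfaceMesh(vertices=np.asarray(tm.vertices, float),
                          triangles=np.asarray(tm.faces, np.int64))


def write_mesh(mesh: TriSurfaceMesh, path) -> None:
    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise ValueError(f"unsupported mesh format '{path.suffix}' (use STL or PLY)")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    tm.export(path)


def read_displacement_csv(path) -> VertexDisplacementField:
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["vertex_index", "dx", "dy", "dz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"displacement CSV missing columns {missing}")
    df = df.sort_values("vertex_index")
    idx = df["vertex_index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(idx))):
        raise ValueError("vertex_index must cover 0..n-1 exactly once")
    return VertexDisplacementField(vectors=df[["dx", "dy", "dz"]].to_numpy(float))


def write_displacement_csv(field: VertexDisplacementField, path) -> None:
    with open(path, "w", newline="") as f:
        f.write("vertex_index,dx,dy,dz\n")
        for i, (dx, dy, dz) in enumerate(field.vectors):
            f.write(f"{i},{float(dx)!r},{float(dy)!r},{float(dz)!r}\n")


def read_landmarks(path) -> dict:
    with open(path) as f:
        lm = json.load(f)
    return lm


def landmarks_centerline(landmarks: dict) -> Centerline:
    if "centerline" not in landmarks:
        raise ValueError("landmarks JSON has no 'centerline' entry")
    return Centerline(np.asarray(landmarks["centerline"], float))


def write_landmarks(landmarks: dict, path) -> None:
    with open(path, "w") as f:
        json.dump(landmarks, f, sort_keys=True, indent=1)
        f.write("\n")


def write_phantom_bundle(out_dir, mesh, centerline, landmarks, field, truth) -> dict:
    """Write a complete synthetic subject (mesh/CSV/JSON + ground truth).

    Writes to temporary names first and renames at the end so a failed run
    leaves no partial bundle behind.  Returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mesh": out / "phantom_mesh.ply",
        "displacement": out / "phantom_displacement.csv",
        "landmarks": out / "phantom_landmarks.json",
        "ground_truth": out / "phantom_ground_truth.json",
    }
    # trimesh picks the exporter from the suffix, so the mesh temp file
    # keeps .ply and is distinguished by name instead
    tmp = {
        "mesh": paths["mesh"].with_name("._tmp_phantom_mesh.ply"),
        "displacement": paths["displacement"].with_suffix(".csv.tmp"),
        "landmarks": paths["landmarks"].with_suffix(".json.tmp"),
        "ground_truth": paths["ground_truth"].with_suffix(".json.tmp"),
    }
    write_mesh(mesh, tmp["mesh"])
    write_displacement_csv(field, tmp["displacement"])
    write_landmarks(landmarks, tmp["landmarks"])
    with open(tmp["ground_truth"], "w") as f:
        json.dump(truth.as_dict(), f, sort_keys=True, indent=1)
        f.write("\n")
    for k in paths:
        tmp[k].rename(paths[k])
    return {k: str(p) for k, p in paths.items()}


def metrics_to_row(subject_id: str, m: RootMotionMetrics) -> dict:
    row = {"id": subject_id}
    row.update(m.as_dict())
    return row
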