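"""Serialization: meshes (PLY/OBJ), masks (NIfTI-1), signals and grids.

A breathing fraction is stored as a directory tree::

    <root>/<structure>/phase_00.ply, phase_01.ply, ...

Masks go to NIfTI-1 with the voxel spacing on the affine diagonal and the
world position of voxel (0,0,0) in the translation column.  Patch grids are
JSON (patch id -> vertex ids); patch signals are tidy CSV with columns
``phase, patch, dx, dy, dz`` in mm.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .masks import VolumeMask
from .surface import ExternalSignal, PatchGrid, PhaseMeshSet

__all__ = [
    "save_phase_meshes",
    "load_phase_meshes",
    "save_mask",
    "load_mask",
    "save_patch_grid",
    "load_patch_grid",
    "save_signal_csv",
    "load_signal_csv",
]


def save_phase_meshes(pms: PhaseMeshSet, directory, fmt: str = "ply") -> list[Path]:
    """Write one file per phase; returns the written paths."""
    if fmt not in ("ply", "obj"):
        raise ValueError("mesh format must be 'ply' or 'obj'")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for j in range(pms.n_phases):
        path = directory / f"phase_{j:02d}.{fmt}"
        trimesh.Trimesh(vertices=pms.vertices[j], faces=pms.faces, process=False).export(path)
        paths.append(path)
    return paths


def load_phase_meshes(directory, name: str | None = None) -> PhaseMeshSet:
    """Read ``phase_*.ply|obj`` files (sorted) back into a corresponded set."""
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix in (".ply", ".obj"))
    if not files:
        raise FileNotFoundError(f"no phase meshes found in {directory}")
    meshes = [trimesh.load_mesh(p, process=False) for p in files]
    counts = {len(m.vertices) for m in meshes}
    if len(counts) != 1:
        raise ValueError(f"phase meshes disagree on vertex count: {sorted(counts)}")
    vertices = np.stack([np.asarray(m.vertices, dtype=float) for m in meshes])
    return PhaseMeshSet(
        name=name or directory.name,
        vertices=vertices,
        faces=np.asarray(meshes[0].faces, dtype=np.int64),
    )


def save_mask(mask: VolumeMask, path) -> None:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(mask.spacing)
    affine[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))


def load_mask(path) -> VolumeMask:
    img = nib.load(str(path))
    affine = img.affine
    if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3]))):
        raise ValueError("only axis-aligned NIfTI masks are supported")
    return VolumeMask(
        data=np.asarray(img.dataobj) > 0,
        spacing=np.diag(affine[:3, :3]).copy(),
        origin=affine[:3, 3].copy(),
    )


def save_patch_grid(grid: PatchGrid, path) -> None:
    payload = {
        "rows": grid.rows,
        "cols": grid.cols,
        "excluded": grid.excluded.tolist(),
        "assignments": {str(p): a.tolist() for p, a in enumerate(grid.assignments)},
    }
    Path(path).write_text(json.dumps(payload))


def load_patch_grid(path) -> PatchGrid:
    payload = json.loads(Path(path).read_text())
    n = payload["rows"] * payload["cols"]
    assignments = [
        np.asarray(payload["assignments"][str(p)], dtype=np.int64) for p in range(n)
    ]
    return PatchGrid(
        rows=payload["rows"],
        cols=payload["cols"],
        assignments=assignments,
        excluded=np.asarray(payload["excluded"], dtype=np.int64),
    )


def save_signal_csv(signal: ExternalSignal, path) -> None:
    rows = []
    for j in range(signal.n_phases):
        for i, p in enumerate(signal.patch_ids):
            rows.append({"phase": j, "patch": int(p), "kind": "S",
                         "dx": signal.S[j, i, 0], "dy": signal.S[j, i, 1], "dz": signal.S[j, i, 2]})
            if signal.A is not None:
                rows.append({"phase": j, "patch": int(p), "kind": "A",
                             "dx": signal.A[j, i, 0], "dy": signal.A[j, i, 1], "dz": signal.A[j, i, 2]})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_signal_csv(path) -> ExternalSignal:
    df = pd.read_csv(path)
    patch_ids = np.sort(df["patch"].unique())
    phases = np.sort(df["phase"].unique())
    def block(kind: str) -> np.ndarray | None:
        sub = df[df["kind"] == kind]
        if sub.empty:
            return None
        out = np.empty((len(phases), len(patch_ids), 3), dtype=float)
        sub = sub.set_index(["phase", "patch"]).sort_index()
        for jj, j in enumerate(phases):
            vals = sub.loc[j][["dx", "dy", "dz"]].to_numpy()
            out[jj] = vals
        return out
    S = block("S")
    if S is None:
        raise ValueError("signal file contains no phasic (S) rows")
    return ExternalSignal(S=S, A=block("A"), patch_ids=patch_ids)
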