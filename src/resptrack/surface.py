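"""Surface DVFs, mid-position references and the external patch grid.

All phasic displacement fields are relative to the mid-position (MidP)
reference, the vertex-wise time average of the corresponded phase meshes;
per-vertex phase sums of phasic DVFs therefore vanish identically.
Directional DVFs are first differences of consecutive phasic external
signals with cyclic wrap-around, so they telescope to zero over one cycle.

Axis convention: x = ML, y = AP (anterior positive), z = SI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "PhaseMeshSet",
    "PatchGrid",
    "ExternalSignal",
    "midp_reference",
    "phasic_dvf",
    "build_patch_grid",
    "patch_signal",
    "directional_signal",
]


@dataclass
class PhaseMeshSet:
    """Corresponded triangle meshes of one structure over J phases.

    Vertex k of phase j corresponds to vertex k of every other phase; the
    face list is shared.
    """

    name: str
    vertices: np.ndarray  # (J, M, 3) mm
    faces: np.ndarray  # (F, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 3 or self.vertices.shape[2] != 3:
            raise ValueError("vertices must have shape (J, M, 3)")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("non-finite vertex coordinates")

    @property
    def n_phases(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[1]

    def mesh(self, j: int) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices[j], faces=self.faces, process=False)

    def subset_phases(self, phases) -> "PhaseMeshSet":
        return PhaseMeshSet(self.name, self.vertices[np.asarray(phases)], self.faces)


def midp_reference(phases: PhaseMeshSet) -> np.ndarray:
    """Mid-position vertices: arithmetic mean over phases, (M, 3) mm."""
    return phases.vertices.mean(axis=0)


def phasic_dvf(phases: PhaseMeshSet, midp: np.ndarray) -> np.ndarray:
    """Per-phase, per-vertex displacement from MidP, (J, M, 3) mm."""
    midp = np.asarray(midp, dtype=float)
    if midp.shape != phases.vertices.shape[1:]:
        raise ValueError(
            f"MidP has {midp.shape[0]} vertices but phases have "
            f"{phases.n_vertices}: correspondence mismatch"
        )
    return phases.vertices - midp[None, :, :]


@dataclass
class PatchGrid:
    """Uniform SI x ML binning of anterior-facing external vertices.

    Patch ids are row-major over (rows=SI, cols=ML).  Patches that receive
    no vertex are flagged excluded and dropped from all derived signals.
    """

    rows: int
    cols: int
    assignments: list[np.ndarray]  # patch id -> vertex indices
    excluded: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n_patches(self) -> int:
        return self.rows * self.cols

    @property
    def active_ids(self) -> np.ndarray:
        mask = np.ones(self.n_patches, dtype=bool)
        mask[self.excluded] = False
        return np.nonzero(mask)[0]

    @property
    def n_active(self) -> int:
        return len(self.active_ids)


def _lower_bin(values: np.ndarray, lo: float, hi: float, n: int) -> np.ndarray:
    """Uniform bin index; values exactly on an interior edge go to the lower bin."""
    if hi <= lo:
        return np.zeros(len(values), dtype=np.int64)
    w = (hi - lo) / n
    idx = np.ceil((values - lo) / w).astype(np.int64) - 1
    return np.clip(idx, 0, n - 1)


def build_patch_grid(
    midp_vertices: np.ndarray,
    faces: np.ndarray,
    rows: int = 14,
    cols: int = 11,
) -> PatchGrid:
    """Bin anterior-facing vertices of the external MidP mesh into rows x cols.

    Anterior-facing means the outward vertex normal has a positive AP (y)
    component.  Rows run along SI (z), columns along ML (x), over the
    bounding box of the anterior vertex set.  Deterministic; empty patches
    are excluded with a warning.
    """
    midp_vertices = np.asarray(midp_vertices, dtype=float)
    mesh = trimesh.Trimesh(vertices=midp_vertices, faces=faces, process=False)
    normals = np.asarray(mesh.vertex_normals)
    anterior = np.nonzero(normals[:, 1] > 0.0)[0]
    if len(anterior) == 0:
        raise ValueError("no anterior-facing vertices on the external surface")

    v = midp_vertices[anterior]
    r = _lower_bin(v[:, 2], v[:, 2].min(), v[:, 2].max(), rows)  # SI
    c = _lower_bin(v[:, 0], v[:, 0].min(), v[:, 0].max(), cols)  # ML
    patch_of = r * cols + c
    assignments = [anterior[patch_of == p] for p in range(rows * cols)]
    excluded = np.asarray([p for p, a in enumerate(assignments) if len(a) == 0], dtype=np.int64)
    if len(excluded):
        warnings.warn(
            f"{len(excluded)} of {rows * cols} patches are empty and excluded from modeling"
        )
    return PatchGrid(rows=rows, cols=cols, assignments=assignments, excluded=excluded)


@dataclass
class ExternalSignal:
    """Patch-averaged external surrogate signals over J phases.

    ``S``: phasic DVFs, (J, N, 3); ``A``: directional DVFs (first
    differences with cyclic wrap), same shape or None; ``patch_ids``: the
    active patch ids of the originating grid, length N.
    """

    S: np.ndarray
    A: np.ndarray | None
    patch_ids: np.ndarray

    @property
    def n_phases(self) -> int:
        return self.S.shape[0]

    @property
    def n_patches(self) -> int:
        return self.S.shape[1]

    def restrict(self, patch_ids) -> "ExternalSignal":
        """Signal restricted to a subset of patch ids (model subset, RoiMod)."""
        patch_ids = np.asarray(patch_ids)
        pos = {p: i for i, p in enumerate(self.patch_ids.tolist())}
        try:
            cols = np.asarray([pos[int(p)] for p in patch_ids])
        except KeyError as e:
            raise ValueError(f"patch id {e} not present in signal") from e
        A = self.A[:, cols] if self.A is not None else None
        return ExternalSignal(self.S[:, cols], A, patch_ids.copy())


def patch_signal(dvfs: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Average per-vertex external DVFs within each active patch.

    ``dvfs``: (J, M_ext, 3) -> returns (J, N_active, 3), ordered by patch id.
    """
    dvfs = np.asarray(dvfs, dtype=float)
    out = np.empty((dvfs.shape[0], grid.n_active, 3), dtype=float)
    for i, p in enumerate(grid.active_ids):
        out[:, i, :] = dvfs[:, grid.assignments[p], :].mean(axis=1)
    return out


def directional_signal(S: np.ndarray) -> np.ndarray:
    """Directional DVFs A_j = S_j - S_{j-1}, cyclic at j=1 (A_1 = S_1 - S_J).

    Telescopes to zero over the cycle: sum_j A_j = 0 exactly.
    """
    S = np.asarray(S, dtype=float)
    return S - np.roll(S, 1, axis=0)


def external_signal(
    external_dvfs: np.ndarray,
    grid: PatchGrid,
    with_directional: bool = True,
) -> ExternalSignal:
    """Convenience: patch-average and (optionally) difference in one call."""
    S = patch_signal(external_dvfs, grid)
    A = directional_signal(S) if with_directional else None
    return ExternalSignal(S=S, A=A, patch_ids=grid.active_ids)


__all__.append("external_signal")
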