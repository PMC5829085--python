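"""Binary volume masks on regular voxel grids.

World convention: the center of voxel (i, j, k) sits at
``origin + index * spacing`` (mm); indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MaskGrid", "VolumeMask", "resample_nearest"]


@dataclass(frozen=True)
class MaskGrid:
    spacing: np.ndarray  # (3,) mm
    origin: np.ndarray  # (3,) mm, center of voxel (0,0,0)
    shape: tuple[int, int, int]


@dataclass
class VolumeMask:
    """Binary voxel grid with physical spacing and origin."""

    data: np.ndarray  # bool, 3D
    spacing: np.ndarray  # (3,) mm
    origin: np.ndarray  # (3,) mm

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("mask data must be 3D")
        if np.any(self.spacing <= 0):
            raise ValueError("mask spacing must be positive")

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def foreground_world(self) -> np.ndarray:
        """World coordinates (mm) of foreground voxel centers, (P, 3)."""
        idx = np.argwhere(self.data)
        return self.origin + idx * self.spacing

    def centroid_world(self) -> np.ndarray:
        """Unweighted centroid of foreground voxel centers (mm)."""
        if self.n_foreground == 0:
            raise ValueError("centroid of an empty mask is undefined")
        idx = np.argwhere(self.data)
        return self.origin + idx.mean(axis=0) * self.spacing

    def same_grid(self, other: "VolumeMask") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


def resample_nearest(mask: VolumeMask, like: VolumeMask) -> VolumeMask:
    """Resample ``mask`` onto the grid of ``like`` by nearest neighbor.

    Voxel centers of the target grid falling outside ``mask``'s grid are
    background.
    """
    if mask.same_grid(like):
        return mask
    shape = like.data.shape
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1)
    world = like.origin + idx * like.spacing
    src = np.rint((world - mask.origin) / mask.spacing).astype(np.int64)
    ok = np.all((src >= 0) & (src < np.asarray(mask.data.shape)), axis=-1)
    out = np.zeros(shape, dtype=bool)
    s = src[ok]
    out[ok] = mask.data[s[:, 0], s[:, 1], s[:, 2]]
    return VolumeMask(out, like.spacing.copy(), like.origin.copy())
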