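"""Tracking-accuracy metrics on binary volumes and boundary point sets.

Given a ground-truth volume A and a predicted volume B:

* COM error — Euclidean distance between the mass centers (mm).
* DC  — Dice coefficient 2|A n B| / (|A| + |B|), in [0, 1], 1 best.
* PE  — percent error (|A u B| - |A n B|) / |A|, in [0, inf), 0 best.
* HD  — exact symmetric Hausdorff distance between boundary point sets (mm).

Overlap metrics are voxel-count based and require a shared grid; when grids
differ the predicted mask is resampled to the truth grid by nearest
neighbor.  PE is deliberately asymmetric (normalized by the truth volume).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .masks import VolumeMask, resample_nearest

__all__ = [
    "com_error",
    "dice",
    "percent_error",
    "hausdorff",
    "boundary_of",
    "evaluate_masks",
]


def _require_nonempty(mask: VolumeMask, label: str) -> None:
    if mask.n_foreground == 0:
        raise ValueError(f"{label} mask is empty")


def com_error(truth: VolumeMask, pred: VolumeMask) -> float:
    """3D Euclidean distance (mm) between foreground centroids."""
    _require_nonempty(truth, "truth")
    _require_nonempty(pred, "predicted")
    return float(np.linalg.norm(truth.centroid_world() - pred.centroid_world()))


def _aligned_counts(truth: VolumeMask, pred: VolumeMask) -> tuple[int, int, int]:
    if not truth.same_grid(pred):
        pred = resample_nearest(pred, like=truth)
    a, b = truth.data, pred.data
    return int(a.sum()), int(b.sum()), int((a & b).sum())


def dice(truth: VolumeMask, pred: VolumeMask) -> float:
    """Dice coefficient 2|A n B| / (|A| + |B|)."""
    na, nb, ni = _aligned_counts(truth, pred)
    if na + nb == 0:
        raise ValueError("Dice undefined: both masks are empty")
    return 2.0 * ni / (na + nb)


def percent_error(truth: VolumeMask, pred: VolumeMask) -> float:
    """Percent error (|A u B| - |A n B|) / |A|; asymmetric in its arguments."""
    _require_nonempty(truth, "truth")
    na, nb, ni = _aligned_counts(truth, pred)
    union = na + nb - ni
    return (union - ni) / na


def hausdorff(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Exact symmetric Hausdorff distance (mm) between point sets (P, 3)."""
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Hausdorff distance of an empty point set is undefined")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite boundary points")
    d_ab = cKDTree(b).query(a)[0].max()
    d_ba = cKDTree(a).query(b)[0].max()
    return float(max(d_ab, d_ba))


def boundary_of(mask: VolumeMask) -> np.ndarray:
    """World-mm centers of foreground voxels with a 6-connected background
    neighbor (voxels on the array border count as boundary)."""
    _require_nonempty(mask, "input")
    d = mask.data
    core = np.ones_like(d)
    for axis in range(3):
        lo = np.take(d, range(0, d.shape[axis] - 1), axis=axis)
        hi = np.take(d, range(1, d.shape[axis]), axis=axis)
        # neighbor missing (array edge) -> boundary
        pad_lo = [slice(None)] * 3
        pad_lo[axis] = slice(1, None)
        pad_hi = [slice(None)] * 3
        pad_hi[axis] = slice(0, -1)
        shifted = np.zeros_like(d)
        shifted[tuple(pad_lo)] = lo
        core &= shifted
        shifted = np.zeros_like(d)
        shifted[tuple(pad_hi)] = hi
        core &= shifted
    boundary = d & ~core
    idx = np.argwhere(boundary)
    return mask.origin + idx * mask.spacing


def evaluate_masks(truth: VolumeMask, pred: VolumeMask) -> dict[str, float]:
    """All four metrics between a truth and a predicted mask."""
    return {
        "com": com_error(truth, pred),
        "dc": dice(truth, pred),
        "pe": percent_error(truth, pred),
        "hd": hausdorff(boundary_of(truth), boundary_of(pred)),
    }
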