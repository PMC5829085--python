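"""Cross-phase vertex correspondence providers.

The modeling pipeline assumes vertex k of every phase mesh is the same
material point.  The analytic phantom guarantees this by construction
(:class:`ExactCorrespondence`); meshes from independent per-phase surface
extractions can be aligned approximately with
:class:`NearestNeighborCorrespondence`.  A full non-rigid point matcher can
be plugged in by implementing the same one-method interface.
"""

from __future__ import annotations

from typing import Protocol

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["CorrespondenceProvider", "ExactCorrespondence", "NearestNeighborCorrespondence"]


class CorrespondenceProvider(Protocol):
    def correspond(self, reference: np.ndarray, target: np.ndarray) -> np.ndarray:
        """Indices into ``target`` such that target[result[k]] matches
        reference vertex k."""
        ...


class ExactCorrespondence:
    """Identity mapping; validates that vertex counts agree."""

    def correspond(self, reference: np.ndarray, target: np.ndarray) -> np.ndarray:
        if len(reference) != len(target):
            raise ValueError(
                f"vertex count mismatch ({len(reference)} vs {len(target)}); "
                "exact correspondence requires identical meshing"
            )
        return np.arange(len(reference))


class NearestNeighborCorrespondence:
    """Closest-point matching, adequate for mild perturbations only."""

    def correspond(self, reference: np.ndarray, target: np.ndarray) -> np.ndarray:
        if len(target) == 0:
            raise ValueError("target mesh has no vertices")
        return cKDTree(np.asarray(target, dtype=float)).query(np.asarray(reference, dtype=float))[1]
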