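"""Analytic 4D thorax phantom for respiratory motion experiments.

Generates a breathing torso as nested ellipsoids — torso shell (external
surface), one lung, and a spherical tumor — sampled at J phases of one
breathing cycle.  The tumor centroid follows sinusoidal medio-lateral (ML),
anterior-posterior (AP) and superior-inferior (SI) trajectories

    u_ML(t) = (H/10) * sin(2*pi/T * (t - T/2))
    u_AP(t) = (H/10) * (sin(2*pi/T * (t - T/4)) + 1)
    u_SI(t) = (H/2)  * (sin(2*pi/T * (t - T/4)) + 1)

where ``T`` is the breathing period in seconds and ``H`` the maximal AP
amplitude of the external surface in mm.  Lung and external-surface vertices
move with the same temporal signal scaled by smooth, spatially varying gain
fields, so internal and external motion share the low-rank temporal
structure that surrogate-driven correlation models assume.

Coordinate convention (world, mm): ``x`` = ML, ``y`` = AP (anterior
positive), ``z`` = SI (superior positive).  Cross-phase vertex
correspondence is exact and by index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .masks import MaskGrid, VolumeMask
from .surface import PhaseMeshSet
from .voxelize import voxelize

__all__ = [
    "CycleSpec",
    "PhantomConfig",
    "Phantom4D",
    "TABLE_CYCLES",
    "trajectory",
    "generate_phantom",
]


@dataclass(frozen=True)
class CycleSpec:
    """Simulation parameters of one breathing cycle."""

    cycle_id: int
    period_T: float  # s
    max_amplitude_H: float  # mm, maximal AP amplitude of the external surface
    tumor_diameter: float  # mm
    n_phases_J: int = 10

    def __post_init__(self) -> None:
        if self.period_T <= 0:
            raise ValueError(f"period_T must be positive, got {self.period_T}")
        if self.max_amplitude_H <= 0:
            raise ValueError("max_amplitude_H must be positive")
        if self.tumor_diameter <= 0:
            raise ValueError("tumor_diameter must be positive")
        if self.n_phases_J < 3:
            raise ValueError("n_phases_J must be at least 3")

    @property
    def phase_times(self) -> np.ndarray:
        """Uniform phase sampling of one period: t_j = (j-1) T / J."""
        j = np.arange(self.n_phases_J)
        return j * self.period_T / self.n_phases_J


#: The five standard breathing cycles used in the phantom experiments:
#: (period s, max AP amplitude mm, tumor diameter mm).
TABLE_CYCLES: dict[int, CycleSpec] = {
    1: CycleSpec(1, 5.0, 12.0, 30.0),
    2: CycleSpec(2, 4.5, 10.0, 30.0),
    3: CycleSpec(3, 5.5, 14.0, 30.0),
    4: CycleSpec(4, 4.0, 8.0, 20.0),
    5: CycleSpec(5, 6.0, 16.0, 20.0),
}


def trajectory(cycle: CycleSpec, t) -> np.ndarray:
    """Tumor centroid displacement (ML, AP, SI) in mm at time ``t`` seconds.

    Vectorized over ``t``; returns shape ``(3,)`` for scalar input and
    ``(len(t), 3)`` otherwise.  Periodic with period ``cycle.period_T``.
    """
    T = cycle.period_T
    H = cycle.max_amplitude_H
    t = np.asarray(t, dtype=float)
    w = 2.0 * np.pi / T
    ml = (H / 10.0) * np.sin(w * (t - T / 2.0))
    ap = (H / 10.0) * (np.sin(w * (t - T / 4.0)) + 1.0)
    si = (H / 2.0) * (np.sin(w * (t - T / 4.0)) + 1.0)
    return np.stack([ml, ap, si], axis=-1)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, meshing, gain-field and rasterization settings.

    Gains are unitless multipliers mapping the tumor-centroid breathing
    signal onto each structure's per-vertex displacement.  The external
    anterior chest wall AP gain is fixed at 5 so its peak-to-peak AP
    excursion equals H (the tumor AP excursion is H/5).
    """

    torso_semiaxes: tuple[float, float, float] = (150.0, 100.0, 180.0)
    lung_center: tuple[float, float, float] = (60.0, 0.0, 20.0)
    lung_semiaxes: tuple[float, float, float] = (50.0, 60.0, 110.0)
    tumor_center: tuple[float, float, float] = (60.0, 10.0, -20.0)
    couch_plane_y: float = -50.0  # external shell keeps vertices with y >= this
    # icosphere subdivision level per structure (vertex counts 4^s*10+2)
    external_subdivisions: int = 5
    lung_subdivisions: int = 3
    tumor_subdivisions: int = 3
    # lung gain field: constant ML/AP, SI ramps from apex to base
    lung_ml_gain: float = 0.6
    lung_ap_gain: float = 0.5
    lung_si_gain_apex: float = 0.4
    lung_si_gain_base: float = 1.0
    # external gain field multipliers on the anterior weight a(v)
    external_ml_gain: float = 1.0
    external_si_gain: float = 0.35
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.5)
    grid_origin: tuple[float, float, float] = (-15.0, -85.0, -115.0)
    grid_shape: tuple[int, int, int] = (76, 86, 108)
    noise_sigma: float = 0.0  # mm, Gaussian vertex jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if any(n <= 1 for n in self.grid_shape):
            raise ValueError(f"degenerate mask grid shape {self.grid_shape}")
        gains = (self.lung_ml_gain, self.lung_ap_gain, self.lung_si_gain_apex,
                 self.lung_si_gain_base, self.external_ml_gain, self.external_si_gain)
        if not all(np.isfinite(gains)):
            raise ValueError("coupling gains must be finite")
        for level, name in ((self.external_subdivisions, "external"),
                            (self.lung_subdivisions, "lung"),
                            (self.tumor_subdivisions, "tumor")):
            if 10 * 4 ** level + 2 < 100:
                raise ValueError(f"{name} mesh would have < 100 vertices")

    @property
    def grid(self) -> MaskGrid:
        return MaskGrid(
            spacing=np.asarray(self.voxel_spacing, dtype=float),
            origin=np.asarray(self.grid_origin, dtype=float),
            shape=tuple(self.grid_shape),
        )


@dataclass
class Phantom4D:
    """One simulated breathing fraction: corresponded meshes and masks."""

    cycle: CycleSpec
    config: PhantomConfig
    structures: dict[str, PhaseMeshSet]
    masks: dict[str, list[VolumeMask]] = field(default_factory=dict)

    @property
    def grid(self) -> MaskGrid:
        return self.config.grid

    @property
    def internal_structures(self) -> list[str]:
        return [name for name in self.structures if name != "external"]


def _icosphere(subdivisions: int, semiaxes, center) -> tuple[np.ndarray, np.ndarray]:
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.asarray(mesh.vertices, dtype=float) * np.asarray(semiaxes, dtype=float)
    v = v + np.asarray(center, dtype=float)
    return v, np.asarray(mesh.faces, dtype=np.int64)


def _external_shell(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Anterior+lateral torso shell above the couch plane (open surface)."""
    v, f = _icosphere(config.external_subdivisions, config.torso_semiaxes, (0.0, 0.0, 0.0))
    keep = v[:, 1] >= config.couch_plane_y
    index = np.full(len(v), -1, dtype=np.int64)
    index[keep] = np.arange(keep.sum())
    f = f[np.all(keep[f], axis=1)]
    return v[keep], index[f]


def _lung_gain_field(vertices: np.ndarray, config: PhantomConfig) -> np.ndarray:
    """Per-vertex (M, 3) gain: constant ML/AP, SI ramp apex -> base."""
    z = vertices[:, 2]
    zmin, zmax = z.min(), z.max()
    zn = (z - zmin) / (zmax - zmin) if zmax > zmin else np.zeros_like(z)
    g = np.empty_like(vertices)
    g[:, 0] = config.lung_ml_gain
    g[:, 1] = config.lung_ap_gain
    # base (inferior, zn=0) moves most — diaphragm-driven
    g[:, 2] = config.lung_si_gain_base + (config.lung_si_gain_apex - config.lung_si_gain_base) * zn
    return g


def _external_gain_field(vertices: np.ndarray, config: PhantomConfig) -> np.ndarray:
    """Anterior-weighted gains; zero on the posterior (couch) side.

    The anterior weight a(v) = clip(y/b, 0, 1)^2 is C1-smooth, equals 1 at
    the anterior pole and 0 for y <= 0.  The AP gain 5*a makes the anterior
    wall's AP peak-to-peak excursion equal H.
    """
    b = config.torso_semiaxes[1]
    a = np.clip(vertices[:, 1] / b, 0.0, None) ** 2
    g = np.empty_like(vertices)
    g[:, 0] = config.external_ml_gain * a
    g[:, 1] = 5.0 * a
    g[:, 2] = config.external_si_gain * a
    return g


def _check_tumor_in_lung(config: PhantomConfig, tumor_vertices: np.ndarray) -> None:
    c = np.asarray(config.lung_center)
    s = np.asarray(config.lung_semiaxes)
    q = np.sum(((tumor_vertices - c) / s) ** 2, axis=1)
    if np.any(q >= 1.0):
        raise ValueError(
            "tumor is not fully inside the lung ellipsoid "
            f"(max normalized radius {np.sqrt(q.max()):.3f} >= 1)"
        )


def generate_phantom(
    config: PhantomConfig,
    cycle: CycleSpec,
    with_masks: bool = True,
) -> Phantom4D:
    """Simulate one breathing fraction of the analytic thorax phantom.

    Returns corresponded phase meshes for ``external``, ``lung`` and
    ``tumor`` and, when ``with_masks`` is true, binary voxel masks of the
    internal structures on the configured grid.  With zero noise the tumor
    mesh translates rigidly along :func:`trajectory`; identical
    ``config.seed`` gives bit-identical output.
    """
    J = cycle.n_phases_J
    times = cycle.phase_times
    signal = trajectory(cycle, times)  # (J, 3)

    tumor_v, tumor_f = _icosphere(
        config.tumor_subdivisions,
        (cycle.tumor_diameter / 2.0,) * 3,
        config.tumor_center,
    )
    _check_tumor_in_lung(config, tumor_v)
    lung_v, lung_f = _icosphere(config.lung_subdivisions, config.lung_semiaxes, config.lung_center)
    ext_v, ext_f = _external_shell(config)

    gains = {
        "external": _external_gain_field(ext_v, config),
        "lung": _lung_gain_field(lung_v, config),
        "tumor": np.ones_like(tumor_v),
    }
    bases = {"external": (ext_v, ext_f), "lung": (lung_v, lung_f), "tumor": (tumor_v, tumor_f)}

    rng = np.random.default_rng(config.seed)
    structures: dict[str, PhaseMeshSet] = {}
    for name, (v0, faces) in bases.items():
        phases = np.empty((J, len(v0), 3), dtype=float)
        for j in range(J):
            phases[j] = v0 + gains[name] * signal[j]
        if config.noise_sigma > 0:
            phases += rng.normal(0.0, config.noise_sigma, size=phases.shape)
        structures[name] = PhaseMeshSet(name=name, vertices=phases, faces=faces)

    masks: dict[str, list[VolumeMask]] = {}
    if with_masks:
        grid = config.grid
        for name in ("lung", "tumor"):
            pms = structures[name]
            masks[name] = [
                voxelize(pms.vertices[j], pms.faces, grid.spacing, grid.origin, grid.shape)
                for j in range(J)
            ]
    return Phantom4D(cycle=cycle, config=config, structures=structures, masks=masks)
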