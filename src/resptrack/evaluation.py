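"""Experimental protocols for intra- and inter-fraction tracking evaluation.

Four protocols are provided:

* ``phantom_intra`` — fit on one phantom breathing cycle, predict every
  phase of held-out cycles with the same anatomy (periods and amplitudes
  may differ).  External observations are referenced to the *training*
  mid-position, as in a single-planning-CT workflow.
* ``phantom_inter`` — held-out cycles with changed anatomy (e.g. tumor
  shrinkage).  The trained operator is kept but re-based on the test
  fraction's own mid-position meshes before prediction.
* ``loo_intra`` — leave-one-phase-out within a single fraction: J fits,
  each trained on J-1 phases and tested on the held-out phase.
* ``inter_4dct`` — train on one fraction, test on another, with baseline
  re-centering (same mechanics as ``phantom_inter``).

For every test phase the predicted internal surfaces are voxelized on the
evaluation grid and compared with the ground-truth masks via COM error,
Dice, percent error and Hausdorff distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masks import MaskGrid, VolumeMask
from .metrics import evaluate_masks
from .model import VARIANTS, CompositeModel, fit_model
from .phantom import TABLE_CYCLES, CycleSpec, Phantom4D, PhantomConfig, generate_phantom
from .surface import (
    PhaseMeshSet,
    build_patch_grid,
    directional_signal,
    external_signal,
    midp_reference,
    patch_signal,
    phasic_dvf,
)
from .voxelize import voxelize

__all__ = [
    "ProtocolSpec",
    "ResultsTable",
    "PhantomSource",
    "run_protocol",
    "compare_variants",
]

METRICS = ("com", "dc", "pe", "hd")
MODES = ("phantom_intra", "phantom_inter", "loo_intra", "inter_4dct")


@dataclass(frozen=True)
class ProtocolSpec:
    """One evaluation protocol run."""

    mode: str
    train: tuple[int, ...]
    test: tuple[int, ...]
    variants: tuple[str, ...] = VARIANTS
    K: int = 9
    seed: int = 0
    patch_rows: int = 14
    patch_cols: int = 11
    roi_count: int = 10

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown variants {sorted(unknown)}")
        # loo_intra trains on the complement of each held-out phase by
        # construction, so train/test disjointness holds per fold.
        if self.mode == "loo_intra" and len(self.train) != 1:
            raise ValueError("loo_intra uses exactly one fraction")


@dataclass
class ResultsTable:
    """Per-phase metric values plus recomputable summary statistics."""

    per_phase: pd.DataFrame  # columns: variant, structure, cycle, phase, metric, value
    spec: ProtocolSpec

    def summary(self) -> pd.DataFrame:
        """Mean and std per (variant, structure, metric)."""
        g = self.per_phase.groupby(["variant", "structure", "metric"])["value"]
        out = g.agg(["mean", "std", "max", "count"]).reset_index()
        out["std"] = out["std"].fillna(0.0)
        return out

    def render_text(self) -> str:
        """Mean +/- std table, one row per structure x metric, variants as columns."""
        s = self.summary()
        lines = [f"Protocol: {self.spec.mode}  (train={self.spec.train}, test={self.spec.test}, K={self.spec.K})"]
        cell = {}
        for _, r in s.iterrows():
            cell[(r["structure"], r["metric"], r["variant"])] = f"{r['mean']:.2f} ± {r['std']:.2f}"
        variants = list(self.spec.variants)
        header = f"{'structure':<10}{'metric':<8}" + "".join(f"{v:>16}" for v in variants)
        lines.append(header)
        for structure in sorted(self.per_phase["structure"].unique()):
            for metric in METRICS:
                row = f"{structure:<10}{metric:<8}"
                row += "".join(f"{cell.get((structure, metric, v), '-'):>16}" for v in variants)
                lines.append(row)
        return "\n".join(lines)


class PhantomSource:
    """Data source generating (and caching) phantom breathing fractions."""

    def __init__(
        self,
        config: PhantomConfig | None = None,
        cycles: dict[int, CycleSpec] | None = None,
    ) -> None:
        self.config = config if config is not None else PhantomConfig()
        self.cycles = dict(cycles) if cycles is not None else dict(TABLE_CYCLES)
        self._cache: dict[tuple[int, bool], Phantom4D] = {}

    def fraction(self, cycle_id: int, with_masks: bool = True) -> Phantom4D:
        key = (cycle_id, with_masks)
        if key not in self._cache:
            if cycle_id not in self.cycles:
                raise KeyError(f"unknown cycle id {cycle_id}; available: {sorted(self.cycles)}")
            self._cache[key] = generate_phantom(self.config, self.cycles[cycle_id], with_masks)
        return self._cache[key]


@dataclass
class _TrainedSet:
    grid_patches: object  # PatchGrid
    ext_midp: np.ndarray
    models: dict[tuple[str, str], CompositeModel]  # (variant, structure) -> model


def _fit_on_fraction(
    fraction,
    spec: ProtocolSpec,
    phases=None,
) -> _TrainedSet:
    ext = fraction.structures["external"]
    if phases is not None:
        ext = ext.subset_phases(phases)
    ext_midp = midp_reference(ext)
    grid = build_patch_grid(ext_midp, ext.faces, spec.patch_rows, spec.patch_cols)
    sig = external_signal(phasic_dvf(ext, ext_midp), grid, with_directional=True)

    models: dict[tuple[str, str], CompositeModel] = {}
    for structure in fraction.internal_structures:
        pms = fraction.structures[structure]
        if phases is not None:
            pms = pms.subset_phases(phases)
        midp = midp_reference(pms)
        dvfs = phasic_dvf(pms, midp)
        for variant in spec.variants:
            models[(variant, structure)] = fit_model(
                dvfs, sig, variant, spec.K, midp, pms.faces, roi_count=spec.roi_count
            )
    return _TrainedSet(grid_patches=grid, ext_midp=ext_midp, models=models)


def _grid_of(fraction) -> MaskGrid:
    grid = fraction.grid
    if grid is None:
        raise ValueError("data source provides no evaluation grid for mask metrics")
    return grid


def _truth_mask(fraction, structure: str, phase: int) -> VolumeMask:
    try:
        return fraction.masks[structure][phase]
    except (KeyError, IndexError) as e:
        raise ValueError(
            f"data source provides no ground-truth mask for {structure} phase {phase}"
        ) from e


def _predict_and_score(
    trained: _TrainedSet,
    fraction,
    spec: ProtocolSpec,
    cycle_label,
    S_test: np.ndarray,
    A_test: np.ndarray,
    rebase: bool,
    rows: list,
    phases=None,
) -> None:
    grid = _grid_of(fraction)
    phase_list = range(S_test.shape[0]) if phases is None else list(phases)
    for (variant, structure), model in trained.models.items():
        use = model
        if rebase:
            pms = fraction.structures[structure]
            use = model.rebase(midp_reference(pms), pms.faces)
        # restrict full-surface observations to the model's patch set
        full_ids = trained.grid_patches.active_ids
        pos = np.searchsorted(full_ids, model.patch_ids)
        for row_idx, phase in enumerate(phase_list):
            S_obs = S_test[row_idx][pos]
            A_obs = A_test[row_idx][pos] if variant == "SurMod" else None
            _, verts = use.predict(S_obs, A_obs=A_obs)
            pred = voxelize(verts, use.faces, grid.spacing, grid.origin, grid.shape)
            truth = _truth_mask(fraction, structure, phase)
            scores = evaluate_masks(truth, pred)
            # per-direction COM components (ML/AP/SI), as reported alongside
            # the 3D COM error
            axis_err = np.abs(truth.centroid_world() - pred.centroid_world())
            scores.update(com_ml=axis_err[0], com_ap=axis_err[1], com_si=axis_err[2])
            for metric, value in scores.items():
                rows.append(
                    {
                        "variant": variant,
                        "structure": structure,
                        "cycle": cycle_label,
                        "phase": phase,
                        "metric": metric,
                        "value": value,
                    }
                )


def run_protocol(spec: ProtocolSpec, source) -> ResultsTable:
    """Execute a protocol against a data source and collect all metrics.

    The source must provide ``fraction(id, with_masks)`` objects carrying
    corresponded ``structures`` (including ``"external"``), ground-truth
    ``masks`` for internal structures, and an evaluation ``grid``.
    """
    rows: list[dict] = []
    if spec.mode in ("phantom_intra", "phantom_inter", "inter_4dct"):
        rebase = spec.mode != "phantom_intra"
        train_fraction = source.fraction(spec.train[0], with_masks=False)
        trained = _fit_on_fraction(train_fraction, spec)
        for cycle_id in spec.test:
            test = source.fraction(cycle_id, with_masks=True)
            ext = test.structures["external"]
            if rebase:
                ref = midp_reference(ext)  # test fraction's own MidP
            else:
                ref = trained.ext_midp  # planning (training) MidP
            S_test = patch_signal(phasic_dvf(ext, ref), trained.grid_patches)
            A_test = directional_signal(S_test)
            _predict_and_score(
                trained, test, spec, cycle_id, S_test, A_test, rebase, rows
            )
    elif spec.mode == "loo_intra":
        fraction = source.fraction(spec.train[0], with_masks=True)
        J = fraction.structures["external"].n_phases
        test_phases = spec.test if spec.test else tuple(range(J))
        for held_out in test_phases:
            train_phases = [p for p in range(J) if p != held_out]
            trained = _fit_on_fraction(fraction, spec, phases=train_phases)
            ext = fraction.structures["external"]
            # observed phasic DVFs of the held-out phase and its cyclic
            # predecessor, both relative to the training MidP
            prev = (held_out - 1) % J
            dv = ext.vertices[[prev, held_out]] - trained.ext_midp[None]
            S_pair = patch_signal(dv, trained.grid_patches)
            S_test = S_pair[1:2]
            A_test = (S_pair[1] - S_pair[0])[None]
            _predict_and_score(
                trained, fraction, spec, spec.train[0], S_test, A_test,
                rebase=False, rows=rows, phases=[held_out],
            )
    else:  # pragma: no cover - guarded by ProtocolSpec
        raise ValueError(spec.mode)

    table = pd.DataFrame(rows, columns=["variant", "structure", "cycle", "phase", "metric", "value"])
    if table.empty:
        raise ValueError("protocol produced no results; check test set and data source")
    return ResultsTable(per_phase=table, spec=spec)


def compare_variants(table: ResultsTable) -> pd.DataFrame:
    """Descriptive per-metric ranking of the variants (no hypothesis tests).

    Returns one row per (structure, metric, variant) with the mean value and
    its rank (1 = best, where best is max for Dice and min otherwise).
    """
    s = table.summary()
    out = []
    for (structure, metric), grp in s.groupby(["structure", "metric"]):
        ascending = metric != "dc"
        grp = grp.sort_values("mean", ascending=ascending).reset_index(drop=True)
        for rank, r in grp.iterrows():
            out.append(
                {
                    "structure": structure,
                    "metric": metric,
                    "variant": r["variant"],
                    "mean": r["mean"],
                    "std": r["std"],
                    "rank": rank + 1,
                }
            )
    return pd.DataFrame(out)
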