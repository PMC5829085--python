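# Methods

## Model

The package models the relationship between internal anatomy motion and
external surface motion over one breathing cycle as *linear in a shared
low-dimensional latent space*. All displacement fields are phasic DVFs
taken relative to the mid-position (MidP) anatomy, the vertex-wise time
average over the J phases; by construction the per-vertex phase sum of
phasic DVFs is zero and the composite mean d̄ is (numerically) zero
whenever the DVFs are computed against the same phases' own MidP.

Per phase the composite vector stacks the internal block (3M entries,
vertex-major x, y, z) followed by, per external patch, the phasic triple
and — in the full variant — the directional triple. The centered composite
matrix D (size (3M + 6N) × J) has rank ≤ J − 1, so its principal
components come from the J × J Gram matrix DᵀD; eigenvectors X are mapped
to covariance eigenvectors E = DX. This "small-matrix" route is exact, not
an approximation, and is O(J²·dim) instead of O(dim²).

Numerical conventions (the underlying equations leave these open):

* **Eigenvector normalization and sign.** Columns of E are scaled to unit
  Euclidean norm with their largest-magnitude entry positive. The
  prediction operator B = E_I E_S⁺ is invariant to any per-column
  rescaling (verified by test), so these choices affect reproducibility of
  stored models only, not predictions.
* **E_S "inverse".** E_S is rectangular ((6N) × K), so the inverse in the
  operator definition is read as the Moore–Penrose pseudo-inverse with
  singular values below 1e-10 · σ_max truncated — equivalent to
  least-squares estimation of the latent weights from the external signal.
  A rank-deficient E_S (e.g. low-rank training motion) emits a warning and
  uses the truncated pseudo-inverse.
* **Zero eigenvalues.** Components with λ ≤ 1e-12 · λ_max are zeroed
  rather than normalized (normalizing a numerically null D·x would
  amplify rounding noise); the pseudo-inverse truncation then ignores
  them.
* **Near-degenerate eigenvalues** keep the deterministic symmetric
  eigensolver order and emit a warning; no silent reordering.
* **Directional wrap-around.** A₁ = S₁ − S_J (breathing is cyclic), which
  makes Σⱼ Aⱼ telescope to zero. In float64 the materialized differences
  cancel only to the last ulp (~1e-18 mm residue); tests assert the sum
  below 1e-14 mm, which is physically exact.
* **Directional term at prediction time.** Streaming callers pass the
  previous observation (A(t) = S(t) − S_prev); phase-indexed evaluation
  uses the cyclic previous phase; an explicit zero-directional mode exists
  but is never a silent default.
* **K default 9** (= J − 1 with J = 10), the maximum the decomposition
  permits; configurable per protocol.
* **RoiMod patch subset.** The 10 patches with the largest mean phasic
  displacement magnitude, ties broken by lower patch id. The historical
  ROI placement (between xiphoid and umbilicus) is not recoverable from
  geometry alone; amplitude ranking is this package's documented
  surrogate.

## External patch grid

Anterior-facing external vertices (outward normal with positive AP
component) are binned into a uniform 14 (SI) × 11 (ML) grid over their
bounding box; a vertex exactly on an interior bin edge goes to the
lower-index bin. Patches receiving no vertex are excluded (with a warning)
from S, A and the model consistently. Patch signals are the mean of member
vertex DVFs, hence linear in the underlying field.

## Baseline handling across fractions

Intra-fraction evaluation references all observations — internal truth and
external surrogates — to the *training* MidP, as in a single-planning-CT
workflow. Inter-fraction evaluation keeps the trained operator B but
re-bases the model on the test fraction's own MidP meshes (means reset to
zero, observations taken relative to the new MidP). This mirrors the
clinical update of registering treatment-day anatomy to the planning
anatomy; metrics then honestly include any shape mismatch between the
trained and actual anatomy.

## Analytic phantom

The phantom replaces an anthropomorphic-phantom dependency with nested
ellipsoids: torso shell (external surface restricted to the
anterior+lateral region above the couch plane y = −50 mm), one lung
ellipsoid and a spherical tumor. The tumor centroid follows

    u_ML = (H/10)·sin(2π/T·(t − T/2)),
    u_AP = (H/10)·(sin(2π/T·(t − T/4)) + 1),
    u_SI = (H/2)·(sin(2π/T·(t − T/4)) + 1),

with five stock cycles (T, H, tumor diameter): (5 s, 12 mm, 30 mm),
(4.5, 10, 30), (5.5, 14, 30), (4, 8, 20), (6, 16, 20). J = 10 phases
sample one period uniformly at t_j = (j − 1)T/J. Every structure's
per-vertex displacement is a smooth spatial gain field times this same
temporal signal:

* tumor: unit gains (rigid translation along the trajectory);
* lung: constant ML/AP gains (0.6/0.5) and an SI gain ramping 1.0 at the
  base to 0.4 at the apex — diaphragm-dominated motion;
* external: anterior weight a(v) = clip(y/b, 0, 1)², zero on the
  posterior/couch side; AP gain 5a so the anterior wall's AP peak-to-peak
  excursion equals H (the tumor AP excursion is H/5); SI gain 0.35a; ML
  gain a by default.

Gain magnitudes are the package's own choice of a realistic thorax
(surface AP amplitude dominating laterally-damped motion, lung base moving
with the full SI excursion); the trajectory and cycle parameters are
normative. Setting `external_ml_gain = 0` produces the diagnostic regime
in which the phasic external signal is temporally rank-one while the tumor
keeps its ML quadrature loop (inhale and exhale pass through the same
amplitudes at different tumor positions) — there the phasic-only variants
cannot recover ML motion and the directional variant can, which is the
motivating case for the directional surrogates.

With zero noise the phase-centered motion of every structure spans exactly
two temporal harmonics, so the composite matrix has rank 2: training-cycle
prediction is exact, and held-out cycles with different T and H are exact
up to (a) voxelization granularity and (b) a small constant bias
(~0.06 mm at default geometry) from the amplitude-change baseline offset
projecting imperfectly onto the directional components. What the phantom
deliberately does **not** emulate: irregular or drifting breathing,
hysteresis beyond the built-in quadrature, cardiac motion, registration
error (optional Gaussian vertex jitter stands in for it), and CT intensity
formation. Passing phantom tests therefore demonstrates the correctness of
the algebra and the pipeline, not clinical accuracy on real patients.

## Voxelization and metrics

Masks are rasterized with a center-inside rule: a voxel is foreground iff
its center lies inside the watertight surface, decided by z-column ray
parity with a fixed 1e-7-voxel column offset to dodge lattice-aligned
edges (deterministic tie-break). World coordinates are
origin + index · spacing, 0-based. The default evaluation grid uses
2.0 × 2.0 × 2.5 mm voxels covering the lung with margin.

COM error uses unweighted binary centroids and tolerates different grids;
Dice and percent error are voxel-count based and resample the prediction
to the truth grid by nearest neighbor when grids differ; the Hausdorff
distance is the exact max–min form (no percentile variant) computed by
KD-tree on boundary points. Boundaries are foreground voxels with at least
one 6-connected background (or out-of-grid) neighbor; mask boundaries are
the default HD input, mesh vertices may be passed directly.

## Problem sizes

Default meshes: external icosphere subdivision 5 (10 242 vertices before
the couch cut, ~7 700 after), lung and tumor subdivision 3 (642 vertices
each, comfortably above the ~100-vertex floor and matching the
~1 500-vertex regime where surface meshing saturates). The full five-cycle
protocol suite (fit + 40 test-phase predictions + ~80 voxelizations) runs
in well under a minute on one CPU; unit tests use a coarsened phantom
(subdivisions 4/2/2, 4 × 4 × 5 mm grid).

## Known limitations

* The correlation is strictly linear; breathing patterns outside the
  training span (baseline drift, phase shifts, irregular cycles) degrade
  gracefully but are not modeled.
* Correspondence across phases is assumed given (exact for the phantom,
  nearest-neighbor provider for mild perturbations); no non-rigid point
  matcher is bundled, only the plug-in interface.
* Inter-fraction re-basing transfers the operator unchanged; no
  re-weighting or online update from in-treatment imaging is implemented.
* Statistical significance testing of variant differences is out of scope;
  `compare_variants` is descriptive only.
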