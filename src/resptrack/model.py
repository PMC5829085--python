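"""Internal-external motion correlation model via reduced-cost PCA.

Per breathing phase j, a composite vector stacks the internal per-vertex
phasic DVFs with the external patch surrogates:

    d_j = [I_j ; ext_j],    ext_j = interleave(S_j, A_j)  (full variant)
                            ext_j = S_j                    (phasic variants)

The phase-centered composite matrix D = [d_1 - dbar, ..., d_J - dbar] has
rank at most J-1, so its principal components are found from the small J x J
Gram matrix D^T D: if D^T D X = lambda X then D D^T (D X) = lambda (D X),
i.e. the columns of D X are the eigenvectors of the covariance D D^T with
the same eigenvalues.  Keeping the K <= J-1 leading components E and
splitting rows into internal (E_I) and external (E_S) blocks yields the
linear correlation operator

    B = E_I  E_S^+          (Moore-Penrose; E_S is rectangular)

which predicts internal motion from an observed, centered external
surrogate: I~(t) = B (s(t) - dbar_S).  B is invariant to rescaling of the
eigenvector columns (the scale cancels between E_I and E_S^+).

Model variants:

* ``SurMod``    — full external surface, phasic + directional DVFs.
* ``SurphaMod`` — full external surface, phasic DVFs only.
* ``RoiMod``    — phasic DVFs on a small subset of high-amplitude patches.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from functools import cached_property

import numpy as np
import scipy.linalg

from .surface import ExternalSignal

__all__ = [
    "VARIANTS",
    "CompositeMatrix",
    "CompositeModel",
    "assemble",
    "pca_small",
    "split_and_correlate",
    "select_roi_patches",
    "fit_model",
]

VARIANTS = ("RoiMod", "SurphaMod", "SurMod")

_PINV_RTOL = 1e-10
_MODEL_FORMAT_VERSION = "resptrack-model-1"


def _external_composite(S_j: np.ndarray, A_j: np.ndarray | None, variant: str) -> np.ndarray:
    """External block of d_j: per patch [Sx,Sy,Sz,Ax,Ay,Az] (full) or [Sx,Sy,Sz]."""
    if variant == "SurMod":
        if A_j is None:
            raise ValueError("SurMod requires directional DVFs A")
        return np.concatenate([S_j, A_j], axis=1).ravel()
    return np.asarray(S_j, dtype=float).ravel()


@dataclass
class CompositeMatrix:
    """Centered composite matrix D with its mean and block layout."""

    D: np.ndarray  # (3M + E, J), columns centered
    mean: np.ndarray  # (3M + E,)
    n_internal_vertices: int  # M
    n_patches: int  # N
    variant: str

    @property
    def n_phases(self) -> int:
        return self.D.shape[1]

    @property
    def internal_dim(self) -> int:
        return 3 * self.n_internal_vertices

    @property
    def external_dim(self) -> int:
        return self.D.shape[0] - self.internal_dim


def assemble(internal_dvfs: np.ndarray, signal: ExternalSignal, variant: str) -> CompositeMatrix:
    """Stack internal and external DVFs of all phases into a centered matrix.

    ``internal_dvfs``: (J, M, 3).  The internal block comes first
    (vertex-major x,y,z); the external block follows, per patch the phasic
    triple then (full variant) the directional triple.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    internal_dvfs = np.asarray(internal_dvfs, dtype=float)
    J, M, _ = internal_dvfs.shape
    if signal.n_phases != J:
        raise ValueError(
            f"phase count mismatch: internal has {J}, external has {signal.n_phases}"
        )
    if not np.all(np.isfinite(internal_dvfs)) or not np.all(np.isfinite(signal.S)):
        raise ValueError("non-finite values in DVF input")
    cols = []
    for j in range(J):
        A_j = signal.A[j] if signal.A is not None else None
        cols.append(
            np.concatenate([internal_dvfs[j].ravel(), _external_composite(signal.S[j], A_j, variant)])
        )
    d = np.stack(cols, axis=1)  # (dim, J)
    mean = d.mean(axis=1)
    return CompositeMatrix(
        D=d - mean[:, None],
        mean=mean,
        n_internal_vertices=M,
        n_patches=signal.n_patches,
        variant=variant,
    )


def pca_small(comp: CompositeMatrix, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Leading K principal components of D via the J x J Gram matrix.

    Returns ``(eigenvalues, E)`` with eigenvalues descending and E of shape
    (dim, K); columns are unit-norm with the largest-magnitude entry
    positive.  Columns whose eigenvalue is numerically zero are zeroed.
    """
    D = comp.D
    J = D.shape[1]
    if not 1 <= K <= J - 1:
        raise ValueError(f"K must satisfy 1 <= K <= J-1 = {J - 1}, got {K}")
    gram = D.T @ D
    lam, X = scipy.linalg.eigh(gram)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)[:K]
    X = X[:, order[:K]]
    if K >= 2:
        gaps = np.abs(np.diff(lam))
        scale = max(lam[0], 1e-300)
        if np.any(gaps < 1e-9 * scale):
            warnings.warn(
                "near-degenerate eigenvalues; component order fixed by the "
                "deterministic symmetric-eigensolver tie-break"
            )
    E = D @ X
    tol = max(lam[0], 0.0) * 1e-12
    for k in range(K):
        norm = np.linalg.norm(E[:, k])
        if lam[k] <= tol or norm == 0.0:
            E[:, k] = 0.0
            continue
        E[:, k] /= norm
        lead = np.argmax(np.abs(E[:, k]))
        if E[lead, k] < 0:
            E[:, k] = -E[:, k]
    return lam, E


@dataclass
class CompositeModel:
    """Fitted correlation model: eigenbasis split and prediction operator."""

    variant: str
    K: int
    eigenvalues: np.ndarray  # (K,), descending
    E_I: np.ndarray  # (3M, K)
    E_S: np.ndarray  # (E, K)
    mean_internal: np.ndarray  # (3M,)
    mean_external: np.ndarray  # (E,)
    patch_ids: np.ndarray  # (N,)
    midp_vertices: np.ndarray  # (M, 3) reference internal anatomy
    faces: np.ndarray  # (F, 3)
    version: str = _MODEL_FORMAT_VERSION

    @property
    def n_internal_vertices(self) -> int:
        return self.E_I.shape[0] // 3

    @property
    def n_patches(self) -> int:
        return len(self.patch_ids)

    @cached_property
    def _pinv_E_S(self) -> np.ndarray:
        return np.linalg.pinv(self.E_S, rcond=_PINV_RTOL)

    @cached_property
    def B(self) -> np.ndarray:
        """Correlation operator, internal = B @ centered external."""
        return self.E_I @ self._pinv_E_S

    def _observed_composite(
        self,
        S_obs: np.ndarray,
        A_obs: np.ndarray | None,
        prev_S: np.ndarray | None,
        zero_directional: bool,
    ) -> np.ndarray:
        S_obs = np.asarray(S_obs, dtype=float)
        if S_obs.shape != (self.n_patches, 3):
            raise ValueError(
                f"observed signal has shape {S_obs.shape}, expected ({self.n_patches}, 3)"
            )
        if self.variant != "SurMod":
            return S_obs.ravel()
        if A_obs is None:
            if prev_S is not None:
                A_obs = S_obs - np.asarray(prev_S, dtype=float)
            elif zero_directional:
                A_obs = np.zeros_like(S_obs)
            else:
                raise ValueError(
                    "SurMod prediction needs a directional observation: pass A_obs, "
                    "a predecessor prev_S (use the cyclic previous phase in "
                    "phase-indexed evaluation), or zero_directional=True"
                )
        return np.concatenate([S_obs, np.asarray(A_obs, dtype=float)], axis=1).ravel()

    def predict(
        self,
        S_obs: np.ndarray,
        A_obs: np.ndarray | None = None,
        prev_S: np.ndarray | None = None,
        zero_directional: bool = False,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Predict internal motion from an observed external surrogate.

        Returns ``(dvf, vertices)``: the predicted internal DVF (M, 3) about
        the mean state, and the absolute internal surface
        ``midp + mean_internal + dvf``.
        """
        s = self._observed_composite(S_obs, A_obs, prev_S, zero_directional)
        s_tilde = s - self.mean_external
        i_tilde = self.E_I @ (self._pinv_E_S @ s_tilde)
        dvf = i_tilde.reshape(-1, 3)
        vertices = self.midp_vertices + self.mean_internal.reshape(-1, 3) + dvf
        return dvf, vertices

    def rebase(self, midp_vertices: np.ndarray, faces: np.ndarray | None = None) -> "CompositeModel":
        """Re-center the model on a new fraction's mid-position anatomy.

        The correlation operator is kept; the reference internal anatomy is
        replaced and the means reset to zero, so subsequent observations
        must be phasic DVFs relative to the new fraction's own MidP.
        """
        midp_vertices = np.asarray(midp_vertices, dtype=float)
        if midp_vertices.shape[0] != self.n_internal_vertices:
            raise ValueError(
                "new MidP anatomy has a different vertex count than the trained model"
            )
        return replace(
            self,
            midp_vertices=midp_vertices,
            faces=self.faces if faces is None else np.asarray(faces, dtype=np.int64),
            mean_internal=np.zeros_like(self.mean_internal),
            mean_external=np.zeros_like(self.mean_external),
        )

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        """Write the model as a single NumPy archive (lossless round trip)."""
        meta = {"variant": self.variant, "K": int(self.K), "version": self.version}
        np.savez_compressed(
            path,
            meta=json.dumps(meta),
            eigenvalues=self.eigenvalues,
            E_I=self.E_I,
            E_S=self.E_S,
            B=self.B,
            mean_internal=self.mean_internal,
            mean_external=self.mean_external,
            patch_ids=self.patch_ids,
            midp_vertices=self.midp_vertices,
            faces=self.faces,
        )

    @classmethod
    def load(cls, path) -> "CompositeModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            model = cls(
                variant=meta["variant"],
                K=meta["K"],
                eigenvalues=z["eigenvalues"],
                E_I=z["E_I"],
                E_S=z["E_S"],
                mean_internal=z["mean_internal"],
                mean_external=z["mean_external"],
                patch_ids=z["patch_ids"],
                midp_vertices=z["midp_vertices"],
                faces=z["faces"],
                version=meta["version"],
            )
        return model


def split_and_correlate(
    eigenvalues: np.ndarray,
    E: np.ndarray,
    comp: CompositeMatrix,
    signal: ExternalSignal,
    midp_vertices: np.ndarray,
    faces: np.ndarray,
) -> CompositeModel:
    """Split the eigenbasis into internal/external blocks and form the model.

    E_I takes the first 3M rows of E, E_S the remaining external rows.  A
    rank-deficient E_S triggers a warning; the pseudo-inverse truncates
    singular values below rtol * sigma_max (rtol = 1e-10).
    """
    K = E.shape[1]
    three_m = comp.internal_dim
    E_I, E_S = E[:three_m], E[three_m:]
    if np.linalg.matrix_rank(E_S, tol=_PINV_RTOL * max(1.0, np.linalg.norm(E_S, 2))) < K:
        warnings.warn(
            "external eigenbasis E_S is rank deficient; using a truncated "
            "pseudo-inverse (small singular values discarded)"
        )
    return CompositeModel(
        variant=comp.variant,
        K=K,
        eigenvalues=np.asarray(eigenvalues, dtype=float),
        E_I=E_I,
        E_S=E_S,
        mean_internal=comp.mean[:three_m],
        mean_external=comp.mean[three_m:],
        patch_ids=np.asarray(signal.patch_ids).copy(),
        midp_vertices=np.asarray(midp_vertices, dtype=float),
        faces=np.asarray(faces, dtype=np.int64),
    )


def select_roi_patches(signal: ExternalSignal, count: int = 10) -> np.ndarray:
    """Patch ids with the largest mean phasic displacement magnitude.

    Deterministic tie-break: lower patch id wins.  Returns ids sorted
    ascending.
    """
    if count > signal.n_patches:
        raise ValueError(
            f"requested {count} ROI patches but only {signal.n_patches} available"
        )
    amplitude = np.linalg.norm(signal.S, axis=2).mean(axis=0)  # (N,)
    order = np.lexsort((signal.patch_ids, -amplitude))
    return np.sort(signal.patch_ids[order[:count]])


def fit_model(
    internal_dvfs: np.ndarray,
    signal: ExternalSignal,
    variant: str,
    K: int,
    midp_vertices: np.ndarray,
    faces: np.ndarray,
    roi_count: int = 10,
) -> CompositeModel:
    """Assemble, eigendecompose and split in one call.

    For ``RoiMod`` the signal is first restricted to the ``roi_count``
    highest-amplitude patches.
    """
    if variant == "RoiMod":
        signal = signal.restrict(select_roi_patches(signal, roi_count))
    comp = assemble(internal_dvfs, signal, variant)
    lam, E = pca_small(comp, K)
    return split_and_correlate(lam, E, comp, signal, midp_vertices, faces)
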