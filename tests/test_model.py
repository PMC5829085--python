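"""Correlation model: composite assembly, reduced-cost PCA, operator algebra."""

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import resptrack as rt
from resptrack.model import _PINV_RTOL
from resptrack.surface import ExternalSignal

from conftest import random_composite


def toy_signal(rng, J, N, with_A=True):
    S = rng.normal(size=(J, N, 3))
    S -= S.mean(axis=0, keepdims=True)
    A = rt.directional_signal(S) if with_A else None
    return ExternalSignal(S=S, A=A, patch_ids=np.arange(N))


def toy_internal(rng, J, M):
    I = rng.normal(size=(J, M, 3))
    return I - I.mean(axis=0, keepdims=True)


def fit_toy(rng, J=6, M=4, N=3, variant="SurMod", K=None):
    sig = toy_signal(rng, J, N, with_A=(variant == "SurMod"))
    I = toy_internal(rng, J, M)
    K = J - 1 if K is None else K
    midp = rng.normal(size=(M, 3))
    faces = np.array([[0, 1, 2]])
    model = rt.fit_model(I, sig, variant, K, midp, faces, roi_count=min(3, N))
    return model, I, sig


class TestAssemble:
    def test_identical_phases_give_zero_matrix(self):
        I = np.ones((4, 2, 3))
        sig = ExternalSignal(S=np.ones((4, 3, 3)), A=None, patch_ids=np.arange(3))
        comp = rt.assemble(I, sig, "SurphaMod")
        npt.assert_array_equal(comp.D, 0.0)
        npt.assert_array_equal(comp.mean, np.ones(comp.D.shape[0]))

    def test_two_phases_center_antisymmetrically(self):
        rng = np.random.default_rng(0)
        I = rng.normal(size=(2, 3, 3))
        sig = toy_signal(rng, 2, 2, with_A=False)
        comp = rt.assemble(I, sig, "SurphaMod")
        npt.assert_allclose(comp.D[:, 0], -comp.D[:, 1], atol=1e-12)

    def test_row_sums_are_zero(self):
        rng = np.random.default_rng(1)
        comp = rt.assemble(toy_internal(rng, 3, 1), toy_signal(rng, 3, 1), "SurMod")
        npt.assert_allclose(comp.D.sum(axis=1), 0.0, atol=1e-12)

    def test_surmod_layout_interleaves_s_and_a_per_patch(self):
        J, M, N = 3, 1, 2
        I = np.zeros((J, M, 3))
        S = np.arange(J * N * 3, dtype=float).reshape(J, N, 3)
        A = 100 + np.arange(J * N * 3, dtype=float).reshape(J, N, 3)
        sig = ExternalSignal(S=S, A=A, patch_ids=np.arange(N))
        comp = rt.assemble(I, sig, "SurMod")
        d0 = comp.D[:, 0] + comp.mean  # un-centered first column
        expected = np.concatenate([I[0].ravel(), S[0, 0], A[0, 0], S[0, 1], A[0, 1]])
        npt.assert_array_equal(d0, expected)
        assert comp.external_dim == 6 * N

    def test_phase_count_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="phase count"):
            rt.assemble(toy_internal(rng, 4, 2), toy_signal(rng, 3, 2), "SurphaMod")

    def test_nan_input_rejected(self):
        rng = np.random.default_rng(3)
        I = toy_internal(rng, 3, 2)
        I[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            rt.assemble(I, toy_signal(rng, 3, 2), "SurphaMod")

    def test_surmod_requires_directional(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="directional"):
            rt.assemble(toy_internal(rng, 3, 2), toy_signal(rng, 3, 2, with_A=False), "SurMod")


class TestPcaSmall:
    def test_rank_one_matrix_has_single_nonzero_eigenvalue(self):
        u = np.arange(1.0, 7.0)[:, None]
        w = np.array([[1.0, -1.0, 2.0, -2.0]])
        comp = rt.CompositeMatrix(D=u @ (w - w.mean()), mean=np.zeros(6),
                                  n_internal_vertices=1, n_patches=1, variant="SurphaMod")
        lam, E = rt.pca_small(comp, K=3)
        assert lam[0] > 1e-6
        npt.assert_allclose(lam[1:], 0.0, atol=1e-9 * lam[0])

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_gram_trick_matches_direct_covariance_eigendecomposition(self, seed):
        """Eigen-trick oracle: dense eigh of D D^T on random small matrices."""
        rng = np.random.default_rng(seed)
        dim = rng.integers(5, 12)
        J = rng.integers(3, min(dim, 7))
        comp = random_composite(rng, dim, J, M=1, N=1)
        lam, E = rt.pca_small(comp, K=J - 1)
        direct = np.linalg.eigvalsh(comp.D @ comp.D.T)[::-1][: J - 1]
        npt.assert_allclose(lam, np.clip(direct, 0, None), rtol=1e-9, atol=1e-9 * max(lam[0], 1))
        # eigenvectors of the covariance: D D^T e_k = lam_k e_k
        for k in range(J - 1):
            if lam[k] > 1e-8 * lam[0]:
                npt.assert_allclose(comp.D @ (comp.D.T @ E[:, k]), lam[k] * E[:, k],
                                    atol=1e-8 * lam[0])

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_full_rank_reconstruction_is_complete(self, seed):
        """K = J-1 spans the centered matrix: ||D - E E^T D|| / ||D|| <= 1e-9."""
        rng = np.random.default_rng(seed)
        comp = random_composite(rng, 8, 5, M=1, N=1)
        _, E = rt.pca_small(comp, K=4)
        resid = comp.D - E @ (E.T @ comp.D)
        assert np.linalg.norm(resid) <= 1e-9 * np.linalg.norm(comp.D)

    def test_columns_unit_norm_with_positive_leading_entry(self):
        rng = np.random.default_rng(9)
        comp = random_composite(rng, 10, 6, M=1, N=1)
        lam, E = rt.pca_small(comp, K=5)
        npt.assert_allclose(np.linalg.norm(E, axis=0), 1.0, atol=1e-12)
        for k in range(5):
            assert E[np.argmax(np.abs(E[:, k])), k] > 0
        assert np.all(np.diff(lam) <= 1e-12)  # descending

    def test_k_larger_than_J_minus_1_rejected(self):
        rng = np.random.default_rng(10)
        comp = random_composite(rng, 8, 4, M=1, N=1)
        with pytest.raises(ValueError, match="K"):
            rt.pca_small(comp, K=4)

    def test_degenerate_eigenvalues_warn(self):
        # two orthogonal columns of equal norm -> tied eigenvalues
        D = np.zeros((4, 3))
        D[0, 0], D[1, 1] = 1.0, 1.0
        D[2, 2] = 0.0
        comp = rt.CompositeMatrix(D=D, mean=np.zeros(4), n_internal_vertices=0,
                                  n_patches=1, variant="SurphaMod")
        with pytest.warns(UserWarning, match="degenerate"):
            rt.pca_small(comp, K=2)


class TestSplitAndPredict:
    def test_identity_coupling_reproduces_internal_motion(self):
        # internal motion mirrored one-to-one onto "patches": B S = I
        rng = np.random.default_rng(11)
        J, M = 6, 5
        I = toy_internal(rng, J, M)
        sig = ExternalSignal(S=I.copy(), A=None, patch_ids=np.arange(M))
        model = rt.fit_model(I, sig, "SurphaMod", J - 1, np.zeros((M, 3)), np.array([[0, 1, 2]]))
        for j in range(J):
            dvf, _ = model.predict(I[j])
            npt.assert_allclose(dvf, I[j], atol=1e-8)

    def test_rank_one_closed_form_pseudo_inverse(self):
        # K=1, E_I = alpha u, E_S = beta v -> B = (alpha/beta) u v^T
        rng = np.random.default_rng(12)
        u = rng.normal(size=6)
        u /= np.linalg.norm(u)
        v = rng.normal(size=4)
        v /= np.linalg.norm(v)
        alpha, beta = 2.5, -0.8
        model = rt.CompositeModel(
            variant="SurphaMod", K=1, eigenvalues=np.array([1.0]),
            E_I=(alpha * u)[:, None], E_S=(beta * v)[:, None],
            mean_internal=np.zeros(6), mean_external=np.zeros(4),
            patch_ids=np.arange(4), midp_vertices=np.zeros((2, 3)),
            faces=np.array([[0, 1, 2]]),
        )
        npt.assert_allclose(model.B, (alpha / beta) * np.outer(u, v), atol=1e-12)

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.sampled_from(["SurphaMod", "SurMod"]))
    def test_in_sample_prediction_recovers_training_phases(self, seed, variant):
        """With K=J-1 and full-column-rank E_S, training phases are reproduced.

        Oracle: direct least-squares fit of the internal block on the
        external block across phases.
        """
        rng = np.random.default_rng(seed)
        J, M, N = 6, 3, 4  # external dim >= J-1 so E_S has full column rank
        model, I, sig = fit_toy(rng, J=J, M=M, N=N, variant=variant)
        ext_rows = []
        int_rows = []
        for j in range(J):
            if variant == "SurMod":
                ext_rows.append(np.concatenate([sig.S[j], sig.A[j]], axis=1).ravel())
            else:
                ext_rows.append(sig.S[j].ravel())
            int_rows.append(I[j].ravel())
        X = np.stack(ext_rows, axis=1) - model.mean_external[:, None]
        Y = np.stack(int_rows, axis=1) - model.mean_internal[:, None]
        B_ls = Y @ np.linalg.pinv(X)  # independent least-squares oracle
        for j in range(J):
            A_obs = sig.A[j] if variant == "SurMod" else None
            dvf, _ = model.predict(sig.S[j], A_obs=A_obs)
            expect = I[j] - model.mean_internal.reshape(-1, 3)
            scale = max(np.linalg.norm(expect), 1e-9)
            assert np.linalg.norm(dvf - expect) <= 1e-6 * scale
            npt.assert_allclose(dvf.ravel(), B_ls @ X[:, j], atol=1e-6)

    def test_mean_observation_predicts_mean_anatomy(self):
        rng = np.random.default_rng(14)
        model, I, sig = fit_toy(rng, variant="SurphaMod")
        mean_S = model.mean_external.reshape(-1, 3)
        dvf, verts = model.predict(mean_S)
        npt.assert_allclose(dvf, 0.0, atol=1e-9)
        npt.assert_allclose(verts, model.midp_vertices + model.mean_internal.reshape(-1, 3),
                            atol=1e-9)

    def test_prediction_is_affine_linear(self):
        rng = np.random.default_rng(15)
        model, _, sig = fit_toy(rng, variant="SurphaMod")
        s1, s2 = rng.normal(size=(2, model.n_patches, 3))
        mean = model.mean_external.reshape(-1, 3)
        lhs, _ = model.predict(s1 + s2 - mean)
        r1, _ = model.predict(s1)
        r2, _ = model.predict(s2)
        npt.assert_allclose(lhs, r1 + r2, atol=1e-9)

    def test_b_invariant_under_eigenvector_column_rescaling(self):
        rng = np.random.default_rng(16)
        model, _, _ = fit_toy(rng, J=6, M=3, N=4, variant="SurphaMod")
        scales = rng.uniform(0.2, 5.0, size=model.K) * rng.choice([-1, 1], size=model.K)
        from dataclasses import replace
        scaled = replace(model, E_I=model.E_I * scales, E_S=model.E_S * scales)
        npt.assert_allclose(scaled.B, model.B, atol=1e-9)

    def test_surmod_needs_predecessor_or_explicit_zero_mode(self):
        rng = np.random.default_rng(17)
        model, _, sig = fit_toy(rng, variant="SurMod")
        S = sig.S[2]
        with pytest.raises(ValueError, match="cyclic"):
            model.predict(S)
        dvf_prev, _ = model.predict(S, prev_S=sig.S[1])
        dvf_a, _ = model.predict(S, A_obs=sig.S[2] - sig.S[1])
        npt.assert_allclose(dvf_prev, dvf_a, atol=1e-12)
        model.predict(S, zero_directional=True)  # explicit fallback allowed

    def test_rank_deficient_external_block_warns(self):
        rng = np.random.default_rng(18)
        J, M, N = 6, 4, 1  # external dim 3 < K=5 -> rank deficient
        sig = toy_signal(rng, J, N, with_A=False)
        I = toy_internal(rng, J, M)
        with pytest.warns(UserWarning, match="rank deficient"):
            rt.fit_model(I, sig, "SurphaMod", J - 1, np.zeros((M, 3)), np.array([[0, 1, 2]]))

    def test_monotone_degradation_as_modes_removed(self, small_phantom):
        """Training-phase error does not decrease when K shrinks."""
        ext = small_phantom.structures["external"]
        midp_e = rt.midp_reference(ext)
        grid = rt.build_patch_grid(midp_e, ext.faces)
        sig = rt.external_signal(rt.phasic_dvf(ext, midp_e), grid)
        tum = small_phantom.structures["tumor"]
        midp_t = rt.midp_reference(tum)
        dvfs = rt.phasic_dvf(tum, midp_t)
        errors = []
        for K in range(9, 0, -1):
            model = rt.fit_model(dvfs, sig, "SurphaMod", K, midp_t, tum.faces)
            err = 0.0
            for j in range(tum.n_phases):
                pred, _ = model.predict(sig.S[j])
                err += np.linalg.norm(pred - dvfs[j])
            errors.append(err)
        assert all(b >= a - 1e-9 for a, b in zip(errors, errors[1:]))

    def test_rebase_swaps_reference_anatomy(self):
        rng = np.random.default_rng(19)
        model, _, sig = fit_toy(rng, variant="SurphaMod")
        new_midp = rng.normal(size=model.midp_vertices.shape)
        rebased = model.rebase(new_midp)
        npt.assert_array_equal(rebased.midp_vertices, new_midp)
        npt.assert_array_equal(rebased.mean_internal, 0.0)
        npt.assert_allclose(rebased.B, model.B)
        with pytest.raises(ValueError, match="vertex count"):
            model.rebase(np.zeros((model.n_internal_vertices + 1, 3)))


class TestRoiSelection:
    def test_count_equal_to_n_returns_all(self):
        rng = np.random.default_rng(20)
        sig = toy_signal(rng, 4, 5, with_A=False)
        npt.assert_array_equal(rt.select_roi_patches(sig, 5), sig.patch_ids)

    def test_static_patch_excluded(self):
        S = np.ones((4, 3, 3))
        S[:, 1] = 0.0  # patch 1 static
        sig = ExternalSignal(S=S, A=None, patch_ids=np.array([10, 11, 12]))
        npt.assert_array_equal(rt.select_roi_patches(sig, 2), [10, 12])

    def test_matches_brute_force_amplitude_ranking(self, small_phantom):
        ext = small_phantom.structures["external"]
        midp = rt.midp_reference(ext)
        grid = rt.build_patch_grid(midp, ext.faces)
        sig = rt.external_signal(rt.phasic_dvf(ext, midp), grid, with_directional=False)
        chosen = rt.select_roi_patches(sig, 10)
        amp = {p: np.linalg.norm(sig.S[:, i], axis=1).mean()
               for i, p in enumerate(sig.patch_ids)}
        brute = sorted(sorted(amp, key=lambda p: (-amp[p], p))[:10])
        npt.assert_array_equal(chosen, brute)

    def test_too_few_patches_rejected(self):
        rng = np.random.default_rng(21)
        with pytest.raises(ValueError, match="ROI"):
            rt.select_roi_patches(toy_signal(rng, 4, 3, with_A=False), 4)


class TestSerialization:
    def test_round_trip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(22)
        model, _, _ = fit_toy(rng, variant="SurMod")
        path = tmp_path / "model.npz"
        model.save(path)
        back = rt.CompositeModel.load(path)
        assert back.variant == model.variant and back.K == model.K
        for attr in ("eigenvalues", "E_I", "E_S", "mean_internal", "mean_external",
                     "patch_ids", "midp_vertices", "faces"):
            npt.assert_array_equal(getattr(back, attr), getattr(model, attr))
        npt.assert_allclose(back.B, model.B, atol=1e-12)
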