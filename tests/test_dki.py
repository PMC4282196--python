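import numpy as np
import pytest
from scipy.stats import special_ortho_group

from conftest import random_tensors
from dkivba import dki
from dkivba.dki import (
    FLAG_CLIPPED,
    FLAG_NONPOS_SIGNAL,
    KurtosisFit,
    apparent_along,
    design_matrix,
    fit_volume,
    fit_voxel,
    full_to_w15,
    kurtosis_maps,
    quadratic_form,
    quartic_form,
    rotate_kt,
    w15_to_full,
)
from dkivba.phantom import isotropic_w15


def forward_signals(scheme, s0, d6, w15):
    """Reference forward model evaluated through the design matrix."""
    md = np.asarray(d6)[..., :3].mean(axis=-1)
    beta = np.concatenate(
        [np.log(s0) * np.ones(np.shape(md) + (1,)), d6, w15 * md[..., None] ** 2],
        axis=-1,
    )
    return np.exp(beta @ design_matrix(scheme).T)


class TestTensorAlgebra:
    def test_w15_full_roundtrip(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal(15)
        np.testing.assert_allclose(full_to_w15(w15_to_full(w)), w)

    def test_full_tensor_is_symmetric(self):
        from itertools import permutations

        rng = np.random.default_rng(1)
        full = w15_to_full(rng.standard_normal(15))
        for perm in permutations(range(4)):
            np.testing.assert_array_equal(full, np.transpose(full, perm))

    def test_quartic_form_matches_full_contraction(self):
        rng = np.random.default_rng(2)
        w = rng.standard_normal(15)
        n = rng.standard_normal(3)
        n /= np.linalg.norm(n)
        expected = np.einsum("ijkl,i,j,k,l->", w15_to_full(w), n, n, n, n)
        assert quartic_form(w, n)[0] == pytest.approx(expected, rel=1e-12)


class TestFit:
    def test_noise_free_recovery_study_scheme(self, scheme51):
        """500 random physiological voxels: both tensors recovered to
        better than 1e-6 relative from the 51-volume acquisition."""
        rng = np.random.default_rng(7)
        d6, w15 = random_tensors(rng, 500)
        sig = forward_signals(scheme51, 500.0, d6, w15)
        fit = fit_volume(sig, scheme51)
        scale_d = np.abs(d6).max()
        scale_w = np.abs(w15).max()
        assert np.abs(fit.d6 - d6).max() / scale_d < 1e-6
        assert np.abs(fit.w15 - w15).max() / scale_w < 1e-6
        np.testing.assert_allclose(fit.s0, 500.0, rtol=1e-8)

    def test_gaussian_limit_zero_kurtosis(self, scheme51):
        """W = 0 with isotropic D collapses to mono-exponential decay:
        every directional kurtosis and every map is exactly zero."""
        d = 1.0e-3
        d6 = np.array([d, d, d, 0, 0, 0])
        sig = forward_signals(scheme51, 300.0, d6[None], np.zeros((1, 15)))
        fit = fit_volume(sig, scheme51)
        for n in scheme51.unique_directions():
            da = apparent_along(fit, n)
            assert da.d_app[0] == pytest.approx(d, rel=1e-7)
            assert abs(da.k_app[0]) < 1e-10
        maps = kurtosis_maps(fit, scheme51)
        for m in (maps.mk, maps.k_axial, maps.k_radial):
            assert abs(m[0]) < 1e-12  # machine-precision zero through the fit
        # map derivation from an exactly-zero kurtosis tensor is exactly zero
        exact = kurtosis_maps(
            KurtosisFit(s0=np.ones(1), d6=d6[None], w15=np.zeros((1, 15))), scheme51
        )
        assert exact.mk[0] == 0.0 and exact.k_axial[0] == 0.0
        assert exact.k_radial[0] == 0.0

    def test_three_point_single_direction_oracle(self, scheme51):
        """Along one gradient direction the noise-free 3-point log-signal
        admits an exact quadratic inversion for (D_app, K_app); the tensor
        fit must agree with it."""
        rng = np.random.default_rng(11)
        d6, w15 = random_tensors(rng, 1)
        sig = forward_signals(scheme51, 800.0, d6, w15)[0]
        fit = fit_voxel(sig, scheme51)
        n = scheme51.unique_directions()[4]
        s0 = 800.0
        sb = {0.0: s0}
        for b in (1000.0, 2000.0):
            sb[b] = float(
                forward_signals(
                    dki.GradientScheme(np.array([0.0, b]), np.vstack([[0, 0, 0], n])),
                    s0, d6, w15,
                )[0, 1]
            )
        a1 = np.log(sb[0.0]) - np.log(sb[1000.0])
        a2 = np.log(sb[0.0]) - np.log(sb[2000.0])
        d_app = (4 * a1 - a2) / 2000.0
        k_app = (1000.0 * d_app - a1) * 6.0 / (1000.0**2 * d_app**2)
        da = apparent_along(fit, n)
        assert da.d_app[0] == pytest.approx(d_app, rel=1e-9)
        assert da.k_app[0] == pytest.approx(k_app, rel=1e-7)

    def test_nonpositive_signal_flagged_not_raised(self, scheme51):
        sig = np.ones((2, 51))
        sig[0, 3] = 0.0
        fit = fit_volume(sig, scheme51)
        assert fit.flags[0] & FLAG_NONPOS_SIGNAL
        assert not (fit.flags[1] & FLAG_NONPOS_SIGNAL)

    def test_eigvals_sorted_descending(self, scheme51):
        rng = np.random.default_rng(5)
        d6, w15 = random_tensors(rng, 20)
        fit = fit_volume(forward_signals(scheme51, 100.0, d6, w15), scheme51)
        assert np.all(np.diff(fit.eigvals, axis=-1) <= 0)
        # eigenvectors orthonormal
        RtR = np.einsum("...ji,...jk->...ik", fit.eigvecs, fit.eigvecs)
        np.testing.assert_allclose(RtR, np.broadcast_to(np.eye(3), RtR.shape), atol=1e-8)


class TestApparentAlong:
    def test_isotropic_d_reads_off_w1111(self, scheme51):
        """Isotropic D forces MD/D_app = 1, so k_app along x equals the
        raw W_xxxx element."""
        d = 0.8e-3
        w15 = isotropic_w15(0.7)
        w15[0] = 1.3  # perturb W_xxxx only
        sig = forward_signals(
            scheme51, 100.0, np.array([[d, d, d, 0, 0, 0]]), w15[None]
        )
        fit = fit_volume(sig, scheme51)
        da = apparent_along(fit, np.array([1.0, 0.0, 0.0]))
        assert da.d_app[0] == pytest.approx(d, rel=1e-9)
        assert da.k_app[0] == pytest.approx(1.3, rel=1e-6)

    def test_antipodal_symmetry(self, scheme51):
        rng = np.random.default_rng(3)
        d6, w15 = random_tensors(rng, 1)
        fit = KurtosisFit(s0=np.ones(1), d6=d6, w15=w15)
        n = rng.standard_normal(3)
        n /= np.linalg.norm(n)
        a = apparent_along(fit, n)
        b = apparent_along(fit, -n)
        assert a.d_app[0] == b.d_app[0]
        assert a.k_app[0] == b.k_app[0]

    def test_principal_direction_matches_axial_map(self, scheme51):
        rng = np.random.default_rng(9)
        d6, w15 = random_tensors(rng, 1)
        fit = fit_volume(forward_signals(scheme51, 200.0, d6, w15), scheme51)
        e1 = fit.eigvecs[0, :, 0]
        da = apparent_along(fit, e1 / np.linalg.norm(e1))
        maps = kurtosis_maps(fit, scheme51, clip_range=(-50, 50))
        assert da.k_app[0] == pytest.approx(maps.k_axial[0], rel=1e-9)


class TestRotateKt:
    def test_identity_rotation_is_noop(self):
        w = isotropic_w15(0.9)
        w[3] = 0.2
        fit = KurtosisFit(
            s0=np.ones(1), d6=np.array([[1.5e-3, 1.0e-3, 0.5e-3, 0, 0, 0]]),
            w15=w[None],
        )
        # axis-aligned D: eigenframe is the lab frame (descending order)
        np.testing.assert_allclose(rotate_kt(fit)[0], w, atol=1e-12)

    def test_axis_swap_moves_w1111(self):
        """D whose largest eigenvalue lies along y: the eigenframe transform
        must carry W_yyyy into the transformed W_1111 slot."""
        w = np.zeros(15)
        w[1] = 2.0  # W_yyyy
        fit = KurtosisFit(
            s0=np.ones(1), d6=np.array([[1.0e-3, 1.5e-3, 0.5e-3, 0, 0, 0]]),
            w15=w[None],
        )
        rotated = rotate_kt(fit)[0]
        assert rotated[0] == pytest.approx(2.0, abs=1e-12)
        assert np.abs(np.delete(rotated, 0)).max() < 1e-12

    def test_eigenframe_kapp_invariance(self):
        """k_app evaluated from (D, W) in the lab frame equals k_app from
        (diag(lambda), rotated W) in the eigenframe, for random voxels and
        20 random directions."""
        rng = np.random.default_rng(21)
        d6, w15 = random_tensors(rng, 5)
        fit = KurtosisFit(s0=np.ones(5), d6=d6, w15=w15)
        what = rotate_kt(fit)
        dirs = rng.standard_normal((20, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        for v in range(5):
            R = fit.eigvecs[v]
            lam6 = np.concatenate([fit.eigvals[v], np.zeros(3)])
            for n in dirs:
                n_eig = R.T @ n
                d_lab = quadratic_form(fit.d6[v], n)[0]
                d_eig = quadratic_form(lam6, n_eig)[0]
                k_lab = fit.md[v] ** 2 / d_lab**2 * quartic_form(fit.w15[v], n)[0]
                k_eig = fit.md[v] ** 2 / d_eig**2 * quartic_form(what[v], n_eig)[0]
                assert k_lab == pytest.approx(k_eig, abs=1e-9)


class TestKurtosisMaps:
    def test_isotropy_collapses_all_metrics(self, scheme51):
        k = 0.75
        d = 1.1e-3
        fit = KurtosisFit(
            s0=np.ones(1), d6=np.array([[d, d, d, 0, 0, 0]]),
            w15=isotropic_w15(k)[None],
        )
        maps = kurtosis_maps(fit, scheme51)
        assert maps.mk[0] == pytest.approx(k, abs=1e-12)
        assert maps.k_axial[0] == pytest.approx(k, abs=1e-12)
        assert maps.k_radial[0] == pytest.approx(k, abs=1e-12)

    def test_prolate_voxel_hand_computed(self):
        """Eigen-kurtoses chosen by hand: Khat_1 = 0.5 along the long axis
        and Khat_2 = Khat_3 = 1.2 across it must come back verbatim as
        axial and radial kurtosis."""
        lam = np.array([1.7e-3, 0.3e-3, 0.3e-3])
        md = lam.mean()
        w = np.zeros(15)
        w[0] = 0.5 * lam[0] ** 2 / md**2
        w[1] = 1.2 * lam[1] ** 2 / md**2
        w[2] = 1.2 * lam[2] ** 2 / md**2
        fit = KurtosisFit(
            s0=np.ones(1), d6=np.array([[lam[0], lam[1], lam[2], 0, 0, 0]]),
            w15=w[None],
        )
        maps = kurtosis_maps(fit, mk_directions="sphere321")
        assert maps.k_axial[0] == pytest.approx(0.5, abs=1e-12)
        assert maps.k_radial[0] == pytest.approx(1.2, abs=1e-12)

    def test_mk_direction_set_insensitivity(self, scheme51):
        """MK from the acquired 25 directions vs a dense 321-point sphere:
        mean absolute difference below 0.05 over random voxels."""
        rng = np.random.default_rng(17)
        d6, w15 = random_tensors(rng, 100)
        fit = KurtosisFit(s0=np.ones(100), d6=d6, w15=w15)
        mk_acq = kurtosis_maps(fit, scheme51, mk_directions="acquired",
                               clip_range=(-50, 50)).mk
        mk_dense = kurtosis_maps(fit, scheme51, mk_directions="sphere321",
                                 clip_range=(-50, 50)).mk
        mad = np.abs(mk_acq - mk_dense).mean()
        assert mad < 0.05

    def test_clipping_sets_flag(self, scheme51):
        fit = KurtosisFit(
            s0=np.ones(1), d6=np.array([[1e-3, 1e-3, 1e-3, 0, 0, 0]]),
            w15=isotropic_w15(25.0)[None],
        )
        maps = kurtosis_maps(fit, scheme51, clip_range=(0.0, 10.0))
        assert maps.mk[0] == 10.0
        assert maps.flags[0] & FLAG_CLIPPED

    def test_rotation_invariance_of_maps(self, scheme51):
        """Jointly rotating the ground-truth tensors and the gradient
        directions leaves MK, axial and radial kurtosis unchanged."""
        rng = np.random.default_rng(29)
        d6, w15 = random_tensors(rng, 3)
        sig = forward_signals(scheme51, 400.0, d6, w15)
        maps0 = kurtosis_maps(fit_volume(sig, scheme51), scheme51)

        R = special_ortho_group.rvs(3, random_state=rng)
        Dm = dki.d6_to_matrix(d6)
        d6r = dki.matrix_to_d6(np.einsum("ia,...ab,jb->...ij", R, Dm, R))
        w15r = full_to_w15(
            np.einsum("ia,jb,kc,ld,...abcd->...ijkl", R, R, R, R, w15_to_full(w15))
        )
        scheme_r = dki.GradientScheme(scheme51.bvals, scheme51.bvecs @ R.T)
        sig_r = forward_signals(scheme_r, 400.0, d6r, w15r)
        maps_r = kurtosis_maps(fit_volume(sig_r, scheme_r), scheme_r)

        np.testing.assert_allclose(maps_r.mk, maps0.mk, atol=1e-9)
        np.testing.assert_allclose(maps_r.k_axial, maps0.k_axial, atol=1e-9)
        np.testing.assert_allclose(maps_r.k_radial, maps0.k_radial, atol=1e-9)
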