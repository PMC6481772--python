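"""Core MNF algebra: covariance, whitening, eigenproblem, selection, transforms."""

import numpy as np
import pytest

from conftest import random_spd
from mnfdenoise.core import (
    band_diagnostics,
    build_transforms,
    compute_covariance,
    forward_transform,
    inverse_reconstruct,
    mnf_eigendecomposition,
    select_bands,
    whiten_covariance,
    CovariancePair,
)
from mnfdenoise import MNF
from mnfdenoise.io import PixelMatrix, cube_to_matrix
from mnfdenoise.metrics import rmse
from mnfdenoise.noise import decompose_noise
from mnfdenoise.synth import SynthConfig, simulate


def _pm(Y, w=None, h=None):
    w = w or Y.shape[0]
    h = h or 1
    return PixelMatrix(Y=Y, width=w, height=h,
                       wavenumbers=np.arange(float(Y.shape[1])))


def _fit(pm, sigma_delta, threshold=5.0, variance_retained=1.0):
    """Standard MNF pieces wired by hand; returns (cov, noise, transform)."""
    cov = compute_covariance(pm)
    noise = decompose_noise(sigma_delta, variance_retained)
    G, lam = mnf_eigendecomposition(whiten_covariance(cov, noise))
    K = select_bands(lam, threshold)
    model = build_transforms(noise, G, lam, K, cov.mean_Y)
    return cov, noise, model


class TestCovariance:
    def test_hand_computed_two_pixels(self):
        cov = compute_covariance(_pm(np.array([[0.0, 0.0], [2.0, 2.0]])))
        np.testing.assert_allclose(cov.mean_Y, [1.0, 1.0])
        np.testing.assert_allclose(cov.sigma_Y, [[2.0, 2.0], [2.0, 2.0]])

    def test_constant_data_zero_covariance(self):
        cov = compute_covariance(_pm(np.full((10, 3), 4.2)))
        np.testing.assert_allclose(cov.sigma_Y, 0.0, atol=1e-12)

    def test_single_pixel_rejected(self):
        with pytest.raises(ValueError):
            compute_covariance(_pm(np.ones((1, 3))))

    def test_additivity_signal_plus_noise(self):
        """Σ_Y ≈ Σ_D + Σ_δ for independent signal and noise at N = 1e5."""
        cfg = SynthConfig(width=400, height=250, bands=15, rank=2,
                          component_snrs=3.0, noise="iid", seed=13)
        cube, truth = simulate(cfg)
        pm = _pm(cube.data.reshape(-1, 15), 400, 250)
        sigma_Y = compute_covariance(pm).sigma_Y
        sigma_D = np.cov(truth.D, rowvar=False)
        expected = sigma_D + truth.sigma_delta_true
        rel = np.linalg.norm(sigma_Y - expected) / np.linalg.norm(expected)
        assert rel < 0.05


class TestWhitening:
    def test_identity_pair(self):
        cov = CovariancePair(sigma_Y=np.eye(4), mean_Y=np.zeros(4), n_pixels=10)
        noise = decompose_noise(np.eye(4), 1.0)
        np.testing.assert_allclose(whiten_covariance(cov, noise), np.eye(4), atol=1e-12)

    def test_scaling_identity(self):
        """Σ_Y = 2 Σ_δ whitens to 2I for any SPD noise covariance."""
        sigma_d = random_spd(np.random.default_rng(7), 12)
        cov = CovariancePair(sigma_Y=2.0 * sigma_d, mean_Y=np.zeros(12), n_pixels=10)
        noise = decompose_noise(sigma_d, 1.0)
        np.testing.assert_allclose(
            whiten_covariance(cov, noise), 2.0 * np.eye(12), atol=1e-8
        )

    def test_against_dense_oracle(self):
        rng = np.random.default_rng(8)
        sigma_y = random_spd(rng, 10)
        sigma_d = random_spd(rng, 10)
        cov = CovariancePair(sigma_Y=sigma_y, mean_Y=np.zeros(10), n_pixels=10)
        noise = decompose_noise(sigma_d, 1.0)
        lam, E = np.linalg.eigh(sigma_d)
        inv_sqrt = np.diag(1.0 / np.sqrt(lam))
        oracle = inv_sqrt @ E.T @ sigma_y @ E @ inv_sqrt
        # oracle uses ascending eigh order; compare spectra, which are
        # basis-order independent
        np.testing.assert_allclose(
            np.linalg.eigvalsh(whiten_covariance(cov, noise)),
            np.linalg.eigvalsh(oracle),
            atol=1e-10,
        )


class TestEigendecomposition:
    def test_diagonal_sorting(self):
        G, lam = mnf_eigendecomposition(np.diag([5.0, 2.0, 9.0]))
        np.testing.assert_allclose(lam, [9.0, 5.0, 2.0])
        assert np.allclose(np.abs(G), np.eye(3)[:, [2, 0, 1]])

    def test_identity_all_ones(self):
        _, lam = mnf_eigendecomposition(np.eye(5))
        np.testing.assert_allclose(lam, 1.0)

    def test_reconstruction_oracle(self):
        A = random_spd(np.random.default_rng(9), 15)
        G, lam = mnf_eigendecomposition(A)
        assert np.linalg.norm((G * lam) @ G.T - A) < 1e-10 * np.linalg.norm(A)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            mnf_eigendecomposition(np.array([[1.0, 1.0], [0.0, 1.0]]))


class TestSelectBands:
    def test_threshold_counting(self):
        lam = np.array([101.0, 10.0, 6.01, 5.99, 1.5])
        assert select_bands(lam, 5.0) == 3

    def test_boundary_inclusive(self):
        assert select_bands(np.array([6.0]), 5.0) == 1

    def test_never_zero_with_warning(self):
        with pytest.warns(UserWarning, match="keeping the top"):
            assert select_bands(np.array([2.0, 1.5, 1.0]), 5.0) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_bands(np.array([]))


class TestTransforms:
    def test_identity_noise_gives_G_columns(self):
        rng = np.random.default_rng(10)
        pm = _pm(rng.normal(size=(50, 6)))
        cov = compute_covariance(pm)
        noise = decompose_noise(np.eye(6), 1.0)
        G, lam = mnf_eigendecomposition(whiten_covariance(cov, noise))
        model = build_transforms(noise, G, lam, 3, cov.mean_Y)
        np.testing.assert_allclose(model.phi_forward, G[:, :3], atol=1e-12)
        np.testing.assert_allclose(model.phi_inverse, G[:, :3], atol=1e-12)

    def test_phi_inverse_transpose_phi_forward_is_identity(self):
        """Φ̃ᵀΦ̂ = I_K: the inversion-free construction is a true inverse pair."""
        rng = np.random.default_rng(11)
        for trial in range(5):
            s = 8
            pm = _pm(rng.normal(size=(60, s)))
            _, _, model = _fit(pm, random_spd(rng, s), threshold=-np.inf)
            np.testing.assert_allclose(
                model.phi_inverse.T @ model.phi_forward, np.eye(model.K), atol=1e-8
            )

    def test_whitening_and_diagonalization_contracts(self):
        """Φ̂ᵀΣ_δΦ̂ = I_K and Φ̂ᵀΣ_YΦ̂ = diag(λ_1..λ_K)."""
        rng = np.random.default_rng(12)
        s = 10
        pm = _pm(rng.normal(size=(200, s)) * 3.0)
        cov, noise, model = _fit(pm, random_spd(rng, s), threshold=-np.inf)
        K = model.K
        np.testing.assert_allclose(
            model.phi_forward.T @ noise.sigma_delta @ model.phi_forward,
            np.eye(K), atol=1e-6,
        )
        np.testing.assert_allclose(
            model.phi_forward.T @ cov.sigma_Y @ model.phi_forward,
            np.diag(model.lambda_mnf[:K]), atol=1e-6,
        )

    def test_full_band_round_trip_identity(self):
        """K = S, m = S reconstructs the input within 1e-8 relative."""
        rng = np.random.default_rng(13)
        s = 12
        pm = _pm(rng.normal(size=(80, s)))
        _, _, model = _fit(pm, random_spd(rng, s), threshold=-np.inf)
        assert model.K == s
        rec = inverse_reconstruct(pm, model)
        assert np.linalg.norm(rec.Y - pm.Y) / np.linalg.norm(pm.Y) < 1e-8
        # and Φ̂ Φ̃ᵀ itself is the identity
        np.testing.assert_allclose(
            model.phi_forward @ model.phi_inverse.T, np.eye(s), atol=1e-8
        )

    def test_K_out_of_range_rejected(self):
        rng = np.random.default_rng(14)
        pm = _pm(rng.normal(size=(30, 4)))
        cov = compute_covariance(pm)
        noise = decompose_noise(np.eye(4), 1.0)
        G, lam = mnf_eigendecomposition(whiten_covariance(cov, noise))
        with pytest.raises(ValueError):
            build_transforms(noise, G, lam, 5, cov.mean_Y)


class TestForwardInverse:
    def test_score_variances_match_lambda(self, small_fit):
        model, res = small_fit
        scores = forward_transform(model.pixels, res.transform)
        var = scores.var(axis=0, ddof=1)
        np.testing.assert_allclose(var, res.lambda_mnf[: res.k_selected], rtol=0.02)

    def test_first_eigenimage_has_highest_empirical_snr(self):
        """With distinct component SNRs, component 1 carries the best SNR."""
        cfg = SynthConfig(width=24, height=24, bands=100, rank=4,
                          component_snrs=[60.0, 30.0, 15.0, 8.0], seed=17)
        cube, truth = simulate(cfg)
        res = MNF(cube, noise=truth.sigma_delta_true).fit()
        phi = res.transform.phi_forward
        sig = (truth.D - truth.D.mean(axis=0)) @ phi
        noi = truth.delta @ phi
        snr = sig.var(axis=0) / noi.var(axis=0)
        assert np.argmax(snr) == 0

    def test_denoising_reduces_error(self, small_sim, small_fit):
        _, cube, truth = small_sim
        _, res = small_fit
        Y = cube.data.reshape(-1, cube.n_bands)
        assert rmse(res.denoised.Y, truth.D) < rmse(Y, truth.D)

    def test_band_count_mismatch_rejected(self, small_fit):
        _, res = small_fit
        bad = _pm(np.zeros((4, 3)))
        with pytest.raises(ValueError):
            forward_transform(bad, res.transform)


class TestOracleEquivalence:
    def test_inversion_free_equals_naive_inverse(self):
        """D̂ = (Y−μ)Φ̂Φ̃ᵀ+μ matches the explicit Y·Φ·R·Φ^{-1} formula.

        The naive route builds the full square Φ = E Λ^{-1/2} G and uses a
        dense matrix inverse; the factorized route never inverts anything.
        """
        rng = np.random.default_rng(20)
        s = 20
        for trial in range(20):
            pm = _pm(rng.normal(size=(100, s)) + rng.normal(size=(1, s)) * 2)
            sigma_d = random_spd(rng, s, cond=30)
            cov = compute_covariance(pm)
            noise = decompose_noise(sigma_d, 1.0)
            G, lam = mnf_eigendecomposition(whiten_covariance(cov, noise))
            K = int(rng.integers(1, s + 1))
            model = build_transforms(noise, G, lam, K, cov.mean_Y)
            fact = inverse_reconstruct(pm, model).Y

            phi_full = noise.whitening_matrix() @ G  # S × S
            R = np.zeros((s, s))
            R[:K, :K] = np.eye(K)
            naive = (pm.Y - cov.mean_Y) @ phi_full @ R @ np.linalg.inv(phi_full) \
                + cov.mean_Y
            assert np.linalg.norm(fact - naive) / np.linalg.norm(naive) < 1e-8


class TestDiagnostics:
    def test_snr_and_noise_fraction_definitions(self):
        lam = np.array([6.0, 2.0, 1.0])
        rng = np.random.default_rng(15)
        pm = _pm(rng.normal(size=(30, 3)))
        cov = compute_covariance(pm)
        noise = decompose_noise(np.eye(3), 1.0)
        model = build_transforms(noise, np.eye(3), lam, 2, cov.mean_Y)
        diag = band_diagnostics(model)
        np.testing.assert_allclose(diag.snr, [5.0, 1.0, 0.0])
        np.testing.assert_allclose(diag.noise_fraction, [1 / 6, 0.5, 1.0])
        assert np.all(np.diff(diag.snr) <= 0)

    def test_eigenimage_shape_and_content(self, small_fit):
        model, res = small_fit
        diag = band_diagnostics(res.transform, model.pixels)
        img = diag.eigenimage(0)
        assert img.shape == (32, 32)
        scores = forward_transform(model.pixels, res.transform)
        np.testing.assert_array_equal(img.ravel(), scores[:, 0])
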