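"""The standard Minimum Noise Fraction transform.

MNF orders linear components of a hyperspectral image by signal-to-noise
ratio rather than by variance.  It is computed here in the
noise-whitening (NAPC) form:

1.  data covariance  Σ_Y = Σ_D + Σ_δ  (signal and noise uncorrelated);
2.  whitening        Σ_W = Λ_δ^{-1/2} Eᵀ Σ_Y E Λ_δ^{-1/2}
    with Σ_δ = E Λ_δ Eᵀ, which turns the noise contribution into the
    identity;
3.  eigendecomposition Σ_W = G Λ_MNF Gᵀ with λ₁ ≥ λ₂ ≥ … , so components
    show decreasing image quality;
4.  per component:  SNR_i = λ_i − 1  and  noise fraction = 1/λ_i.

Band selection applies the Rose criterion — an SNR of at least 5.0 is
needed to distinguish image features with certainty — keeping the top K
components with λ_i − 1 ≥ 5.0.

The forward and inverse transforms are built inversion-free from the
factorization

    Φ̂ = E Λ_δ^{-1/2} G R,      Φ̃ = E Λ_δ^{+1/2} G R,
    D̂ = (Y − μ) Φ̂ Φ̃ᵀ + μ,

where R is the K-column block identity: only diagonal reciprocal square
roots and transposes are needed, never a matrix inverse.  Data are
column-mean-centred before the covariance step and the mean is restored
after reconstruction, so covariance additivity holds for nonzero-mean
signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import PixelMatrix
from .noise import NoiseModel, fix_eigenvector_signs

__all__ = [
    "CovariancePair",
    "MNFTransform",
    "BandDiagnostics",
    "compute_covariance",
    "whiten_covariance",
    "mnf_eigendecomposition",
    "select_bands",
    "build_transforms",
    "forward_transform",
    "inverse_reconstruct",
    "band_diagnostics",
    "ROSE_SNR_THRESHOLD",
]

#: Rose criterion: minimum SNR for an image feature to be distinguishable.
ROSE_SNR_THRESHOLD = 5.0


@dataclass
class CovariancePair:
    """Sample data covariance Σ_Y with the per-band mean and pixel count."""

    sigma_Y: np.ndarray
    mean_Y: np.ndarray
    n_pixels: int


@dataclass
class MNFTransform:
    """A fitted MNF transform.

    ``phi_forward`` (Φ̂, ``S × K``) maps centred spectra into the retained
    MNF bands; ``phi_inverse`` (Φ̃, ``S × K``) maps back.  ``lambda_mnf``
    holds every computed MNF eigenvalue (length ``m`` for the standard
    transform, ``K̂`` for truncated variants), descending; ``K`` is the
    automatically selected band count.
    """

    phi_forward: np.ndarray
    phi_inverse: np.ndarray
    lambda_mnf: np.ndarray
    K: int
    snr_threshold: float
    variant: str
    mean_Y: np.ndarray
    G: np.ndarray
    seed: int | None = None

    @property
    def n_bands(self) -> int:
        return self.phi_forward.shape[0]

    @property
    def R_rank(self) -> int:
        """Rank of the block-identity truncation R (equals K)."""
        return self.K

    @property
    def snr(self) -> np.ndarray:
        """Per-component SNR, λ_i − 1 (non-increasing)."""
        return self.lambda_mnf - 1.0

    @property
    def noise_fraction(self) -> np.ndarray:
        """Per-component noise fraction, 1/λ_i."""
        return 1.0 / self.lambda_mnf


@dataclass
class BandDiagnostics:
    """Per-band SNR / noise-fraction accounting plus eigenimage access."""

    snr: np.ndarray
    noise_fraction: np.ndarray
    lambda_mnf: np.ndarray
    K: int
    _scores: np.ndarray | None = None
    _width: int = 0
    _height: int = 0

    def eigenimage(self, i: int) -> np.ndarray:
        """The ``W × H`` spatial image of MNF component ``i`` (0-based)."""
        if self._scores is None:
            raise ValueError("diagnostics were built without transformed data")
        return self._scores[:, i].reshape(self._width, self._height)


def compute_covariance(pm: PixelMatrix) -> CovariancePair:
    """Per-band mean and unbiased (1/(N−1)) sample covariance of Y."""
    Y = pm.Y
    n = Y.shape[0]
    if n < 2:
        raise ValueError("covariance needs at least 2 pixels")
    mean = Y.mean(axis=0)
    Yc = Y - mean
    sigma = (Yc.T @ Yc) / (n - 1)
    return CovariancePair(sigma_Y=0.5 * (sigma + sigma.T), mean_Y=mean, n_pixels=n)


def whiten_covariance(cov: CovariancePair, noise: NoiseModel) -> np.ndarray:
    """Noise-whitened data covariance Σ_W = Λ^{-1/2} Eᵀ Σ_Y E Λ^{-1/2} (``m × m``).

    If Σ_Y equals Σ_δ exactly and all noise dimensions are retained, the
    result is the identity — the noise contribution has been whitened away.
    """
    if noise.m < 1:
        raise ValueError("noise model retains no dimensions")
    if noise.E.shape[0] != cov.sigma_Y.shape[0]:
        raise ValueError("noise model and covariance have different band counts")
    W = noise.whitening_matrix()  # S × m
    sigma_w = W.T @ cov.sigma_Y @ W
    return 0.5 * (sigma_w + sigma_w.T)


def mnf_eigendecomposition(sigma_W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full eigendecomposition of Σ_W, eigenvalues descending.

    Returns orthonormal ``G`` (columns sign-fixed: largest-magnitude entry
    positive) and ``lambda_mnf`` with λ₁ ≥ λ₂ ≥ …, so components are in
    decreasing image-quality order.
    """
    sigma_W = np.asarray(sigma_W, dtype=float)
    scale = np.linalg.norm(sigma_W)
    if scale > 0 and np.linalg.norm(sigma_W - sigma_W.T) > 1e-8 * scale:
        raise ValueError("whitened covariance is not symmetric")
    lam, G = np.linalg.eigh(0.5 * (sigma_W + sigma_W.T))
    order = np.argsort(-lam, kind="stable")  # descending, stable on ties
    return fix_eigenvector_signs(G[:, order]), np.maximum(lam[order], 0.0)


def select_bands(lambda_mnf: np.ndarray, snr_threshold: float = ROSE_SNR_THRESHOLD) -> int:
    """Automatic band selection by the Rose criterion.

    Keeps the top K components whose SNR = λ_i − 1 meets the threshold
    (inclusive: "at least 5.0").  If no component qualifies, K = 1 is
    returned with a warning — an empty basis would reconstruct nothing.
    """
    lam = np.asarray(lambda_mnf, dtype=float)
    if lam.size == 0:
        raise ValueError("empty eigenvalue vector")
    if np.any(np.diff(lam) > 1e-9 * max(abs(lam[0]), 1.0)):
        raise ValueError("lambda_mnf must be sorted descending")
    K = int(np.sum(lam - 1.0 >= snr_threshold))
    if K == 0:
        warnings.warn(
            f"no MNF component reaches SNR >= {snr_threshold}; keeping the top "
            "component only",
            stacklevel=2,
        )
        K = 1
    return K


def build_transforms(
    noise: NoiseModel,
    G: np.ndarray,
    lambda_mnf: np.ndarray,
    K: int,
    mean_Y: np.ndarray,
    variant: str = "standard",
    snr_threshold: float = ROSE_SNR_THRESHOLD,
    seed: int | None = None,
) -> MNFTransform:
    """Materialize Φ̂ = E Λ^{-1/2} G R and Φ̃ = E Λ^{+1/2} G R (``S × K``).

    Only diagonal reciprocal square roots and transposes are used — no
    matrix inversion.  With identity noise, Φ̂ = Φ̃ = G[:, :K].
    """
    if not (1 <= K <= G.shape[1]):
        raise ValueError(f"K={K} out of range [1, {G.shape[1]}]")
    GK = G[:, :K]
    phi_forward = noise.whitening_matrix() @ GK
    phi_inverse = noise.unwhitening_matrix() @ GK
    return MNFTransform(
        phi_forward=phi_forward,
        phi_inverse=phi_inverse,
        lambda_mnf=np.asarray(lambda_mnf, dtype=float),
        K=K,
        snr_threshold=snr_threshold,
        variant=variant,
        mean_Y=np.asarray(mean_Y, dtype=float),
        G=G,
        seed=seed,
    )


def forward_transform(pm: PixelMatrix, model: MNFTransform) -> np.ndarray:
    """Project centred data into the retained MNF bands: (Y − μ) Φ̂ (``N × K``).

    Column ``i`` is the i-th eigenimage (flattened), in decreasing SNR
    order; at large N its variance approaches λ_i.
    """
    if pm.n_bands != model.n_bands:
        raise ValueError(
            f"data has {pm.n_bands} bands, model expects {model.n_bands}"
        )
    return (pm.Y - model.mean_Y) @ model.phi_forward


def inverse_reconstruct(pm: PixelMatrix, model: MNFTransform) -> PixelMatrix:
    """Denoise: D̂ = (Y − μ) Φ̂ Φ̃ᵀ + μ, same shape as the input.

    With all bands kept (K = S, all noise dimensions retained) this is the
    identity up to floating point: Φ̂ Φ̃ᵀ = E Λ^{-1/2} G Gᵀ Λ^{1/2} Eᵀ = I.
    """
    scores = forward_transform(pm, model)
    D_hat = scores @ model.phi_inverse.T + model.mean_Y
    return PixelMatrix(
        Y=D_hat, width=pm.width, height=pm.height, wavenumbers=pm.wavenumbers
    )


def band_diagnostics(
    model: MNFTransform, pm: PixelMatrix | None = None
) -> BandDiagnostics:
    """SNR (λ−1) and noise fraction (1/λ) per component; eigenimages if data given."""
    scores = None
    w = h = 0
    if pm is not None:
        scores = forward_transform(pm, model)
        w, h = pm.width, pm.height
    return BandDiagnostics(
        snr=model.snr,
        noise_fraction=model.noise_fraction,
        lambda_mnf=model.lambda_mnf,
        K=model.K,
        _scores=scores,
        _width=w,
        _height=h,
    )
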