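"""Noise covariance estimation and its truncated eigendecomposition.

MNF needs the band-noise covariance Σ_δ.  When it is not known, the
classical shift-difference estimator is used: for spatially smooth scenes
the difference of adjacent pixel spectra cancels the signal and doubles
the noise, so

    Σ̂_δ = Cov(y_p − y_q) / 2

over all spatially adjacent pixel pairs (p, q) along one direction.

Whitening uses the spectral decomposition Σ_δ = E Λ_δ Eᵀ.  Because
Λ_δ^{-1/2} explodes on near-null noise directions, only the leading
eigenvectors covering a fixed fraction of the noise variance (default
99%) are retained, with an absolute floor of 1e-12·λ_max as a numerical
backstop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PixelMatrix

__all__ = ["NoiseModel", "estimate_noise_shift_difference", "decompose_noise"]

#: eigenvalues below this multiple of λ_max are dropped before Λ^{-1/2}
EIGENVALUE_FLOOR = 1e-12


@dataclass
class NoiseModel:
    """Σ_δ together with its retained eigendecomposition.

    Attributes
    ----------
    sigma_delta
        The full ``S × S`` symmetric noise covariance.
    E
        ``S × m`` orthonormal eigenvectors retained for whitening.
    lambda_delta
        Length-``m`` positive eigenvalues (diagonal of Λ_δ), descending.
    variance_retained
        Fraction of tr(Σ_δ) the retained pairs were required to cover.
    estimator_tag
        Provenance: ``"shift_difference"``, ``"provided"`` or ``"truth"``.
    """

    sigma_delta: np.ndarray
    E: np.ndarray
    lambda_delta: np.ndarray
    variance_retained: float
    estimator_tag: str = "provided"

    def __post_init__(self) -> None:
        if np.any(self.lambda_delta <= 0):
            raise ValueError("retained noise eigenvalues must be strictly positive")
        if np.any(np.diff(self.lambda_delta) > 0):
            raise ValueError("noise eigenvalues must be sorted descending")

    @property
    def m(self) -> int:
        """Number of retained noise dimensions."""
        return self.lambda_delta.size

    def whitening_matrix(self) -> np.ndarray:
        """``E Λ_δ^{-1/2}`` (``S × m``); right-multiplying data by it whitens the noise."""
        return self.E * (1.0 / np.sqrt(self.lambda_delta))

    def unwhitening_matrix(self) -> np.ndarray:
        """``E Λ_δ^{+1/2}`` (``S × m``), the transpose-inverse of the whitener."""
        return self.E * np.sqrt(self.lambda_delta)


def fix_eigenvector_signs(V: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (in place safe copy).

    Eigenvectors are defined up to sign; fixing it makes transforms
    reproducible across BLAS implementations.
    """
    V = V.copy()
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def estimate_noise_shift_difference(
    pm: PixelMatrix, direction: str = "horizontal"
) -> np.ndarray:
    """Shift-difference estimate of Σ_δ (``S × S``, symmetric).

    ``direction="horizontal"`` differences spatially adjacent columns,
    ``"vertical"`` adjacent rows.  The differences are mean-centred and
    their covariance halved (each difference carries two independent
    noise draws).

    Raises
    ------
    ValueError
        If the image has fewer than 2 pixels along the chosen direction.
    """
    cube = pm.Y.reshape(pm.width, pm.height, pm.n_bands)
    if direction == "horizontal":
        if pm.height < 2:
            raise ValueError("horizontal shift-difference needs >= 2 columns")
        diffs = cube[:, 1:, :] - cube[:, :-1, :]
    elif direction == "vertical":
        if pm.width < 2:
            raise ValueError("vertical shift-difference needs >= 2 rows")
        diffs = cube[1:, :, :] - cube[:-1, :, :]
    else:
        raise ValueError("direction must be 'horizontal' or 'vertical'")
    d = diffs.reshape(-1, pm.n_bands)
    d = d - d.mean(axis=0)
    denom = max(d.shape[0] - 1, 1)
    sigma = (d.T @ d) / (2.0 * denom)
    return 0.5 * (sigma + sigma.T)


def decompose_noise(
    sigma_delta: np.ndarray,
    variance_retained: float = 0.99,
    estimator_tag: str = "provided",
) -> NoiseModel:
    """Eigendecompose Σ_δ and retain the leading variance fraction.

    The retained count ``m`` is the smallest number of descending
    eigenvalues whose cumulative sum reaches ``variance_retained`` of the
    total; eigenvalues below 1e-12·λ_max are dropped regardless.

    Raises
    ------
    ValueError
        If the matrix is non-symmetric beyond 1e-10 relative tolerance,
        not positive semidefinite (beyond −1e-10·trace), or all zero
        (noiseless data needs no denoising).
    """
    sigma_delta = np.asarray(sigma_delta, dtype=float)
    if sigma_delta.ndim != 2 or sigma_delta.shape[0] != sigma_delta.shape[1]:
        raise ValueError("sigma_delta must be square")
    scale = np.linalg.norm(sigma_delta)
    if scale == 0:
        raise ValueError("noise covariance is identically zero")
    if np.linalg.norm(sigma_delta - sigma_delta.T) > 1e-10 * scale:
        raise ValueError("noise covariance is not symmetric")
    if not (0 < variance_retained <= 1):
        raise ValueError("variance_retained must be in (0, 1]")
    sigma_delta = 0.5 * (sigma_delta + sigma_delta.T)

    lam, V = np.linalg.eigh(sigma_delta)
    order = np.argsort(-lam, kind="stable")  # descending, stable on ties
    lam, V = lam[order], V[:, order]
    trace = lam.sum()
    if lam[0] <= 0 or trace <= 0:
        raise ValueError("noise covariance has no positive eigenvalues")
    if lam[-1] < -1e-10 * trace:
        raise ValueError("noise covariance is not positive semidefinite")

    cumulative = np.cumsum(lam)
    m = int(np.searchsorted(cumulative, variance_retained * trace - 1e-12 * trace) + 1)
    # numerical backstop: never keep near-null directions
    floor = EIGENVALUE_FLOOR * lam[0]
    m = min(m, int(np.sum(lam > floor)))
    m = max(m, 1)

    return NoiseModel(
        sigma_delta=sigma_delta,
        E=fix_eigenvector_signs(V[:, :m]),
        lambda_delta=lam[:m].copy(),
        variance_retained=variance_retained,
        estimator_tag=estimator_tag,
    )
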