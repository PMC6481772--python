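"""Model / Results interface to MNF denoising.

The :class:`MNF` class is constructed from data (a cube, a pixel matrix,
or a file) plus a noise specification, and :meth:`MNF.fit` returns an
:class:`MNFResults` carrying the fitted transform, the eigenvalue /
SNR spectrum, the automatically selected band count and convenience
methods for reconstruction, eigenimages, quality metrics and a text
summary::

    from mnfdenoise import MNF, SynthConfig, simulate

    cube, truth = simulate(SynthConfig(seed=1))
    res = MNF(cube, noise=truth.sigma_delta_true).fit()
    print(res.summary())
    denoised = res.reconstruct_cube()
"""

from __future__ import annotations

import numpy as np

from . import io as _io
from .core import ROSE_SNR_THRESHOLD, MNFTransform, band_diagnostics, forward_transform
from .io import HSICube, PixelMatrix, cube_to_matrix, matrix_to_cube
from .metrics import MNIResult, mni_per_band, rmse
from .noise import NoiseModel, decompose_noise, estimate_noise_shift_difference
from .synth import SyntheticTruth
from .variants import MNF_METHODS, VariantConfig

__all__ = ["MNF", "MNFResults"]


class MNF:
    """Minimum Noise Fraction denoising model.

    Parameters
    ----------
    data
        The noisy observations: an :class:`HSICube` or a
        :class:`PixelMatrix`.
    noise
        How to obtain Σ_δ: ``"shift_difference"`` (estimate from the data
        itself, the default), a ready :class:`NoiseModel`, an ``S × S``
        covariance array, or a :class:`SyntheticTruth` (uses the true
        simulated covariance — for validation runs).
    snr_threshold
        Rose-criterion SNR threshold for automatic band selection
        (default 5.0).
    variance_retained
        Fraction of noise variance the whitening basis must cover
        (default 0.99).
    noise_direction
        Shift direction for the shift-difference estimator.
    """

    def __init__(
        self,
        data: HSICube | PixelMatrix,
        noise: str | NoiseModel | SyntheticTruth | np.ndarray = "shift_difference",
        *,
        snr_threshold: float = ROSE_SNR_THRESHOLD,
        variance_retained: float = 0.99,
        noise_direction: str = "horizontal",
    ) -> None:
        if isinstance(data, HSICube):
            self.cube: HSICube | None = data
            self.pixels = cube_to_matrix(data)
        elif isinstance(data, PixelMatrix):
            self.cube = None
            self.pixels = data
        else:
            raise TypeError("data must be an HSICube or a PixelMatrix")
        self.snr_threshold = float(snr_threshold)
        self.variance_retained = float(variance_retained)
        self.noise_model = self._resolve_noise(noise, noise_direction)

    @classmethod
    def from_envi(cls, header_path: str, **kwargs) -> "MNF":
        return cls(_io.read_envi(header_path), **kwargs)

    @classmethod
    def from_hdf5(cls, path: str, **kwargs) -> "MNF":
        return cls(_io.read_hdf5(path), **kwargs)

    def _resolve_noise(self, noise, direction: str) -> NoiseModel:
        if isinstance(noise, NoiseModel):
            return noise
        if isinstance(noise, SyntheticTruth):
            return decompose_noise(
                noise.sigma_delta_true, self.variance_retained, estimator_tag="truth"
            )
        if isinstance(noise, str):
            if noise not in ("shift_difference", "shift-diff"):
                raise ValueError(f"unknown noise estimator {noise!r}")
            sigma = estimate_noise_shift_difference(self.pixels, direction)
            return decompose_noise(
                sigma, self.variance_retained, estimator_tag="shift_difference"
            )
        sigma = np.asarray(noise, dtype=float)
        return decompose_noise(sigma, self.variance_retained, estimator_tag="provided")

    def fit(
        self,
        method: str = "standard",
        *,
        khat_fraction: float = 0.03,
        epsilon: float = 0.1,
        oversampling: int = 10,
        depth: int = 4,
        seed: int = 0,
    ) -> "MNFResults":
        """Fit the transform and denoise.

        ``method`` is one of ``"standard"``, ``"fast"``, ``"approx"``,
        ``"rand"``; the keyword arguments parameterize the truncated /
        randomized variants and are ignored by the exact ones.
        """
        if method not in MNF_METHODS:
            raise ValueError(
                f"unknown method {method!r}; choose from {sorted(MNF_METHODS)}"
            )
        if method in ("approx", "rand"):
            cfg = VariantConfig(
                khat_fraction=khat_fraction,
                epsilon=epsilon,
                oversampling=oversampling,
                depth=depth,
                seed=seed,
            )
            transform, denoised = MNF_METHODS[method](
                self.pixels, self.noise_model, self.snr_threshold, cfg
            )
        else:
            transform, denoised = MNF_METHODS[method](
                self.pixels, self.noise_model, self.snr_threshold
            )
        return MNFResults(self, transform, denoised)


class MNFResults:
    """Results of a fitted MNF transform.

    Attributes
    ----------
    transform
        The fitted :class:`MNFTransform` (Φ̂, Φ̃, λ, K, variant).
    denoised
        The denoised :class:`PixelMatrix` D̂ of the model's own data.
    """

    def __init__(self, model: MNF, transform: MNFTransform, denoised: PixelMatrix):
        self.model = model
        self.transform = transform
        self.denoised = denoised

    # -- estimates -----------------------------------------------------
    @property
    def k_selected(self) -> int:
        """Automatically selected number of MNF bands."""
        return self.transform.K

    @property
    def lambda_mnf(self) -> np.ndarray:
        return self.transform.lambda_mnf

    @property
    def snr(self) -> np.ndarray:
        """Per-component SNR estimates, λ − 1."""
        return self.transform.snr

    @property
    def noise_fraction(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return self.transform.noise_fraction

    @property
    def variant(self) -> str:
        return self.transform.variant

    # -- application ---------------------------------------------------
    def scores(self, data: PixelMatrix | HSICube | None = None) -> np.ndarray:
        """MNF-space representation (N × K) of ``data`` (default: own data)."""
        pm = self._coerce(data)
        return forward_transform(pm, self.transform)

    def reconstruct(self, data: PixelMatrix | HSICube | None = None) -> PixelMatrix:
        """Denoised pixel matrix for ``data`` (default: the fitted one)."""
        if data is None:
            return self.denoised
        pm = self._coerce(data)
        scores = forward_transform(pm, self.transform)
        return PixelMatrix(
            Y=scores @ self.transform.phi_inverse.T + self.transform.mean_Y,
            width=pm.width,
            height=pm.height,
            wavenumbers=pm.wavenumbers,
        )

    def reconstruct_cube(self) -> HSICube:
        """The denoised cube (W × H × S)."""
        return matrix_to_cube(self.denoised, metadata={"description": "MNF denoised"})

    def eigenimage(self, i: int) -> np.ndarray:
        """W × H image of MNF component ``i`` (0-based, decreasing SNR)."""
        diag = band_diagnostics(self.transform, self.model.pixels)
        return diag.eigenimage(i)

    def _coerce(self, data) -> PixelMatrix:
        if data is None:
            return self.model.pixels
        if isinstance(data, HSICube):
            return cube_to_matrix(data)
        return data

    # -- quality -------------------------------------------------------
    def mni(self, window: int = 11) -> MNIResult:
        """No-reference MNI score per band (needs cube-shaped data)."""
        noisy = matrix_to_cube(self.model.pixels)
        return mni_per_band(noisy, matrix_to_cube(self.denoised), window=window)

    def rmse_to_input(self) -> float:
        """RMSE between the denoised output and the noisy input."""
        return rmse(self.model.pixels, self.denoised)

    # -- reporting -----------------------------------------------------
    def summary(self, top: int = 10) -> str:
        """Human-readable fit report (variant, dimensions, K, top SNRs)."""
        t = self.transform
        nm = self.model.noise_model
        lines = [
            "Minimum Noise Fraction results",
            "=" * 46,
            f"variant:              {t.variant}",
            f"pixels (N):           {self.model.pixels.n_pixels}",
            f"spectral bands (S):   {t.n_bands}",
            f"noise estimator:      {nm.estimator_tag}",
            f"noise dims kept (m):  {nm.m}  (>= {nm.variance_retained:.0%} variance)",
            f"eigenvalues computed: {t.lambda_mnf.size}",
            f"SNR threshold (Rose): {t.snr_threshold:g}",
            f"selected bands (K):   {t.K}",
            f"compression (S/K):    {t.n_bands / t.K:.1f}x",
            "-" * 46,
            " band        lambda           SNR   kept",
        ]
        for i in range(min(top, t.lambda_mnf.size)):
            kept = "yes" if i < t.K else "no"
            lines.append(
                f"{i + 1:5d}  {t.lambda_mnf[i]:12.4f}  {t.lambda_mnf[i] - 1:12.4f}   {kept}"
            )
        if t.lambda_mnf.size > top:
            lines.append(f"  ...  ({t.lambda_mnf.size - top} more components)")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MNFResults variant={self.variant!r} K={self.k_selected} "
            f"S={self.transform.n_bands}>"
        )
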