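"""Denoising quality: MNI (no-reference), SSIM maps, RMSE, empirical SNR.

The Method Noise Image (MNI) score judges a denoiser without ground
truth.  For each spectral band it compares two local structural
similarity (SSIM) maps against the noisy band image: one with the
*method noise* (noisy − denoised, which should look like pure noise) and
one with the denoised image (which should retain all structure).  The
MNI value of the band is the Pearson correlation of the two maps over
all pixels; lower values indicate better denoising with preserved
structure.  On FTIR tissue images this produces the characteristic
profile of low MNI across the fingerprint region (900–1800 cm⁻¹) and
high MNI in the IR-silent region where bands carry mostly noise.

MNI is *not* symmetric in (noisy, denoised); argument order matters.
Bands where either SSIM map is constant (e.g. a perfect pass-through
denoiser making the method noise identically zero) have an undefined
correlation and are flagged rather than coerced to a number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .io import HSICube, PixelMatrix
from .synth import SyntheticTruth

__all__ = [
    "MNIResult",
    "method_noise",
    "ssim_map",
    "mni_per_band",
    "rmse",
    "empirical_snr",
]


@dataclass
class MNIResult:
    """Per-band MNI values with their defined-ness flags.

    ``mni[i]`` is NaN wherever ``defined[i]`` is False.  ``ssim_maps(i)``
    recomputes the pair of W×H SSIM maps for band ``i`` on demand (noisy
    vs method noise, noisy vs denoised).
    """

    mni: np.ndarray
    defined: np.ndarray
    wavenumbers: np.ndarray
    window: int
    _noisy: HSICube | None = None
    _denoised: HSICube | None = None

    def ssim_maps(self, band: int) -> tuple[np.ndarray, np.ndarray]:
        if self._noisy is None or self._denoised is None:
            raise ValueError("source cubes were not retained")
        a = self._noisy.band(band)
        b = self._denoised.band(band)
        rng_ = float(a.max() - a.min()) or 1.0
        return (
            ssim_map(a, a - b, self.window, rng_),
            ssim_map(a, b, self.window, rng_),
        )


def method_noise(noisy: PixelMatrix, denoised: PixelMatrix) -> PixelMatrix:
    """The residual the denoiser removed: noisy − denoised, elementwise."""
    if noisy.Y.shape != denoised.Y.shape:
        raise ValueError("noisy and denoised shapes differ")
    return PixelMatrix(
        Y=noisy.Y - denoised.Y,
        width=noisy.width,
        height=noisy.height,
        wavenumbers=noisy.wavenumbers,
    )


def ssim_map(
    image_a: np.ndarray,
    image_b: np.ndarray,
    window: int = 11,
    dynamic_range: float | None = None,
) -> np.ndarray:
    """Local SSIM map between two equally shaped spatial images.

    Gaussian-weighted windows (σ = 1.5) with the standard stabilizers
    C1 = (0.01·L)², C2 = (0.03·L)², L = ``dynamic_range`` (defaulting to
    the joint max−min of the two images).  Values lie in [−1, 1].
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > min(a.shape):
        raise ValueError("window larger than image")
    if dynamic_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        dynamic_range = float(hi - lo) or 1.0
    _, smap = structural_similarity(
        a,
        b,
        win_size=window,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        data_range=dynamic_range,
        full=True,
    )
    return smap


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson r, or None when either input has (numerically) zero variance."""
    x = x.ravel()
    y = y.ravel()
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx <= 1e-12 * max(np.abs(x).max(), 1.0) * np.sqrt(x.size) or \
       sy <= 1e-12 * max(np.abs(y).max(), 1.0) * np.sqrt(y.size):
        return None
    return float((xc @ yc) / (sx * sy))


def mni_per_band(
    noisy: HSICube, denoised: HSICube, window: int = 11
) -> MNIResult:
    """Method-noise-image score for every spectral band.

    For band i: MNI_i = corr( SSIM(noisy_i, noisy_i − denoised_i),
    SSIM(noisy_i, denoised_i) ).  Both maps use the noisy band's
    dynamic range.  Bands with a constant SSIM map are flagged
    undefined (NaN).
    """
    if noisy.shape != denoised.shape:
        raise ValueError("cube shapes differ")
    s = noisy.n_bands
    mni = np.full(s, np.nan)
    defined = np.zeros(s, dtype=bool)
    for i in range(s):
        a = noisy.band(i)
        b = denoised.band(i)
        rng_ = float(a.max() - a.min()) or 1.0
        map_noise = ssim_map(a, a - b, window, rng_)
        map_den = ssim_map(a, b, window, rng_)
        r = _pearson(map_noise, map_den)
        if r is not None:
            mni[i] = r
            defined[i] = True
    return MNIResult(
        mni=mni,
        defined=defined,
        wavenumbers=noisy.wavenumbers,
        window=window,
        _noisy=noisy,
        _denoised=denoised,
    )


def rmse(a: PixelMatrix | np.ndarray, b: PixelMatrix | np.ndarray) -> float:
    """Root mean square difference over all entries."""
    A = a.Y if isinstance(a, PixelMatrix) else np.asarray(a)
    B = b.Y if isinstance(b, PixelMatrix) else np.asarray(b)
    if A.shape != B.shape:
        raise ValueError("shapes differ")
    return float(np.sqrt(np.mean((A - B) ** 2)))


def empirical_snr(truth: SyntheticTruth, denoised: PixelMatrix | np.ndarray) -> float:
    """Realized SNR of a reconstruction: Var(D) / Var(D̂ − D), pooled.

    Returns ``inf`` for an exact reconstruction (zero residual variance).
    """
    D_hat = denoised.Y if isinstance(denoised, PixelMatrix) else np.asarray(denoised)
    if D_hat.shape != truth.D.shape:
        raise ValueError("shapes differ")
    signal_var = float(np.var(truth.D))
    resid_var = float(np.var(D_hat - truth.D))
    if resid_var == 0.0:
        return float("inf")
    return signal_var / resid_var
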