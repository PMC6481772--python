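"""Synthetic FTIR-like hyperspectral cubes with known ground truth.

The data model is the additive one the MNF transform assumes: each pixel
spectrum is a noiseless signal plus zero-mean Gaussian noise,

    y_j = d_j + δ_j,

where the signal matrix ``D`` is low-rank — a linear mixture of ``r``
smooth endmember spectra (sums of Gaussian peaks over a wavenumber axis)
weighted by spatially smooth abundance maps — and the noise is independent
across pixels with a known band covariance Σ_δ (iid, AR(1) band-correlated
or diagonal heteroscedastic).

Because the denoiser's band selection operates on MNF-component SNR
(signal variance over noise variance *after* noise whitening), the
generator calibrates the signal in whitened coordinates: the centred
signal is whitened with Σ_δ^{-1/2}, its singular values are rescaled so
that each of the ``r`` components attains exactly its requested SNR, and
the result is mapped back.  The emitted :class:`SyntheticTruth` therefore
has per-component SNRs that are exact with respect to the realized sample
covariance of ``D`` and the true Σ_δ.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so spectra, abundances and noise
are each independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import HSICube, PixelMatrix

__all__ = [
    "SynthConfig",
    "SyntheticTruth",
    "generate_spectra",
    "generate_abundances",
    "assemble_cube",
    "simulate",
]

_NOISE_FAMILIES = ("iid", "ar1", "diag")


@dataclass
class SynthConfig:
    """Parameters of the synthetic cube generator.

    Parameters
    ----------
    width, height
        Spatial dimensions (rows, columns).
    bands
        Number of spectral channels ``S``.
    rank
        True signal rank ``r`` (number of independent spectral
        components); must satisfy ``r < S`` and ``r <= min(N, S)``.
    wn_min, wn_max
        Wavenumber range in cm⁻¹ (default 900–3800, the mid-IR span of a
        tissue FTIR measurement).
    component_snrs
        Per-MNF-component SNR targets — a scalar (shared by all ``r``
        components), a length-``r`` sequence, or ``None`` to skip
        calibration and leave the raw mixture scale.
    peak_range
        Sub-range of the wavenumber axis inside which endmember peaks are
        placed (default: the full axis).  Restricting it to e.g.
        (950, 1750) emulates a fingerprint region with structured signal
        next to an IR-silent region carrying pure noise.
    baseline
        Constant absorbance offset added to every pixel spectrum
        (emulates the instrument baseline; with a nonzero baseline the
        signal matrix gains one constant rank on top of the mixing rank).
    noise
        Covariance family: ``"iid"`` (σ²·I), ``"ar1"`` (band-correlated,
        Σ_ij = σ²·ρ^|i−j|) or ``"diag"`` (per-band variances).
    noise_sigma
        Base noise standard deviation σ (0 allowed: noiseless cube).
    rho
        AR(1) band correlation, ``0 <= rho < 1``.
    band_variances
        Per-band noise variances for the ``"diag"`` family.
    seed
        Master seed; every operation derives its own stream from it.
    """

    width: int = 64
    height: int = 64
    bands: int = 200
    rank: int = 5
    wn_min: float = 900.0
    wn_max: float = 3800.0
    component_snrs: float | tuple | list | np.ndarray | None = 20.0
    peak_range: tuple[float, float] | None = None
    baseline: float = 0.0
    noise: str = "iid"
    noise_sigma: float = 1.0
    rho: float = 0.9
    band_variances: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.width * self.height
        if not (1 <= self.rank < self.bands and self.rank <= min(n, self.bands)):
            raise ValueError(
                f"rank must satisfy 1 <= r < S and r <= min(N, S); "
                f"got r={self.rank}, S={self.bands}, N={n}"
            )
        if self.noise not in _NOISE_FAMILIES:
            raise ValueError(f"noise family must be one of {_NOISE_FAMILIES}")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.component_snrs is not None:
            snrs = np.broadcast_to(
                np.asarray(self.component_snrs, dtype=float), (self.rank,)
            )
            if np.any(snrs <= 0):
                raise ValueError("component SNR targets must be positive")

    @property
    def n_pixels(self) -> int:
        return self.width * self.height

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.linspace(self.wn_min, self.wn_max, self.bands)

    def snr_targets(self) -> np.ndarray | None:
        if self.component_snrs is None:
            return None
        return np.broadcast_to(
            np.asarray(self.component_snrs, dtype=float), (self.rank,)
        ).copy()

    def child_rng(self, label: str) -> np.random.Generator:
        """A reproducible stream for one generator stage.

        Streams for distinct labels are independent; the same
        (seed, label) pair always yields the same stream.
        """
        idx = {"spectra": 0, "abundances": 1, "noise": 2}[label]
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(3)[idx])


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic cube.

    ``Y = D + delta`` holds bit-exactly for the emitted cube's pixel
    matrix; ``D`` has matrix rank exactly ``rank``; ``sigma_delta_true``
    is the population noise covariance (symmetric positive definite for
    ``noise_sigma > 0``, zero for a noiseless cube).
    """

    D: np.ndarray
    delta: np.ndarray
    sigma_delta_true: np.ndarray
    rank: int
    component_snrs: np.ndarray | None
    width: int = 0
    height: int = 0
    wavenumbers: np.ndarray | None = None

    def signal_matrix(self) -> PixelMatrix:
        return PixelMatrix(
            Y=self.D, width=self.width, height=self.height, wavenumbers=self.wavenumbers
        )


def _gaussian_peaks(wn: np.ndarray, centers, widths, heights) -> np.ndarray:
    spec = np.zeros_like(wn)
    for c, w, h in zip(centers, widths, heights):
        spec += h * np.exp(-0.5 * ((wn - c) / w) ** 2)
    return spec


def generate_spectra(config: SynthConfig, max_retries: int = 50) -> np.ndarray:
    """Draw ``r`` smooth nonnegative endmember spectra (``r × S``).

    Each endmember is a sum of 3–8 Gaussian peaks with widths 10–60 cm⁻¹
    placed inside the configured wavenumber range.  The stack is
    guaranteed numerically independent (smallest singular value above
    1e-6 of the largest); otherwise the draw is repeated up to
    ``max_retries`` times before raising.
    """
    rng = config.child_rng("spectra")
    wn = config.wavenumbers
    r = config.rank
    lo, hi = config.peak_range or (config.wn_min, config.wn_max)
    for _ in range(max_retries):
        stack = np.empty((r, config.bands))
        for i in range(r):
            n_peaks = rng.integers(3, 9)
            centers = rng.uniform(lo, hi, n_peaks)
            widths = rng.uniform(10.0, 60.0, n_peaks)
            heights = rng.uniform(0.2, 1.0, n_peaks)
            stack[i] = _gaussian_peaks(wn, centers, widths, heights)
        sv = np.linalg.svd(stack, compute_uv=False)
        if sv[-1] > 1e-6 * sv[0]:
            return stack
    raise RuntimeError(
        f"could not draw {r} numerically independent endmembers in "
        f"{max_retries} attempts (rank too large for {config.bands} bands?)"
    )


def generate_abundances(config: SynthConfig, constant: bool = False) -> np.ndarray:
    """Spatially smooth nonnegative abundance maps (``N × r``).

    Maps are low-frequency Gaussian random fields: white noise blurred
    with a Gaussian kernel (σ = max(2, min(W, H)/8) pixels), shifted to be
    nonnegative.  With ``constant=True`` every map is a constant field
    (useful for noise-estimator tests on signal-free scenes).
    """
    w, h, r = config.width, config.height, config.rank
    if constant:
        return np.ones((w * h, r))
    rng = config.child_rng("abundances")
    sigma = max(2.0, min(w, h) / 8.0)
    maps = np.empty((w * h, r))
    for i in range(r):
        f = gaussian_filter(rng.standard_normal((w, h)), sigma=sigma, mode="reflect")
        f = f - f.min() + 0.05 * (f.std() + 1e-12)
        maps[:, i] = f.ravel()
    return maps


def build_noise_covariance(config: SynthConfig) -> np.ndarray:
    """The population Σ_δ of the configured noise family (``S × S``)."""
    s2 = config.noise_sigma**2
    if config.noise == "iid":
        return s2 * np.eye(config.bands)
    if config.noise == "ar1":
        idx = np.arange(config.bands)
        return s2 * config.rho ** np.abs(idx[:, None] - idx[None, :])
    if config.band_variances is None:
        raise ValueError("'diag' noise family needs band_variances")
    v = np.asarray(config.band_variances, dtype=float)
    if v.shape != (config.bands,) or np.any(v <= 0):
        raise ValueError("band_variances must be length-S and positive")
    return np.diag(s2 * v)


def _calibrate_signal(
    D: np.ndarray, sigma_delta: np.ndarray, snr_targets: np.ndarray
) -> np.ndarray:
    """Rescale the signal so each MNF component hits its SNR target.

    Works in noise-whitened coordinates: with Σ_δ = E Λ Eᵀ, the whitened
    centred signal ``D_c E Λ^{-1/2}`` has sample-covariance eigenvalues
    equal to the per-component SNRs; setting its singular values to
    ``sqrt(snr_i (N-1))`` makes them exactly the targets.
    """
    n, _ = D.shape
    r = snr_targets.size
    mu = D.mean(axis=0)
    Dc = D - mu
    lam, E = np.linalg.eigh(sigma_delta)
    if np.any(lam <= 0):
        raise ValueError("noise covariance must be positive definite to set SNR targets")
    whiten = E * (1.0 / np.sqrt(lam))  # E Λ^{-1/2}
    unwhiten = (E * np.sqrt(lam)).T  # Λ^{1/2} Eᵀ
    Dw = Dc @ whiten
    U, sv, Vt = np.linalg.svd(Dw, full_matrices=False)
    if np.any(sv[:r] <= sv[0] * 1e-12):
        raise ValueError(
            "signal has fewer independent components than SNR targets requested"
        )
    # Components come out of the SVD largest-first; targets are applied in
    # descending order so "component i" means the i-th strongest.
    targets = np.sort(snr_targets)[::-1]
    new_sv = np.sqrt(targets * (n - 1))
    Dw_cal = (U[:, :r] * new_sv) @ Vt[:r]
    return Dw_cal @ unwhiten + mu


def assemble_cube(
    abundances: np.ndarray, spectra: np.ndarray, config: SynthConfig
) -> tuple[HSICube, SyntheticTruth]:
    """Mix abundances and spectra, calibrate SNR, add noise: ``Y = D + δ``.

    Returns the noisy cube and the matching :class:`SyntheticTruth`
    (signal ``D``, noise ``δ``, true Σ_δ, rank, realized component SNRs).

    Raises
    ------
    ValueError
        If shapes disagree, or SNR targets are requested with zero noise
        or degenerate signal (unreachable targets).
    """
    n, s = config.n_pixels, config.bands
    if abundances.shape != (n, config.rank) or spectra.shape != (config.rank, s):
        raise ValueError(
            f"shape mismatch: abundances {abundances.shape}, spectra "
            f"{spectra.shape}, expected ({n},{config.rank}) and ({config.rank},{s})"
        )
    D = abundances @ spectra + config.baseline
    sigma_delta = build_noise_covariance(config)
    targets = config.snr_targets()

    if targets is not None:
        if config.noise_sigma == 0:
            raise ValueError("SNR targets are unreachable with zero noise variance")
        D = _calibrate_signal(D, sigma_delta, targets)
        realized = np.sort(targets)[::-1]
    else:
        realized = None

    if config.noise_sigma > 0:
        rng = config.child_rng("noise")
        chol = np.linalg.cholesky(sigma_delta)
        delta = rng.standard_normal((n, s)) @ chol.T
    else:
        delta = np.zeros((n, s))

    Y = D + delta
    # store the noise as Y - D so the truth identity holds bit-exactly in
    # floating point (a single rounded subtraction, reproducible downstream)
    delta = Y - D
    cube = HSICube(
        data=Y.reshape(config.width, config.height, s),
        wavenumbers=config.wavenumbers,
        metadata={"description": "synthetic FTIR-like cube", "seed": config.seed},
    )
    truth = SyntheticTruth(
        D=D,
        delta=delta,
        sigma_delta_true=sigma_delta,
        rank=config.rank,
        component_snrs=realized,
        width=config.width,
        height=config.height,
        wavenumbers=config.wavenumbers,
    )
    return cube, truth


def simulate(config: SynthConfig) -> tuple[HSICube, SyntheticTruth]:
    """Full generator pipeline: spectra → abundances → assembled noisy cube."""
    spectra = generate_spectra(config)
    abundances = generate_abundances(config)
    return assemble_cube(abundances, spectra, config)
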