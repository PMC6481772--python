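"""Accelerated MNF implementations sharing the core data model.

Four compute paths, identical in contract, different in cost:

* ``standard`` — full eigendecomposition of Σ_W, full N×S transform, then
  bands beyond K zeroed at reconstruction.
* ``fast`` — same full eigendecomposition, but only the selected S×K
  transforms and the N×K transformed matrix are ever materialized.
* ``approx`` — rank-K̂ block-Krylov truncated eigendecomposition with
  K̂ = ceil(0.03·S) (the empirical 2–3% of bands the selector keeps),
  then automatic band selection on the K̂ eigenvalues.
* ``rand`` — as ``approx`` with the randomized sketch engine; memory
  efficient, accuracy within a (1+ε) Frobenius factor.

If band selection saturates the truncation (K = K̂), the truncated rank
is doubled and the decomposition repeated up to the whitened dimension,
so selection is never silently clipped when the true signal rank exceeds
0.03·S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    ROSE_SNR_THRESHOLD,
    MNFTransform,
    build_transforms,
    compute_covariance,
    forward_transform,
    inverse_reconstruct,
    mnf_eigendecomposition,
    select_bands,
    whiten_covariance,
)
from .io import PixelMatrix
from .noise import NoiseModel
from .solvers import randomized_svd_sym, truncated_eig_krylov

__all__ = [
    "VariantConfig",
    "mnf_standard",
    "mnf_fast",
    "mnf_approx",
    "mnf_rand",
    "MNF_METHODS",
]


@dataclass
class VariantConfig:
    """Tuning knobs of the truncated/randomized variants.

    ``khat_fraction`` sets the initial truncated rank K̂ = ceil(f·S);
    ``epsilon`` is the Frobenius error target the randomized engine is
    expected to meet; ``oversampling`` and ``depth`` parameterize the
    sketch; ``seed`` makes the randomized variant reproducible.
    """

    khat_fraction: float = 0.03
    epsilon: float = 0.1
    oversampling: int = 10
    depth: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.khat_fraction <= 1):
            raise ValueError("khat_fraction must be in (0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.oversampling < 0:
            raise ValueError("oversampling must be >= 0")


def _whitened_covariance(pm: PixelMatrix, noise: NoiseModel):
    cov = compute_covariance(pm)
    return cov, whiten_covariance(cov, noise)


def mnf_standard(
    pm: PixelMatrix, noise: NoiseModel, threshold: float = ROSE_SNR_THRESHOLD
) -> tuple[MNFTransform, PixelMatrix]:
    """Reference MNF: full decomposition, full transform, truncate at K."""
    cov, sigma_w = _whitened_covariance(pm, noise)
    G, lam = mnf_eigendecomposition(sigma_w)
    K = select_bands(lam, threshold)
    # Full S×m transform materialized, bands beyond K zeroed by R at the
    # inverse step — the unaccelerated formulation.
    full = build_transforms(
        noise, G, lam, G.shape[1], cov.mean_Y, variant="standard", snr_threshold=threshold
    )
    scores = forward_transform(pm, full)  # N × m
    D_hat = scores[:, :K] @ full.phi_inverse[:, :K].T + cov.mean_Y
    model = build_transforms(
        noise, G, lam, K, cov.mean_Y, variant="standard", snr_threshold=threshold
    )
    denoised = PixelMatrix(
        Y=D_hat, width=pm.width, height=pm.height, wavenumbers=pm.wavenumbers
    )
    return model, denoised


def mnf_fast(
    pm: PixelMatrix, noise: NoiseModel, threshold: float = ROSE_SNR_THRESHOLD
) -> tuple[MNFTransform, PixelMatrix]:
    """Fast MNF: full decomposition, but only S×K transforms and an N×K
    transformed matrix are materialized (transposes replace inverses)."""
    cov, sigma_w = _whitened_covariance(pm, noise)
    G, lam = mnf_eigendecomposition(sigma_w)
    K = select_bands(lam, threshold)
    model = build_transforms(
        noise, G, lam, K, cov.mean_Y, variant="fast", snr_threshold=threshold
    )
    denoised = inverse_reconstruct(pm, model)
    return model, denoised


def _truncated_mnf(
    pm: PixelMatrix,
    noise: NoiseModel,
    threshold: float,
    config: VariantConfig,
    engine,
    variant: str,
) -> tuple[MNFTransform, PixelMatrix]:
    cov, sigma_w = _whitened_covariance(pm, noise)
    m = sigma_w.shape[0]
    khat = min(max(math.ceil(config.khat_fraction * pm.n_bands), 1), m)
    while True:
        G, lam = engine(sigma_w, khat)
        K = select_bands(lam, threshold)
        if K < khat or khat == m:
            break
        khat = min(2 * khat, m)  # selection saturated the truncation
    model = build_transforms(
        noise, G, lam, K, cov.mean_Y, variant=variant, snr_threshold=threshold,
        seed=config.seed if variant == "rand" else None,
    )
    denoised = inverse_reconstruct(pm, model)
    return model, denoised


def mnf_approx(
    pm: PixelMatrix,
    noise: NoiseModel,
    threshold: float = ROSE_SNR_THRESHOLD,
    config: VariantConfig | None = None,
) -> tuple[MNFTransform, PixelMatrix]:
    """Approx MNF: block-Krylov rank-K̂ decomposition, K̂ = ceil(0.03·S)."""
    config = config or VariantConfig()

    def engine(sigma_w, khat):
        return truncated_eig_krylov(
            sigma_w, khat, depth=config.depth,
            oversampling=config.oversampling, seed=config.seed,
        )

    return _truncated_mnf(pm, noise, threshold, config, engine, "approx")


def mnf_rand(
    pm: PixelMatrix,
    noise: NoiseModel,
    threshold: float = ROSE_SNR_THRESHOLD,
    config: VariantConfig | None = None,
) -> tuple[MNFTransform, PixelMatrix]:
    """Rand MNF: randomized sketch rank-K̂ decomposition (seeded)."""
    config = config or VariantConfig()

    def engine(sigma_w, khat):
        return randomized_svd_sym(
            sigma_w, khat, oversampling=config.oversampling,
            power_iterations=config.depth, seed=config.seed,
        )

    return _truncated_mnf(pm, noise, threshold, config, engine, "rand")


MNF_METHODS = {
    "standard": mnf_standard,
    "fast": mnf_fast,
    "approx": mnf_approx,
    "rand": mnf_rand,
}
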