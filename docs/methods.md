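# Methods

## The statistical model

Every pixel of a hyperspectral cube is modelled as a noisy measurement of a
smooth spectrum: `y_j = d_j + δ_j`, with the signal and noise uncorrelated
so that the band covariances add, `Σ_Y = Σ_D + Σ_δ`. The noise is assumed
zero-mean Gaussian, independent across pixels but possibly correlated
across bands — exactly the regime in which the MNF covariance algebra is
valid. Nothing in the transform assumes the signal is low-rank, but the
denoising benefit comes entirely from it being so: a tissue FTIR image with
~1500 channels typically carries a few tens of independent spectral
components.

MNF is computed in its noise-whitening (NAPC-equivalent) form. Writing
`Σ_δ = E Λ_δ Eᵀ`, the whitened data covariance
`Σ_W = Λ_δ^{-1/2} Eᵀ Σ_Y E Λ_δ^{-1/2}` has the noise contribution equal to
the identity, so its eigenvalues λ decompose as signal-SNR-plus-one:
per component, `SNR = λ − 1` and noise fraction `= 1/λ`. Components are
ordered by descending λ (decreasing image quality). Two normalization
conventions circulate for the MNF vectors (unit noise variance per
component, `φᵀΣ_δφ = 1`, versus unit total variance, `φᵀΣ_Yφ = 1`); they
are mutually inconsistent, and this package adopts the former — it is the
one under which the whitening chain `Φ = E Λ_δ^{-1/2} G` and the
inversion-free inverse below are exact.

### Mean centering

The covariance algebra silently assumes zero-mean data; real absorbance
images have large nonzero band means, for which `Σ_Y = Σ_D + Σ_δ` would
fail. Data are therefore column-mean-centred before any covariance is
formed and the mean is restored after reconstruction. The stored transform
carries the mean so new data can be projected through a fitted model.

### Inversion-free reconstruction

With `G` the eigenvectors of `Σ_W` and `R` the K-column block identity,

    Φ̂ = E Λ_δ^{-1/2} G R,   Φ̃ = E Λ_δ^{+1/2} G R,
    D̂ = (Y − μ) Φ̂ Φ̃ᵀ + μ.

Because `Φ̃ᵀΦ̂ = I_K`, this equals the textbook `Y Φ R Φ^{-1}` route while
involving only diagonal reciprocal square roots and transposes; the test
suite verifies the equivalence against a dense-inversion oracle on random
instances. With all bands and all noise dimensions kept the product
`Φ̂ Φ̃ᵀ` is the identity, so the full-band transform is lossless.

## Noise covariance estimation

The package does not try to be clever about Σ_δ: the default is the
classical shift-difference estimator, `Cov(y_p − y_q)/2` over adjacent
pixel pairs (horizontal by default), which is consistent when the signal is
spatially smooth at the one-pixel scale. A known covariance (or, for
simulations, the generator's true Σ_δ) can be passed instead. Which
estimator real deployments should use depends on the instrument; the
transform code is agnostic.

Before whitening, the eigendecomposition of Σ_δ is truncated to the
leading eigenvectors covering **99% of the noise variance** (default,
configurable via `variance_retained`). This guards `Λ_δ^{-1/2}` against
near-null noise directions and shrinks every later step; an absolute floor
of `1e-12·λ_max` is kept as a numerical backstop. Eigenvalue ties are
broken by the stable order of the underlying solver and every eigenvector's
largest-magnitude entry is made positive, so transforms are reproducible
across BLAS builds.

## Automatic band selection

The Rose criterion — an SNR of at least 5 is needed to distinguish image
features reliably — is applied to the MNF spectrum: `K = #{i : λ_i − 1 ≥
5.0}`, boundary inclusive. If nothing qualifies the top component is kept
with a warning rather than returning an empty basis. The threshold is a
parameter (`snr_threshold`) but its default is the point of the package:
no human looks at eigenimages.

## Accelerated variants

* **fast** — identical spectra to standard MNF (same full eigendecomposition)
  but only `S×K` transform matrices and an `N×K` transformed matrix are
  materialized.
* **approx** — a block-Krylov (Block Lanczos style) truncated
  eigendecomposition at rank `K̂ = ceil(0.03·S)`, the empirical 2–3% of
  bands that selection typically keeps. Each depth step contributes two
  Krylov blocks with QR re-orthonormalization between multiplications;
  depth 4 with oversampling 10 reaches near machine precision on spectra
  with a genuine gap at K.
* **rand** — a single-sketch randomized range finder (Gaussian test matrix
  of `K̂ + 10` columns, 4 power iterations with QR) followed by
  Rayleigh–Ritz extraction; satisfies the usual (1+ε) Frobenius bound
  versus the best rank-K̂ approximation (checked empirically at ε = 0.1
  over seeds) and is deterministic given its seed, which is recorded in the
  fitted model.

If band selection returns `K = K̂` the truncation may have clipped it, so
`K̂` is doubled and the decomposition repeated (up to the whitened
dimension). This guard matters whenever the true signal rank exceeds
0.03·S. The observed agreement ladder on well-gapped synthetic cubes —
fast ≤ 1e-8, approx ≤ 1e-6, rand ≤ 1e-3 relative Frobenius distance from
the standard reconstruction — is asserted in the test suite.

## The synthetic-data generator

The generator emulates an FTIR tissue image: `r` endmember spectra, each a
sum of 3–8 Gaussian peaks (widths 10–60 cm⁻¹) on a 900–3800 cm⁻¹ axis,
mixed by spatially smooth nonnegative abundance maps (Gaussian-blurred
white noise, blur σ = min(W,H)/8 pixels), plus Gaussian noise with a known
covariance (iid, band-correlated AR(1), or diagonal). Optional
`peak_range` confines peaks to a sub-range (e.g. a 950–1750 cm⁻¹
fingerprint region, leaving the rest IR-silent) and `baseline` adds a
constant absorbance offset.

Per-component SNR targets are met exactly rather than approximately: the
centred signal is mapped to noise-whitened coordinates, its singular
values are set to `sqrt(SNR_i · (N−1))`, and the result is mapped back.
"Component SNR" therefore means precisely the quantity the band selector
thresholds — the eigenvalues-minus-one of the whitened covariance — making
dimension-recovery experiments exact by construction in expectation, while
the fitted values still fluctuate through the sampled noise. The emitted
truth stores the noise as `Y − D` so the additive identity holds bit-exactly.

All randomness flows from one integer seed through `SeedSequence`
spawning; spectra, abundances and noise have independent, individually
reproducible streams.

**What the generator does not emulate:** Poisson/shot noise,
multiplicative gain variation, baseline drift or atmospheric artifacts,
spatially varying noise, and instrument point-spread blurring. Passing
tests on these cubes validate the covariance algebra, the selector and the
variant approximations under the model's own assumptions — not robustness
to real-instrument pathologies.

## Quality metrics

`mni_per_band` implements the Method Noise Image score as the Pearson
correlation, over pixels, of two SSIM maps per band: noisy-versus-method-
noise and noisy-versus-denoised. SSIM uses the standard parameters
(11×11 Gaussian window, σ = 1.5, K1 = 0.01, K2 = 0.03) with the noisy
band's dynamic range. Lower MNI indicates a cleaner split of structure and
noise; bands where either map is constant (a degenerate denoiser) are
flagged undefined rather than coerced to a value. Richer formulations that
pre-segment homogeneous versus structured regions exist; this package
implements the plain correlation form only.

A practical caveat found while validating: the correlation is scale-free,
so on cubes where *every* band carries at least faint smooth structure and
spectra have no baseline, MNI is uniformly negative and the
fingerprint-versus-silent contrast does not appear. The contrast emerges
under realistic conditions — truly signal-free bands plus a nonzero
absorbance baseline — which is how the ordering tests construct their
cubes (`peak_range=(950, 1750)`, `baseline=1.0`).

With ground truth available, `rmse` and `empirical_snr`
(`Var(D)/Var(D̂−D)`) are provided for validation.

## Numerical choices and problem sizes

Contract tolerances default to 1e-6 (whitening / diagonalization of fitted
models) and 1e-8 (exact algebraic identities), comfortable in double
precision up to S ≈ 2000. Sample covariance uses the unbiased 1/(N−1)
normalizer. The validation studies run at deliberately desk-friendly sizes
— 50×50×1506 for the FTIR-scale band-selection study (mirroring the
~1500-channel spectral axis while keeping N small), 32×32×160 for the
10-seed recovery suite — chosen so the full suite plus the acceptance
script completes in well under a minute on one core. With N this small
relative to S, sample-covariance eigenvalue spreading inflates pure-noise
MNF eigenvalues to λ ≈ 3 (SNR ≈ 2), still safely below the Rose threshold;
at larger N the margin only widens.

## Known limitations

* The shift-difference estimator biases Σ_δ upward where the signal has
  one-pixel-scale spatial detail; supply a measured covariance in that case.
* Band selection assumes the noise model is right: an underestimated Σ_δ
  inflates λ and keeps too many bands.
* No out-of-core or streaming covariance; cubes must fit in memory.
* MNI is a relative, no-reference diagnostic; its absolute values are not
  comparable across cubes with different dynamic ranges.
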