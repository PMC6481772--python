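import numpy as np
import pytest

from mnfdenoise import MNF, SynthConfig, simulate
from mnfdenoise.io import cube_to_matrix

#: conditions of the parameter-recovery suite: a handful of strong
#: components (SNR 20) among pure-noise directions, true Σ_δ supplied.
RECOVERY_CONFIG = dict(
    width=32, height=32, bands=160, rank=6, component_snrs=20.0,
    noise="iid", noise_sigma=1.0,
)
RECOVERY_SEEDS = tuple(range(10))


@pytest.fixture(scope="session")
def small_sim():
    """One modest synthetic cube + truth shared by cheap tests."""
    cfg = SynthConfig(width=32, height=32, bands=160, rank=5,
                      component_snrs=20.0, seed=11)
    cube, truth = simulate(cfg)
    return cfg, cube, truth


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """Standard MNF fitted to the shared cube with the true noise covariance."""
    _, cube, truth = small_sim
    model = MNF(cube, noise=truth.sigma_delta_true)
    return model, model.fit(method="standard")


@pytest.fixture(scope="session")
def fingerprint_sim():
    """FTIR-like cube: structured fingerprint region next to IR-silent bands.

    Peaks confined to 950-1750 cm⁻¹ on a 900-3800 axis, unit absorbance
    baseline — so bands above ~1800 cm⁻¹ carry pure noise.
    """
    cfg = SynthConfig(width=32, height=32, bands=160, rank=5,
                      component_snrs=20.0, peak_range=(950.0, 1750.0),
                      baseline=1.0, seed=11)
    cube, truth = simulate(cfg)
    res = MNF(cube, noise=truth.sigma_delta_true).fit(method="standard")
    return cfg, cube, truth, res


@pytest.fixture(scope="session")
def recovery_suite():
    """Ten seeded recovery runs: (truth, pixel matrix, fitted results)."""
    runs = []
    for seed in RECOVERY_SEEDS:
        cfg = SynthConfig(seed=seed, **RECOVERY_CONFIG)
        cube, truth = simulate(cfg)
        res = MNF(cube, noise=truth.sigma_delta_true).fit(method="standard")
        runs.append((truth, cube_to_matrix(cube), res))
    return runs


def random_spd(rng: np.random.Generator, s: int, cond: float = 50.0) -> np.ndarray:
    """A well-conditioned random symmetric positive definite matrix."""
    Q, _ = np.linalg.qr(rng.standard_normal((s, s)))
    lam = np.geomspace(cond, 1.0, s)
    return (Q * lam) @ Q.T
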