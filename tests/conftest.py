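import numpy as np
import pytest

from selenospec import EMGParams, SamplerConfig
from selenospec.calibration import SE_PANEL, StandardLibrary
from selenospec.chromatogram import to_elution_distribution
from selenospec.simulate import ChromSimSpec, simulate_mixture_chromatogram


#: well-separated panel truths used across the recovery tests; apexes span
#: the 0-25 min window with > 2 min gaps so the weights are identifiable
PANEL_TRUTHS = {
    "GSSeSG": EMGParams(13.6, 0.12, 6.0),
    "MSA": EMGParams(9.0, 0.10, 4.0),
    "selenite": EMGParams(16.0, 0.10, 5.0),
    "DMSeO": EMGParams(19.0, 0.15, 3.0),
}


@pytest.fixture(scope="session")
def panel_truths():
    return PANEL_TRUTHS


@pytest.fixture(scope="session")
def true_library():
    """Library built from the generating truths (bypasses calibration)."""
    return StandardLibrary(SE_PANEL, PANEL_TRUTHS)


@pytest.fixture(scope="session")
def fast_sampler():
    """Reduced sampler budget for tests where full convergence polish is
    not the property under test."""
    return SamplerConfig(tune=500, steps=800, seed=71)


def make_mixture_distribution(weights, total_counts=5000, seed=0, noise="multinomial"):
    spec = ChromSimSpec(
        components=tuple(PANEL_TRUTHS[c] for c in SE_PANEL),
        weights=tuple(weights),
        total_counts=total_counts,
        seed=seed,
        noise=noise,
        names=SE_PANEL,
    )
    return to_elution_distribution(simulate_mixture_chromatogram(spec))


def random_valid_emg(rng) -> EMGParams:
    return EMGParams(
        mu=float(rng.uniform(-5, 20)),
        sigma=float(rng.uniform(0.02, 2.0)),
        lam=float(rng.uniform(0.2, 50.0)),
    )
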