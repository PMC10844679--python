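"""Seeded generators for synthetic chromatograms and kinetics datasets.

These generators produce data with exactly the statistical structure the
analysis stages assume — EMG mixture elution profiles with count noise,
and Michaelis-Menten saturation curves with Gaussian noise — so that
calibration, deconvolution, and kinetic fitting are all verifiable by
parameter recovery without any instrument data.

Chromatograms: retention times are distributed as the specified EMG
mixture; binned intensities are drawn either as one multinomial draw of
the total ion count N over the bin probabilities (default; total is
conserved exactly) or as independent Poisson counts with the same means.
The default grid, 0-25 min at 0.05 min steps, brackets the elution
landmarks of the selenium panel (GSSeSG near 13.8 min, selenite near
16.2 min).

All randomness in a generator call flows from the single spec seed
through ``numpy.random.SeedSequence`` spawning, one child stream per
logical draw, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chromatogram import Chromatogram
from .emg import EMGParams, emg_pdf, emg_sample
from .kinetics import DEFAULT_S0_GRID, KineticsDataset, mm_rate

__all__ = [
    "ChromSimSpec",
    "KinSimSpec",
    "simulate_mixture_chromatogram",
    "simulate_standard_chromatogram",
    "simulate_kinetics",
    "sample_mixture_times",
    "mixture_bin_probabilities",
    "DEFAULT_WINDOW",
    "DEFAULT_STEP",
]

DEFAULT_WINDOW = (0.0, 25.0)
DEFAULT_STEP = 0.05

NOISE_MODELS = ("multinomial", "poisson")


@dataclass(frozen=True)
class ChromSimSpec:
    """Ground truth for one simulated mixture chromatogram."""

    components: tuple  # EMGParams per panel compound, elution order
    weights: tuple
    total_counts: int = 5000
    window: tuple[float, float] = DEFAULT_WINDOW
    step: float = DEFAULT_STEP
    noise: str = "multinomial"
    seed: Optional[int] = None
    names: Optional[tuple] = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if len(self.components) != w.size:
            raise ValueError("one weight per component required")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must lie on the simplex, got {w}")
        if self.total_counts < 1:
            raise ValueError("total_counts must be >= 1")
        if not self.step > 0:
            raise ValueError("grid step must be positive")
        if self.noise not in NOISE_MODELS:
            raise ValueError(f"noise must be one of {NOISE_MODELS}")
        lo, hi = self.window
        for p, wk in zip(self.components, w):
            if wk == 0:
                continue
            if p.mu - 5 * p.sigma < lo or p.mu + 5 * p.sigma + 5 / p.lam > hi:
                raise ValueError(
                    f"window {self.window} too narrow for component at mu={p.mu}"
                )


@dataclass(frozen=True)
class KinSimSpec:
    """Ground truth for one simulated saturation-kinetics dataset.

    ``noise_sd`` defaults to 5% of the true V_max; rates are truncated
    at zero, as negative initial rates are not physical.
    """

    km: float
    vmax: float
    s0_grid: tuple = DEFAULT_S0_GRID
    noise_sd: Optional[float] = None
    replicates: int = 3
    seed: Optional[int] = None

    def __post_init__(self):
        if not self.km > 0:
            raise ValueError("km must be positive")
        if self.vmax < 0:
            raise ValueError("vmax must be nonnegative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def sd(self) -> float:
        return 0.05 * self.vmax if self.noise_sd is None else self.noise_sd


def _grid(window: tuple[float, float], step: float) -> np.ndarray:
    lo, hi = window
    n = int(round((hi - lo) / step))
    return lo + step * (np.arange(n) + 0.5)  # bin centers


def mixture_bin_probabilities(spec: ChromSimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Bin centers and mixture bin probabilities over the grid.

    Each bin's probability is the bin integral of the mixture density
    (Simpson over edges and center, renormalized over the window), i.e.
    the distribution of binned retention-time draws.
    """
    centers = _grid(spec.window, spec.step)
    h = spec.step / 2.0
    dens = np.zeros_like(centers)
    for p, w in zip(spec.components, spec.weights):
        if w > 0:
            avg = (emg_pdf(centers - h, p) + 4.0 * emg_pdf(centers, p)
                   + emg_pdf(centers + h, p)) / 6.0
            dens += w * avg
    prob = dens * spec.step
    return centers, prob / prob.sum()


def sample_mixture_times(spec: ChromSimSpec, n: Optional[int] = None) -> np.ndarray:
    """Draw raw retention times: species label ~ Categorical(weights),
    then an EMG draw from that component."""
    n = n or spec.total_counts
    ss = np.random.SeedSequence(spec.seed)
    s_label, s_times = ss.spawn(2)
    rng = np.random.default_rng(s_label)
    z = rng.choice(len(spec.components), size=n, p=np.asarray(spec.weights))
    times = np.empty(n)
    for k, child in enumerate(s_times.spawn(len(spec.components))):
        mask = z == k
        if mask.any():
            times[mask] = emg_sample(spec.components[k], int(mask.sum()), child)
    return times


def simulate_mixture_chromatogram(spec: ChromSimSpec) -> Chromatogram:
    """Simulate a binned mixture trace with count noise.

    With ``noise="multinomial"`` the bin counts are one multinomial draw
    of ``total_counts`` over the mixture bin probabilities, so the summed
    intensity equals the total exactly; ``"poisson"`` draws independent
    per-bin Poisson counts with the same means.
    """
    centers, prob = mixture_bin_probabilities(spec)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(3)[2])
    if spec.noise == "multinomial":
        counts = rng.multinomial(spec.total_counts, prob)
    else:
        counts = rng.poisson(spec.total_counts * prob)
    meta = {
        "simulated": True,
        "noise": spec.noise,
        "total_counts": spec.total_counts,
        "seed": spec.seed,
        "channel": "Se m/z 82",
    }
    if spec.names:
        meta["panel"] = ",".join(spec.names)
    return Chromatogram(centers, counts.astype(float), meta)


def simulate_standard_chromatogram(
    p: EMGParams,
    total_counts: int = 5000,
    window: tuple[float, float] = DEFAULT_WINDOW,
    step: float = DEFAULT_STEP,
    seed: Optional[int] = None,
    noise: str = "multinomial",
    name: Optional[str] = None,
) -> Chromatogram:
    """Single-compound standard: the degenerate one-component mixture."""
    spec = ChromSimSpec(
        components=(p,), weights=(1.0,), total_counts=total_counts,
        window=window, step=step, noise=noise, seed=seed,
        names=(name,) if name else None,
    )
    return simulate_mixture_chromatogram(spec)


def simulate_kinetics(spec: KinSimSpec) -> KineticsDataset:
    """Michaelis-Menten rates with truncated Gaussian noise.

    v0 = mm_rate(S0; km, vmax) + Normal(0, noise_sd), clipped at zero;
    with ``noise_sd=0`` the data lie exactly on the curve.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    S = np.tile(np.asarray(spec.s0_grid, dtype=float), spec.replicates)
    rep = np.repeat(np.arange(1, spec.replicates + 1), len(spec.s0_grid))
    clean = mm_rate(S, spec.km, spec.vmax)
    noisy = clean + rng.normal(0.0, spec.sd, size=S.size) if spec.sd > 0 else clean
    return KineticsDataset(S, np.clip(noisy, 0.0, None), rep)
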