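"""Calibration of per-compound EMG peak shapes from standard chromatograms.

Each standard compound of the selenium panel is injected alone; its
elution profile, converted to a probability distribution over time bins,
is treated as (effective) ion-count observations from a single EMG
density.  Continuous uniform priors are placed on (mu, sigma, lam) and
the posterior is explored by MCMC.  The posterior means become the fixed
component parameters of the downstream mixture model; the full posterior
summary (SD, 94% interval, R-hat, ESS) is kept alongside so the library
records how well each shape was determined.

The weighted log-likelihood is ``sum_b c_b * log EMG(x_b; mu, sigma,
lam)`` with ``c_b`` the per-bin effective counts — the i.i.d.-sample
reading of the profile-to-distribution conversion, without materializing
the counts as literal pseudo-observations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import erfcx, logsumexp

from .chromatogram import ElutionDistribution, EmptySignalError
from .emg import EMGParams, emg_apex, _log_erfcx
from .mcmc import PosteriorSummary, SamplerConfig, run_sampler

__all__ = [
    "PriorBounds",
    "StandardLibrary",
    "SE_PANEL",
    "fit_standard",
    "build_standard_library",
    "emg_loglike_grid",
    "bin_steps",
]

#: The four-species selenium panel, in elution order of the mixture model.
SE_PANEL = ("GSSeSG", "MSA", "selenite", "DMSeO")

PARAM_NAMES = ("mu", "sigma", "lam")


@dataclass(frozen=True)
class PriorBounds:
    """Uniform prior box for one standard's (mu, sigma, lam).

    Defaults derive from the fitted time window: mu anywhere in the
    window, sigma up to the window span, lam between 0.01 and 1000 per
    minute.  All ranges are echoed into the fit output.
    """

    mu: tuple[float, float]
    sigma: tuple[float, float] = (1e-3, np.inf)
    lam: tuple[float, float] = (1e-2, 1e3)

    def __post_init__(self):
        for name in PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"empty prior range for {name}: ({lo}, {hi})")
        if self.sigma[0] <= 0 or self.lam[0] <= 0:
            raise ValueError("sigma and lam prior ranges must be positive")

    @classmethod
    def from_window(cls, t_lo: float, t_hi: float) -> "PriorBounds":
        span = t_hi - t_lo
        return cls(mu=(t_lo, t_hi), sigma=(1e-3, span), lam=(1e-2, 1e3))

    def to_dict(self) -> dict:
        return {n: list(getattr(self, n)) for n in PARAM_NAMES}


def _batch_logpdf(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """(m, B) EMG log-density: parameter batch theta=(m,3) against grid x."""
    mu, sigma, lam = theta[:, 0:1], theta[:, 1:2], theta[:, 2:3]
    u = (x[None, :] - mu) / sigma
    v = lam * sigma
    return np.log(lam / 2.0) - 0.5 * u**2 + _log_erfcx((v - u) / np.sqrt(2.0))


def bin_steps(x: np.ndarray) -> np.ndarray:
    """Local bin widths for a strictly increasing grid of bin centers."""
    edges = np.concatenate([[x[0] - (x[1] - x[0]) / 2],
                            (x[1:] + x[:-1]) / 2,
                            [x[-1] + (x[-1] - x[-2]) / 2]])
    return np.diff(edges)


def emg_loglike_grid(
    theta: np.ndarray, x: np.ndarray, counts: np.ndarray,
    step: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Weighted EMG log-likelihood for a batch of parameter vectors.

    ``theta`` has shape (m, 3) columns (mu, sigma, lam); returns shape
    (m,).  With ``step`` given, each bin's density is Simpson-averaged
    over the bin (edges and center) instead of evaluated at the center
    only: the data are binned counts, and for peaks whose sigma is
    comparable to the bin width the center-point density is biased enough
    to distort the posterior.  Same stable erfcx evaluation as
    :func:`selenospec.emg.emg_logpdf` throughout.
    """
    if step is None:
        logpdf = _batch_logpdf(theta, x)
    else:
        h = step / 2.0
        stacked = np.stack([
            _batch_logpdf(theta, x - h) + np.log(1.0 / 6.0),
            _batch_logpdf(theta, x) + np.log(4.0 / 6.0),
            _batch_logpdf(theta, x + h) + np.log(1.0 / 6.0),
        ])
        logpdf = logsumexp(stacked, axis=0)
    return logpdf @ counts


def _moment_init(d: ElutionDistribution) -> np.ndarray:
    """Method-of-moments starting point from the binned profile."""
    x, p = d.bin_centers, d.probabilities
    m = float(np.dot(x, p))
    var = float(np.dot((x - m) ** 2, p))
    m3 = float(np.dot((x - m) ** 3, p))
    if m3 > 0:
        tau = (m3 / 2.0) ** (1.0 / 3.0)
    else:
        tau = np.sqrt(var) / 2.0
    sig2 = var - tau**2
    if sig2 <= 0:
        tau = np.sqrt(var) / 2.0
        sig2 = var - tau**2
    return np.array([m - tau, np.sqrt(sig2), 1.0 / tau])


def fit_standard(
    d: ElutionDistribution,
    prior_bounds: Optional[PriorBounds] = None,
    mcmc: Optional[SamplerConfig] = None,
) -> PosteriorSummary:
    """Posterior over (mu, sigma, lam) for a single-compound standard.

    Raises :class:`EmptySignalError` for an informationless profile,
    ``ValueError`` if the prior box excludes the data's support, and
    warns or raises on R-hat > threshold per the sampler config policy.
    """
    if not np.any(d.probabilities > 0):
        raise EmptySignalError("distribution carries no signal")
    mcmc = mcmc or SamplerConfig()
    t_lo, t_hi = float(d.bin_centers[0]), float(d.bin_centers[-1])
    pb = prior_bounds or PriorBounds.from_window(t_lo, t_hi)
    span = t_hi - t_lo
    if pb.mu[0] > t_hi or pb.mu[1] < t_lo - span:
        raise ValueError("mu prior range excludes the data's time support")

    x = d.bin_centers
    counts = d.counts
    step = bin_steps(x)
    lo = np.array([pb.mu[0], pb.sigma[0], pb.lam[0]])
    hi = np.array([pb.mu[1], pb.sigma[1], pb.lam[1]])

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        inside = np.all((theta > lo) & (theta < hi), axis=1)
        out = np.full(theta.shape[0], -np.inf)
        if inside.any():
            out[inside] = emg_loglike_grid(theta[inside], x, counts, step)
        return out

    center = np.clip(_moment_init(d), lo * 1.001 + 1e-9, np.minimum(hi * 0.999, 1e9))
    scale = np.maximum(np.abs(center) * 0.02, [1e-3, 1e-4, 1e-3])
    return run_sampler(
        log_prob, center, scale, PARAM_NAMES, mcmc,
        extra_settings={"prior_bounds": pb.to_dict(),
                        "total_counts": float(d.total_counts)},
    )


@dataclass(frozen=True)
class StandardLibrary:
    """Calibrated EMG parameters for an ordered compound panel."""

    panel: tuple
    params: Mapping[str, EMGParams]
    summaries: Mapping[str, PosteriorSummary] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.panel)) != len(self.panel):
            raise ValueError("duplicate compound names in panel")
        missing = [c for c in self.panel if c not in self.params]
        if missing:
            raise ValueError(f"missing compounds: {missing}")

    def __len__(self) -> int:
        return len(self.panel)

    def __getitem__(self, compound: str) -> EMGParams:
        return self.params[compound]

    def ordered_params(self) -> list[EMGParams]:
        return [self.params[c] for c in self.panel]

    def apexes(self) -> dict[str, float]:
        """Elution time (density apex) per compound, minutes."""
        return {c: emg_apex(self.params[c]) for c in self.panel}

    def content_hash(self) -> str:
        payload = json.dumps(
            {c: [self.params[c].mu, self.params[c].sigma, self.params[c].lam]
             for c in self.panel},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "panel": list(self.panel),
            "compounds": {
                c: {
                    "mu": self.params[c].mu,
                    "sigma": self.params[c].sigma,
                    "lam": self.params[c].lam,
                    **({"summary": self.summaries[c].to_dict()}
                       if c in self.summaries else {}),
                }
                for c in self.panel
            },
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "StandardLibrary":
        params = {}
        summaries = {}
        for c, entry in d["compounds"].items():
            params[c] = EMGParams(entry["mu"], entry["sigma"], entry["lam"])
            if "summary" in entry:
                summaries[c] = PosteriorSummary.from_dict(entry["summary"])
        return cls(tuple(d["panel"]), params, summaries, d.get("provenance", {}))

    @classmethod
    def from_json(cls, path) -> "StandardLibrary":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_standard_library(
    fits: Mapping[str, PosteriorSummary],
    panel: Sequence[str] = SE_PANEL,
    allow_nonconverged: bool = False,
    provenance: Optional[dict] = None,
) -> StandardLibrary:
    """Assemble the panel library from per-compound posterior fits.

    Point estimates are the posterior means.  A non-converged fit is
    rejected unless ``allow_nonconverged`` is set explicitly.
    """
    panel = tuple(panel)
    missing = [c for c in panel if c not in fits]
    if missing:
        raise ValueError(f"missing fits for panel compounds: {missing}")
    params = {}
    for c in panel:
        s = fits[c]
        if not s.converged and not allow_nonconverged:
            raise ValueError(
                f"fit for {c!r} did not converge (max R-hat {s.max_rhat():.4f}); "
                "pass allow_nonconverged=True to override"
            )
        params[c] = EMGParams(s.mean["mu"], s.mean["sigma"], s.mean["lam"])
    return StandardLibrary(panel, params, dict(fits), dict(provenance or {}))
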