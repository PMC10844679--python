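"""Chromatogram container, CSV I/O, and conversion to probability distributions.

An LC-ICP-MS trace is a detector intensity (counts per second on an
element-specific channel, e.g. Se m/z 82) sampled on an increasing grid of
retention times.  For Bayesian fitting, the elution profile is converted
into a one-dimensional probability distribution over the time bins: the
bin probabilities are the (optionally baseline-corrected) intensities
normalized to unit sum, and the summed corrected intensity acts as the
effective number of ion-count observations behind the profile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Chromatogram",
    "ElutionDistribution",
    "read_chromatogram",
    "write_chromatogram",
    "to_elution_distribution",
]

MIN_POINTS = 10

CSV_HEADER = ("time_min", "intensity_cps")


class ChromatogramError(ValueError):
    """Raised on malformed chromatogram input."""


class EmptySignalError(ValueError):
    """Raised when a trace carries no signal after baseline handling."""


@dataclass(frozen=True)
class Chromatogram:
    """A retention-time/intensity trace with sample metadata.

    ``time_min`` must be strictly increasing, ``intensity_cps``
    nonnegative, both the same length with at least 10 points.
    """

    time_min: np.ndarray
    intensity_cps: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        y = np.asarray(self.intensity_cps, dtype=float)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "intensity_cps", y)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ChromatogramError("time and intensity must be 1-D and equal length")
        if t.size < MIN_POINTS:
            raise ChromatogramError(f"need >= {MIN_POINTS} points, got {t.size}")
        dt = np.diff(t)
        if not np.all(dt > 0):
            row = int(np.argmin(dt > 0)) + 1
            raise ChromatogramError(f"time not strictly increasing at row {row}")
        if np.any(y < 0):
            row = int(np.argmax(y < 0))
            raise ChromatogramError(f"negative intensity at row {row}")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ChromatogramError("non-finite values in trace")

    def __len__(self) -> int:
        return self.time_min.size


@dataclass(frozen=True)
class ElutionDistribution:
    """Elution profile as a discrete probability distribution.

    ``probabilities`` are nonnegative and sum to one over the
    ``bin_centers`` grid; ``total_counts`` is the effective sample size
    the profile represents (possibly capped, see
    :func:`to_elution_distribution`).
    """

    bin_centers: np.ndarray
    probabilities: np.ndarray
    total_counts: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = np.asarray(self.bin_centers, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "bin_centers", x)
        object.__setattr__(self, "probabilities", p)
        if x.shape != p.shape or x.ndim != 1:
            raise ValueError("bin_centers and probabilities must be 1-D and equal length")
        if not np.all(np.diff(x) > 0):
            raise ValueError("bin_centers must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")
        if not self.total_counts > 0:
            raise ValueError("total_counts must be positive")

    @property
    def counts(self) -> np.ndarray:
        """Per-bin effective counts, ``total_counts * probabilities``."""
        return self.total_counts * self.probabilities

    def mean(self) -> float:
        return float(np.dot(self.bin_centers, self.probabilities))

    def to_json(self, path) -> None:
        payload = {
            "bin_centers": self.bin_centers.tolist(),
            "probabilities": self.probabilities.tolist(),
            "total_counts": self.total_counts,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "ElutionDistribution":
        d = json.loads(Path(path).read_text())
        return cls(
            np.array(d["bin_centers"]), np.array(d["probabilities"]),
            d["total_counts"], d.get("provenance", {}),
        )


def read_chromatogram(source, meta: Optional[dict] = None) -> Chromatogram:
    """Read a two-column CSV trace (time_min, intensity_cps).

    Accepts a path or open text handle.  A header row naming the columns
    is optional; lines starting with ``#`` are comments.  Parse and
    validation errors name the offending row.
    """
    try:
        df = pd.read_csv(source, comment="#", header=None, skip_blank_lines=True,
                         float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ChromatogramError(f"cannot parse chromatogram: {exc}") from exc
    if df.shape[1] != 2:
        raise ChromatogramError(f"expected 2 columns, got {df.shape[1]}")
    # drop an optional header row
    first = df.iloc[0]
    if any(isinstance(v, str) for v in first):
        df = df.iloc[1:].reset_index(drop=True)
    cols = []
    for col in (0, 1):
        vals = np.empty(len(df))
        for row, cell in enumerate(df[col]):
            try:
                vals[row] = float(cell)  # correctly-rounded, bit-exact round-trip
            except (TypeError, ValueError):
                raise ChromatogramError(
                    f"non-numeric cell {cell!r} in column {col} at data row {row}"
                ) from None
        cols.append(vals)
    if any(np.isnan(v).any() for v in cols):
        raise ChromatogramError("missing values in trace")
    name = getattr(source, "name", None) or (str(source) if isinstance(source, (str, Path)) else None)
    m = dict(meta or {})
    if name and "source" not in m:
        m["source"] = str(name)
    return Chromatogram(cols[0], cols[1], m)


def write_chromatogram(c: Chromatogram, path) -> None:
    """Write a trace in the canonical CSV dialect (header, full precision)."""
    with open(path, "w") as fh:
        fh.write(",".join(CSV_HEADER) + "\n")
        for t, y in zip(c.time_min, c.intensity_cps):
            fh.write(f"{float(t)!r},{float(y)!r}\n")


def to_elution_distribution(
    c: Chromatogram,
    baseline: str = "none",
    window: Optional[tuple[float, float]] = None,
    n_eff_cap: Optional[float] = 5000.0,
) -> ElutionDistribution:
    """Convert an elution profile into a discrete probability distribution.

    Parameters
    ----------
    baseline : {"none", "min-subtract"}
        Baseline handling.  ``"none"`` uses raw intensities;
        ``"min-subtract"`` subtracts the per-trace minimum first.
    window : (t_lo, t_hi), optional
        Restrict to retention times in the closed interval before
        normalizing.
    n_eff_cap : float, optional
        Upper bound on ``total_counts``.  Raw summed cps can reach 1e6+,
        which as a multinomial sample size would make posteriors
        implausibly tight; the cap down-weights proportionally and is
        recorded in the provenance.  ``None`` disables capping.

    Raises
    ------
    EmptySignalError
        If no strictly positive corrected intensity remains.
    """
    if baseline not in ("none", "min-subtract"):
        raise ValueError(f"unknown baseline mode {baseline!r}")
    t = c.time_min
    y = c.intensity_cps.astype(float)
    if window is not None:
        lo, hi = window
        keep = (t >= lo) & (t <= hi)
        if not keep.any():
            raise EmptySignalError("window excludes every point")
        t, y = t[keep], y[keep]
    if baseline == "min-subtract":
        y = y - y.min()
    total = float(y.sum())
    if total <= 0 or not np.any(y > 0):
        raise EmptySignalError("no signal after baseline handling")
    prob = y / total
    capped = n_eff_cap is not None and total > n_eff_cap
    n_eff = float(n_eff_cap) if capped else total
    prov = {
        "baseline": baseline,
        "window": list(window) if window is not None else None,
        "raw_total_cps": total,
        "n_eff_cap": n_eff_cap,
        "capped": bool(capped),
        **{k: v for k, v in c.meta.items() if isinstance(v, (str, int, float))},
    }
    return ElutionDistribution(t, prob, n_eff, prov)
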