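"""Linear mapping between positional probability and CAM expression.

The model identifies the cell-concentration field with the positional
probability density up to normalization, and measures concentration through
cell-adhesion-molecule (CAM, e.g. integrin alpha-v) expression ratios of
tumor versus normal tissue:

    p(r, t_hat) = lambda * c(r, t_hat)

where ``lambda`` is a dimensionless normalization factor (CAM copies per
cell scaling) treated as constant.  Since the relation asserts exact
proportionality, ``lambda`` is estimated by through-origin least squares on
paired (probability, concentration-ratio) observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CAMMapping",
    "PairedSeries",
    "probability_to_concentration",
    "concentration_to_probability",
    "estimate_lambda",
    "read_paired_series",
]


@dataclass(frozen=True)
class CAMMapping:
    """Proportionality factor lambda linking density to concentration ratio.

    ``stderr`` is populated when the mapping comes from
    :func:`estimate_lambda` on more than one pair; ``None`` otherwise.
    """

    lam: float
    stderr: float | None = None

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"lambda must be > 0, got {self.lam}")


@dataclass(frozen=True)
class PairedSeries:
    """Paired positional probabilities and CAM concentration ratios."""

    probabilities: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if p.shape != c.shape or p.ndim != 1 or p.size < 1:
            raise ValueError("probabilities and concentrations must be equal-length 1-D, >= 1 pair")
        if np.any(p <= 0) or np.any(c <= 0):
            raise ValueError("all paired values must be > 0")
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "concentrations", c)

    def __len__(self) -> int:
        return self.probabilities.size


def probability_to_concentration(p, mapping: CAMMapping):
    """c = p / lambda; vectorized, requires p >= 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probability density must be non-negative")
    out = p / mapping.lam
    return float(out) if out.ndim == 0 else out


def concentration_to_probability(c, mapping: CAMMapping):
    """p = lambda * c; inverse of :func:`probability_to_concentration`."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration ratio must be non-negative")
    out = c * mapping.lam
    return float(out) if out.ndim == 0 else out


def estimate_lambda(series: PairedSeries) -> CAMMapping:
    """Through-origin least squares: lambda = sum(p*c) / sum(c**2).

    Exact on noise-free proportional data; the standard error uses the
    usual regression-through-origin residual variance (undefined for a
    single pair, reported as ``None`` there).
    """
    p = series.probabilities
    c = series.concentrations
    scc = float(np.sum(c * c))
    if scc == 0.0:
        raise ValueError("degenerate fit: concentrations are all zero")
    lam = float(np.sum(p * c) / scc)
    stderr = None
    n = len(series)
    if n > 1:
        resid = p - lam * c
        stderr = math.sqrt(float(np.sum(resid**2)) / (n - 1) / scc)
    return CAMMapping(lam=lam, stderr=stderr)


def read_paired_series(path) -> PairedSeries:
    """Read a paired series CSV with columns ``probability`` and
    ``concentration_ratio``; lines starting with ``#`` are comments."""
    df = pd.read_csv(path, comment="#")
    missing = {"probability", "concentration_ratio"} - set(df.columns)
    if missing:
        raise ValueError(f"paired-series CSV missing columns: {sorted(missing)}")
    return PairedSeries(
        probabilities=df["probability"].to_numpy(dtype=float),
        concentrations=df["concentration_ratio"].to_numpy(dtype=float),
    )
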