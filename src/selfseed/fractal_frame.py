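"""Fractal space-time coordinate frame.

The model describes cell migration in an anisotropic, heterogeneous medium
by rescaling each physical coordinate with its own fractal exponent:

    r_i = x_i ** beta_i        (fractal lengths)
    t_hat = t ** alpha         (fractal time, the "internal clock")

With ``alpha = beta_i = 1`` the frame is the identity and the model reduces
to classical diffusion.  Exponents below 1 compress large displacements and
long times, producing sub-diffusive transport in physical coordinates.

Physical coordinates are only evaluated at non-negative positions in the
original figures; this module extends the power law to negative coordinates
as an odd function, ``x ** beta := sign(x) * |x| ** beta``, so that the
frame is symmetric about the origin and a point-source density satisfies
``p(r) = p(-r)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FractalExponents",
    "PhysicalPoint",
    "FractalPoint",
    "signed_power",
    "to_fractal",
    "from_fractal",
    "fractal_time",
    "quadratic_form",
]

#: Default time exponent used throughout the model simulations.
DEFAULT_ALPHA = 0.4
#: Default space exponent (applied to all three axes).
DEFAULT_BETA = 0.9


def _as_beta_triple(beta) -> tuple[float, float, float]:
    """Broadcast a scalar exponent to three axes, or validate a 3-vector."""
    arr = np.atleast_1d(np.asarray(beta, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.shape != (3,):
        raise ValueError(f"beta must be a scalar or length-3 vector, got shape {arr.shape}")
    return tuple(float(b) for b in arr)


@dataclass(frozen=True)
class FractalExponents:
    """Fractal scaling exponents: ``alpha`` for time, ``beta`` per space axis.

    Parameters
    ----------
    alpha
        Dimensionless time exponent, > 0.  Default 0.4.
    beta
        Dimensionless space exponents, one per axis; a scalar is broadcast
        to all three axes.  Default 0.9.
    """

    alpha: float = DEFAULT_ALPHA
    beta: tuple[float, float, float] = field(default=(DEFAULT_BETA,) * 3)

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", _as_beta_triple(self.beta))
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not all(b > 0 for b in self.beta):
            raise ValueError(f"all beta_i must be > 0, got {self.beta}")

    @property
    def is_classical(self) -> bool:
        """True when alpha = beta_i = 1, i.e. the frame is the identity."""
        return self.alpha == 1.0 and all(b == 1.0 for b in self.beta)


@dataclass(frozen=True)
class PhysicalPoint:
    """A point in physical coordinates: lengths in mm, time in days."""

    x1: float
    x2: float
    x3: float
    t: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"time must be non-negative, got t={self.t}")

    @property
    def x(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3], dtype=float)


@dataclass(frozen=True)
class FractalPoint:
    """A point in fractal coordinates (fractal lengths, fractal time)."""

    r1: float
    r2: float
    r3: float
    t_hat: float

    def __post_init__(self) -> None:
        if self.t_hat < 0:
            raise ValueError(f"fractal time must be non-negative, got {self.t_hat}")
        if not np.all(np.isfinite([self.r1, self.r2, self.r3])):
            raise ValueError("fractal coordinates must be finite")

    @property
    def r(self) -> np.ndarray:
        return np.array([self.r1, self.r2, self.r3], dtype=float)


def signed_power(x, exponent):
    """Odd-symmetric power ``sign(x) * |x| ** exponent``; vectorized."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.abs(x) ** exponent


def fractal_time(t, alpha: float):
    """Map physical time to the internal clock, ``t_hat = t ** alpha``.

    Strictly increasing in ``t``; vectorized over ``t``.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = t**alpha
    return float(out) if out.ndim == 0 else out


def to_fractal(point: PhysicalPoint, exponents: FractalExponents) -> FractalPoint:
    """Transform a physical point into the fractal frame."""
    r = signed_power(point.x, np.asarray(exponents.beta))
    return FractalPoint(float(r[0]), float(r[1]), float(r[2]), fractal_time(point.t, exponents.alpha))


def from_fractal(point: FractalPoint, exponents: FractalExponents) -> PhysicalPoint:
    """Inverse transform; ``from_fractal(to_fractal(p)) == p`` up to rounding."""
    beta = np.asarray(exponents.beta)
    x = signed_power(point.r, 1.0 / beta)
    return PhysicalPoint(float(x[0]), float(x[1]), float(x[2]), point.t_hat ** (1.0 / exponents.alpha))


def quadratic_form(r, tensor) -> float:
    """Mahalanobis-type exponent argument ``Q = sum_i r_i**2 / D_ii``.

    ``r`` is a :class:`FractalPoint` or a length-3 vector of fractal
    lengths; ``tensor`` is a diagonal diffusion tensor (anything with
    ``d11``, ``d22``, ``d33`` attributes, or a length-3 positive vector).
    Q >= 0, with Q = 0 iff r = 0; even in each coordinate.
    """
    if isinstance(r, FractalPoint):
        r = r.r
    r = np.asarray(r, dtype=float)
    if hasattr(tensor, "d11"):
        diag = np.array([tensor.d11, tensor.d22, tensor.d33], dtype=float)
    else:
        diag = np.asarray(tensor, dtype=float)
    if diag.shape != (3,) or np.any(diag <= 0):
        raise ValueError(f"diffusion tensor diagonal must be 3 positive entries, got {diag}")
    return float(np.sum(r**2 / diag))
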