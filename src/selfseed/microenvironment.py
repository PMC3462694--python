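"""Stokes-Einstein coupling of microenvironment viscosity to diffusion.

The diffusion coefficient of a particle of radius r in a medium of dynamic
viscosity eta at absolute temperature T is

    D = k_B * T / (6 pi eta r)      [m^2/s]

with the exact SI Boltzmann constant.  The model uses this to predict that
raising the viscosity of the medium around a tumor (e.g. by injected
filler gels) lowers the cells' diffusion coefficient and hence their
migration.  The relation is stated for colloidal particles; applying it to
~10 um cells is a deliberate modelling idealization, so no default radius
is supplied — it must be given explicitly.

Viscosities are commonly reported in poise (1 P = 0.1 Pa*s exactly); a
converter is provided, as is a helper turning an SI diffusion coefficient
into the model's mm^2/day units and an isotropic diffusion tensor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffusion_model import DiffusionTensor

__all__ = [
    "BOLTZMANN_CONSTANT",
    "M2_PER_S_TO_MM2_PER_DAY",
    "Microenvironment",
    "stokes_einstein",
    "poise_to_pa_s",
    "diffusion_to_model_units",
    "tensor_from_environment",
    "compare_conditions",
]

BOLTZMANN_CONSTANT = 1.380649e-23  # J/K, exact SI
M2_PER_S_TO_MM2_PER_DAY = 8.64e10  # 1e6 mm^2/m^2 * 86400 s/day


@dataclass(frozen=True)
class Microenvironment:
    """Physical state of the medium a cell diffuses through.

    Parameters
    ----------
    temperature
        Absolute temperature in kelvin (> 0).
    viscosity
        Dynamic viscosity in Pa*s (> 0); use :func:`poise_to_pa_s` for
        values reported in poise.
    radius
        Particle (cell) radius in metres (> 0).  No default on purpose:
        the model supplies no canonical cell radius.
    """

    temperature: float
    viscosity: float
    radius: float

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.viscosity <= 0:
            raise ValueError(f"viscosity must be > 0 Pa*s, got {self.viscosity}")
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0 m, got {self.radius}")


def poise_to_pa_s(value: float) -> float:
    """Convert dynamic viscosity from poise to Pa*s (1 P = 0.1 Pa*s exactly)."""
    if value < 0:
        raise ValueError(f"viscosity cannot be negative, got {value} P")
    return 0.1 * value


def stokes_einstein(env: Microenvironment) -> float:
    """Diffusion coefficient D = k_B T / (6 pi eta r) in m^2/s."""
    return BOLTZMANN_CONSTANT * env.temperature / (6.0 * math.pi * env.viscosity * env.radius)


def diffusion_to_model_units(d_m2_per_s: float) -> float:
    """Convert an SI diffusion coefficient to mm^2/day.

    The model core works in fractal units (mm^(2*beta) per day^alpha); the
    numeric value carries over unchanged under the convention that model
    quantities are numerically consistent, so this helper only rescales the
    SI magnitude to the mm/day scale.
    """
    if d_m2_per_s < 0:
        raise ValueError("diffusion coefficient cannot be negative")
    return d_m2_per_s * M2_PER_S_TO_MM2_PER_DAY


def tensor_from_environment(env: Microenvironment) -> DiffusionTensor:
    """Isotropic model-unit diffusion tensor implied by Stokes-Einstein."""
    return DiffusionTensor.isotropic(diffusion_to_model_units(stokes_einstein(env)))


def compare_conditions(envs: list[Microenvironment]) -> pd.DataFrame:
    """Rank microenvironments by predicted diffusion coefficient.

    Returns a DataFrame (one row per environment, input order) with the
    viscosity, the Stokes-Einstein ``D`` in m^2/s, and ``rank`` (1 = fastest
    diffusion).  At fixed temperature and radius the ranking is strictly
    anti-monotone in viscosity: stiffer media immobilize cells.
    """
    if len(envs) < 2:
        raise ValueError("need at least 2 environments to compare")
    d_values = np.array([stokes_einstein(e) for e in envs])
    order = np.argsort(-d_values, kind="stable")
    rank = np.empty(len(envs), dtype=int)
    rank[order] = np.arange(1, len(envs) + 1)
    return pd.DataFrame(
        {
            "temperature_K": [e.temperature for e in envs],
            "viscosity_pa_s": [e.viscosity for e in envs],
            "radius_m": [e.radius for e in envs],
            "diffusion_m2_per_s": d_values,
            "rank": rank,
        }
    )
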