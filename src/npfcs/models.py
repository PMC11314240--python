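"""Closed-form FCS correlation models and physical conversions.

The fluorescence correlation function of ``m`` freely diffusing species
with per-particle brightness :math:`Q_i` and number fraction :math:`X_i`
in a 3D-Gaussian detection volume is

.. math::

    G(\\tau) = \\frac{\\sum_i Q_i^2 X_i g_i(\\tau)}
                    {N \\left(\\sum_i Q_i X_i\\right)^2},
    \\qquad
    g_i(\\tau) = \\left(1+\\frac{\\tau}{\\tau_{D,i}}\\right)^{-1}
                 \\left(1+\\frac{\\tau}{S^2\\tau_{D,i}}\\right)^{-1/2}

with ``N`` the mean total particle number in the detection volume and
``S`` its axial/lateral aspect ratio.  The convention used throughout is
the normalized fluctuation correlation without a +1 baseline, so a single
species gives ``G(0) = 1/N`` exactly.

For a monomer/aggregate mixture the aggregate brightness is assumed to
scale with the number of comprised monomers, i.e. with particle volume,
so the brightness ratio equals the cube of the diameter ratio
(:func:`two_population_G`).  Diffusion times account for the finite
particle size relative to the detection volume,

.. math:: \\tau_D = \\frac{\\omega_0^2 + (d/2)^2}{4D},

which is meaningful only for ``d <= 2 omega0``; larger fitted diameters
carry a validity flag.  Diffusion coefficients follow the Stokes-Einstein
relation ``D = kB T / (3 pi eta d)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "K_B",
    "N_A",
    "ETA_WATER_21C",
    "ROOM_TEMPERATURE_K",
    "DetectionVolume",
    "PhysicalConditions",
    "Population",
    "ModelParams",
    "single_species_g",
    "multi_species_G",
    "two_population_G",
    "diffusion_coefficient",
    "diffusion_time",
    "diameter_from_diffusion_time",
    "volume_fraction",
    "number_concentration",
    "effective_volume",
]

#: Boltzmann constant, J/K (CODATA, exact since SI 2019).
K_B = 1.380649e-23
#: Avogadro constant, 1/mol (exact).
N_A = 6.02214076e23
#: Dynamic viscosity of water at 21 degC, Pa s; default solvent viscosity.
ETA_WATER_21C = 0.978e-3
#: Laboratory temperature of 21 degC in kelvin.
ROOM_TEMPERATURE_K = 294.15


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectionVolume:
    """Calibrated confocal observation volume.

    Parameters
    ----------
    omega0 : float
        Lateral 1/e^2 radius of the Gaussian detection volume, in metres.
    aspect_ratio : float
        Axial over lateral extent ``S`` (dimensionless, >= 1).
    """

    omega0: float
    aspect_ratio: float

    def __post_init__(self) -> None:
        if not (self.omega0 > 0):
            raise ValidationError(f"omega0 must be positive, got {self.omega0}")
        if not (self.aspect_ratio >= 1):
            raise ValidationError(
                f"aspect ratio must be >= 1, got {self.aspect_ratio}"
            )


@dataclass(frozen=True)
class PhysicalConditions:
    """Absolute temperature (K) and dynamic solution viscosity (Pa s)."""

    temperature: float = ROOM_TEMPERATURE_K
    viscosity: float = ETA_WATER_21C

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValidationError("temperature must be positive (kelvin)")
        if not (self.viscosity > 0):
            raise ValidationError("viscosity must be positive (Pa s)")


@dataclass(frozen=True)
class Population:
    """One diffusing species: hydrodynamic diameter (m), number fraction,
    and detected photon rate per particle at the focus centre (counts/s)."""

    diameter: float
    number_fraction: float
    brightness: float

    def __post_init__(self) -> None:
        if not (self.diameter > 0):
            raise ValidationError("diameter must be positive")
        if not (0.0 <= self.number_fraction <= 1.0):
            raise ValidationError("number fraction must lie in [0, 1]")
        if not (self.brightness >= 0):
            raise ValidationError("brightness must be non-negative")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the monomer/aggregate two-population model.

    ``N`` is the mean total particle number in the detection volume,
    ``Xa`` the aggregate number fraction, ``d1``/``da`` the hydrodynamic
    diameters (m) of the small population and the aggregates.
    """

    N: float
    Xa: float
    d1: float
    da: float

    def __post_init__(self) -> None:
        if not (self.N > 0):
            raise ValidationError("N must be positive")
        if not (0.0 <= self.Xa <= 1.0):
            raise ValidationError("Xa must lie in [0, 1]")
        if not (self.d1 > 0):
            raise ValidationError("d1 must be positive")
        if not (self.da >= self.d1):
            raise ValidationError(
                f"aggregate diameter da={self.da} must be >= d1={self.d1}"
            )


# ---------------------------------------------------------------------------
# Correlation models
# ---------------------------------------------------------------------------


def single_species_g(tau, tau_d: float, aspect_ratio: float):
    """Normalized single-species 3D diffusion decay ``g(tau)``.

    ``g(0) = 1`` and ``g`` decreases strictly monotonically to zero.

    Parameters
    ----------
    tau : array_like
        Lag times in seconds, >= 0.
    tau_d : float
        Diffusion time in seconds, > 0.
    aspect_ratio : float
        Detection-volume aspect ratio ``S`` >= 1.
    """
    if not (tau_d > 0):
        raise ValidationError(f"tau_d must be positive, got {tau_d}")
    if not (aspect_ratio >= 1):
        raise ValidationError(f"aspect ratio must be >= 1, got {aspect_ratio}")
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValidationError("lag times must be non-negative")
    x = tau / tau_d
    return 1.0 / (1.0 + x) / np.sqrt(1.0 + x / aspect_ratio**2)


def multi_species_G(
    tau,
    populations: Sequence[Population],
    N: float,
    volume: DetectionVolume,
    conditions: PhysicalConditions,
    fraction_tol: float = 1e-8,
):
    """Brightness-weighted multi-species correlation function.

    Evaluates ``G(tau) = sum_i Qi^2 Xi gi(tau) / (N (sum_i Qi Xi)^2)``
    with each diffusion time computed from the species diameter via the
    finite-size expression and Stokes-Einstein.
    """
    if not populations:
        raise ValidationError("at least one population is required")
    if not (N > 0):
        raise ValidationError("N must be positive")
    fractions = np.array([p.number_fraction for p in populations])
    if abs(fractions.sum() - 1.0) > fraction_tol:
        raise ValidationError(
            f"number fractions must sum to 1, got {fractions.sum()!r}"
        )
    tau = np.asarray(tau, dtype=float)
    num = np.zeros_like(tau, dtype=float)
    monitor = 0.0
    for pop in populations:
        tau_d, _ = diffusion_time(pop.diameter, volume, conditions)
        g = single_species_g(tau, tau_d, volume.aspect_ratio)
        num = num + pop.brightness**2 * pop.number_fraction * g
        monitor += pop.brightness * pop.number_fraction
    if monitor <= 0:
        raise ValidationError("total brightness must be positive")
    return num / (N * monitor**2)


def two_population_G(
    tau,
    params: ModelParams,
    volume: DetectionVolume,
    conditions: PhysicalConditions,
):
    """Monomer/aggregate correlation model with volume-scaled brightness.

    Rewrites the multi-species model with the aggregate brightness tied to
    its volume, ``Qa/Q1 = (da/d1)^3``:

    .. math::

        G(\\tau) = \\frac{(1-X_a)\\,g_1(\\tau) + X_a (d_a/d_1)^6 g_a(\\tau)}
                        {N\\,[\\,1-X_a+X_a (d_a/d_1)^3\\,]^2}

    With ``Xa = 0`` (or ``da = d1``) this reduces exactly to the
    single-population model ``g1(tau)/N``.
    """
    tau = np.asarray(tau, dtype=float)
    r3 = (params.da / params.d1) ** 3
    tau_d1, _ = diffusion_time(params.d1, volume, conditions)
    tau_da, _ = diffusion_time(params.da, volume, conditions)
    g1 = single_species_g(tau, tau_d1, volume.aspect_ratio)
    ga = single_species_g(tau, tau_da, volume.aspect_ratio)
    weight = 1.0 - params.Xa + params.Xa * r3
    return ((1.0 - params.Xa) * g1 + params.Xa * r3**2 * ga) / (
        params.N * weight**2
    )


# ---------------------------------------------------------------------------
# Physical conversions
# ---------------------------------------------------------------------------


def diffusion_coefficient(d: float, conditions: PhysicalConditions) -> float:
    """Stokes-Einstein diffusion coefficient ``kB T / (3 pi eta d)`` in m^2/s."""
    if not (d > 0):
        raise ValidationError(f"diameter must be positive, got {d}")
    return K_B * conditions.temperature / (3.0 * math.pi * conditions.viscosity * d)


def diffusion_time(
    d: float, volume: DetectionVolume, conditions: PhysicalConditions
) -> tuple[float, bool]:
    """Diffusion time for a particle of finite diameter ``d``.

    Returns ``(tau_d, valid)`` where
    ``tau_d = (omega0^2 + (d/2)^2) / (4 D)`` and ``valid`` is False when
    ``d > 2 omega0``, outside the expression's range of validity.  Sizes
    beyond that limit should be taken with precaution, not rejected.
    """
    D = diffusion_coefficient(d, conditions)
    tau_d = (volume.omega0**2 + (0.5 * d) ** 2) / (4.0 * D)
    return tau_d, bool(d <= 2.0 * volume.omega0)


def diameter_from_diffusion_time(
    tau_d: float, volume: DetectionVolume, conditions: PhysicalConditions
) -> float:
    """Invert the finite-size diffusion-time expression for the diameter.

    Substituting Stokes-Einstein turns ``tau_d(d)`` into the strictly
    increasing cubic ``d^3 + 4 omega0^2 d = 16 kB T tau_d / (3 pi eta)``,
    solved in closed form (single real root, hyperbolic Cardano).
    """
    if not (tau_d > 0):
        raise ValidationError(f"tau_d must be positive, got {tau_d}")
    p = 4.0 * volume.omega0**2
    rhs = (
        16.0
        * K_B
        * conditions.temperature
        * tau_d
        / (3.0 * math.pi * conditions.viscosity)
    )
    # d^3 + p d - rhs = 0, p > 0: unique real root.
    arg = 1.5 * rhs / p * math.sqrt(3.0 / p)
    d = 2.0 * math.sqrt(p / 3.0) * math.sinh(math.asinh(arg) / 3.0)
    if not (d > 0 and math.isfinite(d)):
        raise ValidationError(
            f"diameter inversion failed for tau_d={tau_d} (got {d})"
        )
    return d


def volume_fraction(Xa: float, d1: float, da: float) -> float:
    """Volume share of fluorescent material residing in aggregates.

    ``phi_a = Xa da^3 / (Xa da^3 + (1-Xa) d1^3)``; lies in [0, 1] and is
    >= Xa whenever ``da >= d1``, making it far more sensitive to the onset
    of aggregation than the number fraction itself.
    """
    if not (0.0 <= Xa <= 1.0):
        raise ValidationError("Xa must lie in [0, 1]")
    if not (d1 > 0 and da >= d1):
        raise ValidationError("require da >= d1 > 0")
    va = Xa * da**3
    return va / (va + (1.0 - Xa) * d1**3)


def number_concentration(molar: float) -> float:
    """Convert a molar concentration (mol/L) to particles per mL."""
    if molar < 0:
        raise ValidationError("concentration must be non-negative")
    return molar * N_A / 1000.0


def effective_volume(volume: DetectionVolume) -> float:
    """Effective 3D-Gaussian detection volume ``pi^{3/2} S omega0^3`` (m^3).

    The expected particle number at molar concentration ``C`` is
    ``C * N_A * 1000 * effective_volume`` (concentration in mol/L).
    """
    return math.pi**1.5 * volume.aspect_ratio * volume.omega0**3
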