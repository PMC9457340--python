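"""Microscopic interaction layer.

Long-range dispersion attraction between a fluid molecule and the particle
interface, the resulting inverse-cube interface potential, the linearized
density profile of the gas-like phase, and the radial force one
phase-separated cluster exerts on another through the particle-number
gradient.

Distances are in metres and energies in joules throughout; the single
radial coordinate plays the role of both the wall distance and the mean
relative cluster separation (the long-range limit collapses the two).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .params import KB, InvalidParameterError

__all__ = [
    "MechanismParams",
    "lj_attractive",
    "interface_potential",
    "density_profile",
    "number_gradient",
    "cluster_force",
    "cluster_force_thermal",
]


@dataclass(frozen=True)
class MechanismParams:
    """Interface-layer parameters.

    epsilon : dispersion energy, J.
    sigma : Van der Waals contact distance, m.
    rho_s : fluid density at the interface (gas-like side), m⁻³.
    rho_L : density of the incompressible (gel-like) phase, m⁻³.
    radius : cluster radius, m.
    """

    epsilon: float
    sigma: float
    rho_s: float
    rho_L: float
    radius: float

    def __post_init__(self) -> None:
        for name in ("epsilon", "sigma", "radius"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive")
        if not (self.rho_s > 0 and self.rho_L > 0):
            raise InvalidParameterError("densities must be positive")
        if not self.rho_s < self.rho_L:
            raise InvalidParameterError(
                "rho_s must be below rho_L (gas-like interface density "
                "under a denser gel phase)"
            )

    @classmethod
    def from_config(cls, block: dict) -> "MechanismParams":
        try:
            return cls(
                epsilon=float(block["epsilon_J"]),
                sigma=float(block["sigma_nm"]) * 1e-9,
                rho_s=float(block["rho_s"]),
                rho_L=float(block["rho_L"]),
                radius=float(block["radius_nm"]) * 1e-9,
            )
        except KeyError as exc:
            raise InvalidParameterError(
                f"mechanism config block missing key {exc.args[0]!r}"
            ) from exc


def _require_positive(r, name: str = "r"):
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise InvalidParameterError(f"{name} must be strictly positive")
    return r


def lj_attractive(r, p: MechanismParams):
    """Attractive (r⁻⁶) branch of the pair potential: ``−4ε(σ/r)⁶``, J."""
    r = _require_positive(r)
    return -4.0 * p.epsilon * (p.sigma / r) ** 6


def interface_potential(z, p: MechanismParams):
    """Inverse-cube wall potential ``−(4π/3)·ε·σ⁶·ρs / z³``, J.

    The prefactor is kept exactly as the model states it; the independent
    half-space integration of the pair potential differs by a constant
    factor (see package notes) but shares the z⁻³ law, which is what the
    downstream derivation uses.
    """
    z = _require_positive(z, "z")
    return -(4.0 * math.pi / 3.0) * p.epsilon * p.sigma**6 * p.rho_s / z**3


def density_profile(r, p: MechanismParams, T: float, linearized: bool = True):
    """Fluid density of the gas-like phase at radial distance ``r``, m⁻³.

    Linearized Boltzmann profile ``ρL + (ρs − ρL)(σ/r)³``; valid where the
    interface potential is small against kB·T (a diagnostic warning is
    emitted otherwise).  ``linearized=False`` evaluates the full
    exponential profile for comparison.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < p.sigma):
        raise InvalidParameterError("r must be at least sigma")
    if not T > 0:
        raise InvalidParameterError("T must be positive")
    v_over_kt = np.abs(interface_potential(r, p)) / (KB * T)
    if np.any(v_over_kt > 0.1):
        warnings.warn(
            "interface potential exceeds 0.1 kBT: linearized density "
            "profile is outside its stated validity range",
            stacklevel=2,
        )
    if linearized:
        return p.rho_L + (p.rho_s - p.rho_L) * (p.sigma / r) ** 3
    scale = (p.rho_s - p.rho_L) / (
        math.exp(-interface_potential(p.sigma, p) / (KB * T)) - 1.0
    )
    return p.rho_L + scale * np.expm1(-interface_potential(r, p) / (KB * T))


def number_gradient(r, Z: float):
    """Radial gradient of the interaction-corrected particle number: ``−Z/r``."""
    r = _require_positive(r)
    if not Z > 0:
        raise InvalidParameterError("Z must be positive")
    return -Z / r


def cluster_force(r, Z: float, T: float):
    """Signed radial force between clusters, N.

    Magnitude ``kB·T/(r·Z)``; the sign is negative along the relative
    separation (attraction).  The self-force of a cluster on itself
    vanishes by symmetry and is not represented here.
    """
    r = _require_positive(r)
    if not Z > 0:
        raise InvalidParameterError("Z must be positive")
    if not T > 0:
        raise InvalidParameterError("T must be positive")
    return -KB * T / (r * Z)


def cluster_force_thermal(r_um, Z: float):
    """Cluster force in thermal units kB·T/μm, for the dimensionless
    Langevin layer: magnitude ``1/(r[μm]·Z)``, sign attractive."""
    r_um = _require_positive(r_um, "r_um")
    if not Z > 0:
        raise InvalidParameterError("Z must be positive")
    return -1.0 / (r_um * Z)
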