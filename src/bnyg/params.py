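"""Physical constants, unit handling, and the diffusivity algebra.

All quantities are stored in SI internally; diffusivities cross the module
boundary in μm²/s, which is the unit every other module works in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "KB",
    "WATER_VISCOSITY_PAS",
    "PhysicalParams",
    "PhaseParams",
    "InvalidParameterError",
    "NoPhaseSeparationError",
    "einstein_diffusivity",
    "effective_diffusivity",
    "average_diffusivity",
    "infer_liquid_phase",
]

#: Boltzmann constant, J/K (SI exact).
KB = 1.380649e-23

#: Reference shear viscosity of bulk water, Pa·s.  A documented convention,
#: not a measured input: 1.0 mPa·s at the working temperature.
WATER_VISCOSITY_PAS = 1.0e-3

#: m²/s → μm²/s
_M2S_TO_UM2S = 1.0e12


class InvalidParameterError(ValueError):
    """A physical parameter is outside its valid domain."""


class NoPhaseSeparationError(ValueError):
    """The measured average diffusivity admits no liquid phase faster than
    the gas phase — the regular-Brownian-motion regime."""


@dataclass(frozen=True)
class PhysicalParams:
    """Medium and particle parameters entering the Einstein relation.

    Parameters
    ----------
    temperature : float
        Absolute temperature, K.
    viscosity_multiplier : float
        Shear viscosity of the medium in units of ``eta_water``.
    radius : float
        Brownian-particle radius, m.
    eta_water : float, optional
        Bulk-water shear viscosity reference, Pa·s.
    boltzmann : float, optional
        Boltzmann constant, J/K.
    """

    temperature: float
    viscosity_multiplier: float
    radius: float
    eta_water: float = WATER_VISCOSITY_PAS
    boltzmann: float = KB

    def __post_init__(self) -> None:
        for name in ("temperature", "viscosity_multiplier", "radius",
                     "eta_water", "boltzmann"):
            value = getattr(self, name)
            if not (value > 0.0 and math.isfinite(value)):
                raise InvalidParameterError(
                    f"{name} must be strictly positive and finite, got {value!r}"
                )

    @property
    def eta(self) -> float:
        """Shear viscosity of the medium, Pa·s."""
        return self.eta_water * self.viscosity_multiplier

    def with_viscosity_multiplier(self, multiplier: float) -> "PhysicalParams":
        return replace(self, viscosity_multiplier=multiplier)

    @classmethod
    def from_config(cls, block: dict) -> "PhysicalParams":
        """Build from a ``physical:`` config block.

        Expected keys: ``temperature_C``, ``water_viscosity_mPas``,
        ``viscosity_multiplier``, ``radius_nm``.
        """
        try:
            return cls(
                temperature=float(block["temperature_C"]) + 273.15,
                viscosity_multiplier=float(block["viscosity_multiplier"]),
                radius=float(block["radius_nm"]) * 1e-9,
                eta_water=float(block.get("water_viscosity_mPas", 1.0)) * 1e-3,
            )
        except KeyError as exc:
            raise InvalidParameterError(
                f"physical config block missing key {exc.args[0]!r}"
            ) from exc


@dataclass(frozen=True)
class PhaseParams:
    """Diffusivities and compressibility factors of the two-phase process.

    The six diffusivity fields are mutually redundant; consistency is
    enforced at construction.  ``D`` is the bare (Einstein) diffusivity,
    ``Z_G``/``Z_L`` the gas- and liquid-phase compressibility factors,
    ``DeffG = D/Z_G²``, ``DeffL = D/Z_L²``, ``Davg = (DeffG + DeffL)/2``,
    and ``tc`` the critical time at which the gas-like regime ends.
    All diffusivities in μm²/s, ``tc`` in seconds.
    """

    D: float
    Z_G: float
    Z_L: float
    DeffG: float = field(default=math.nan)
    DeffL: float = field(default=math.nan)
    Davg: float = field(default=math.nan)
    tc: float = 1.0

    _RTOL = 1e-6

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise InvalidParameterError(f"D must be positive, got {self.D!r}")
        if not (0 < self.Z_L and 0 < self.Z_G):
            raise InvalidParameterError("compressibility factors must be positive")
        if not self.tc > 0:
            raise InvalidParameterError(f"tc must be positive, got {self.tc!r}")
        # fill derived fields if not given; verify when given
        derived = {
            "DeffG": self.D / self.Z_G**2,
            "DeffL": self.D / self.Z_L**2,
        }
        derived["Davg"] = 0.5 * (derived["DeffG"] + derived["DeffL"])
        for name, expected in derived.items():
            value = getattr(self, name)
            if math.isnan(value):
                object.__setattr__(self, name, expected)
            elif not math.isclose(value, expected, rel_tol=self._RTOL):
                raise InvalidParameterError(
                    f"inconsistent {name}: got {value!r}, expected {expected!r}"
                )

    @classmethod
    def from_compressibility(cls, D: float, Z_G: float, Z_L: float,
                             tc: float) -> "PhaseParams":
        return cls(D=D, Z_G=Z_G, Z_L=Z_L, tc=tc)


def einstein_diffusivity(params: PhysicalParams, extensional: bool = True) -> float:
    """Stokes–Einstein diffusivity, in μm²/s.

    With ``extensional=True`` the denominator uses the extensional viscosity
    of a Newtonian fluid (three times the shear viscosity), giving
    ``kB·T / (18π·η·R)``; otherwise the familiar ``kB·T / (6π·η·R)``.
    """
    denominator = (18.0 if extensional else 6.0) * math.pi * params.eta * params.radius
    return params.boltzmann * params.temperature / denominator * _M2S_TO_UM2S


def effective_diffusivity(D: float, Z: float) -> float:
    """Phase effective diffusivity ``D / Z²`` (μm²/s)."""
    if not D > 0:
        raise InvalidParameterError(f"D must be positive, got {D!r}")
    if Z == 0:
        raise InvalidParameterError("Z must be nonzero")
    if not Z > 0:
        raise InvalidParameterError(f"Z must be positive, got {Z!r}")
    return D / Z**2


def average_diffusivity(DeffG: float, DeffL: float) -> float:
    """Equal-weight average of the two phase diffusivities (μm²/s)."""
    if DeffG < 0 or DeffL < 0:
        raise InvalidParameterError("effective diffusivities must be nonnegative")
    return 0.5 * (DeffG + DeffL)


def infer_liquid_phase(Davg: float, D: float, Z_G: float = 1.0,
                       tc: float = 1.0) -> PhaseParams:
    """Invert the equal-weight average for the liquid-phase parameters.

    Given the measured ``Davg`` and the bare diffusivity ``D`` (with the
    gas phase treated as an ideal gas unless ``Z_G`` says otherwise),
    solve ``Davg = (D/Z_G² + DeffL)/2`` for ``DeffL`` and
    ``Z_L = sqrt(D/DeffL)``.

    Raises
    ------
    NoPhaseSeparationError
        If ``Davg ≤ DeffG/2`` — there is no liquid phase faster than the
        gas phase and the process is regular Brownian motion.
    """
    if not (Davg > 0 and D > 0 and Z_G > 0):
        raise InvalidParameterError("Davg, D, Z_G must all be positive")
    DeffG = D / Z_G**2
    if not Davg > 0.5 * DeffG:
        raise NoPhaseSeparationError(
            f"Davg={Davg} is not above DeffG/2={0.5 * DeffG}: "
            "no phase separation (regular Brownian motion)"
        )
    DeffL = 2.0 * Davg - DeffG
    Z_L = math.sqrt(D / DeffL)
    return PhaseParams(D=D, Z_G=Z_G, Z_L=Z_L, tc=tc)
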