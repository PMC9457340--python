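"""Closed-form displacement statistics of the two-regime process.

The gas-like regime is an overdamped diffusion with constant-magnitude
drift toward the origin (dry friction); its stationary law is Laplace with
scale λ(t) = sqrt(Deff·t).  Past the critical time tc the drift is
negligible and the Laplace law relaxes under free diffusion with the
liquid-phase diffusivity, giving a Laplace⊛Gaussian transition density.
Externally visible densities are variance-rescaled to 2·Davg·t so that the
mean squared displacement of the observed process is linear in time with
the equal-weight average diffusivity.

Lengths in μm, times in s; the dry-friction propagator alone is
dimensionless (length unit D/μ, time unit D/μ² for drift magnitude μ and
microscopic diffusivity D).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import erfc, erfcx

from .params import InvalidParameterError, PhaseParams

__all__ = [
    "DisplacementPDF",
    "PropagatorQuery",
    "dry_friction_propagator",
    "laplace_pdf",
    "laplace_scale",
    "transition_pdf",
    "transition_variance",
    "transition_excess_kurtosis",
    "msd",
    "observed_pdf",
    "observed_curve",
    "gaussianity_time",
    "rms_relative_distance",
]


@dataclass(frozen=True)
class PropagatorQuery:
    """Dimensionless evaluation point of the dry-friction propagator."""

    r: float
    r0: float
    tau: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise InvalidParameterError(f"tau must be positive, got {self.tau!r}")


@dataclass(frozen=True)
class DisplacementPDF:
    """A displacement density sampled on a symmetric 1-D grid.

    ``grid`` in μm, ``density`` in μm⁻¹, ``time`` the physical time stamp
    in s, ``regime_label`` one of ``gas``, ``transition``, ``mixture``.
    """

    grid: np.ndarray
    density: np.ndarray
    time: float
    regime_label: str

    def mass(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def moment(self, order: int) -> float:
        return float(np.trapezoid(self.grid**order * self.density, self.grid))

    def variance(self) -> float:
        m = self.mass()
        mu = self.moment(1) / m
        return self.moment(2) / m - mu**2

    def excess_kurtosis(self) -> float:
        m = self.mass()
        m2 = self.moment(2) / m
        m4 = self.moment(4) / m
        return m4 / m2**2 - 3.0

    def rescaled_to_variance(self, target: float) -> "DisplacementPDF":
        """Affine change of variable preserving unit mass and shape."""
        if not target > 0:
            raise InvalidParameterError("target variance must be positive")
        c = math.sqrt(target / self.variance())
        return replace(
            self,
            grid=self.grid * c,
            density=self.density / c,
        )


def dry_friction_propagator(r, tau=None, r0=0.0):
    """Transition density of ``dy = −sgn(y)·dτ + √2·dW`` started at ``r0``.

    Dimensionless units: length D/μ and time D/μ² for drift magnitude μ and
    microscopic diffusivity D.  Exact form: a drift-tilted Gaussian plus an
    erfc boundary-layer term whose τ→∞ limit is the Laplace law
    ``(1/2)·e^{−|r|}``.

    Accepts a :class:`PropagatorQuery` as ``r`` (then ``tau``/``r0`` are
    ignored), or array-like ``r`` with scalar ``tau``, ``r0``.
    """
    if isinstance(r, PropagatorQuery):
        r, tau, r0 = r.r, r.tau, r.r0
    if tau is None:
        raise InvalidParameterError("tau is required unless a query is given")
    if not tau > 0:
        raise InvalidParameterError(f"tau must be positive, got {tau!r}")
    r = np.asarray(r, dtype=float)
    a, a0 = np.abs(r), abs(r0)
    gaussian = (
        np.exp(-0.5 * (a - a0) - 0.25 * tau - (r - r0) ** 2 / (4.0 * tau))
        / math.sqrt(4.0 * math.pi * tau)
    )
    boundary = 0.25 * np.exp(-a) * erfc((a + a0 - tau) / (2.0 * math.sqrt(tau)))
    return gaussian + boundary


def laplace_scale(t: float, phase: PhaseParams, rescale: bool = True) -> float:
    """Laplace scale λ(t) in μm: sqrt(Davg·t) rescaled, sqrt(DeffG·t) bare."""
    if not t > 0:
        raise InvalidParameterError(f"t must be positive, got {t!r}")
    Deff = phase.Davg if rescale else phase.DeffG
    return math.sqrt(Deff * t)


def laplace_pdf(x, t: float, phase: PhaseParams, rescale: bool = True):
    """Gas-regime Laplace density ``(1/2λ)·e^{−|x|/λ}``, μm⁻¹.

    ``rescale=True`` uses λ = sqrt(Davg·t), pinning the variance to
    2·Davg·t; otherwise the bare gas-phase scale sqrt(DeffG·t).
    """
    lam = laplace_scale(t, phase, rescale)
    x = np.asarray(x, dtype=float)
    return np.exp(-np.abs(x) / lam) / (2.0 * lam)


def transition_variance(lambda0: float, DeffL: float, t_prime: float) -> float:
    """Variance 2λ0² + 2·DeffL·t′ of the un-rescaled transition density."""
    return 2.0 * lambda0**2 + 2.0 * DeffL * t_prime


def transition_excess_kurtosis(lambda0: float, DeffL: float, t_prime: float) -> float:
    """Excess kurtosis ``3·(2λ0²)² / (2λ0² + 2·DeffL·t′)²``.

    Cumulants add under convolution: the fourth cumulant is the Laplace
    component's 3·(2λ0²)², the variance is the sum.  Invariant under the
    affine variance rescale.
    """
    if lambda0 == 0.0:
        return 0.0
    v_l = 2.0 * lambda0**2
    return 3.0 * v_l**2 / (v_l + 2.0 * DeffL * t_prime) ** 2


def _laplace_gauss_density(x: np.ndarray, lam: float, s: float) -> np.ndarray:
    """Overflow-safe Laplace(λ)⊛Gaussian(variance s²) density.

    ``(1/4λ)·e^{s²/2λ²}·[e^{−x/λ}·erfc(s/√2λ − x/√2s)
                        + e^{x/λ}·erfc(s/√2λ + x/√2s)]``
    evaluated through the scaled complementary error function so the
    ``e^{s²/2λ²}`` factor (which alone can reach e^{10⁴}) never appears.
    """
    b_minus = s / (math.sqrt(2.0) * lam) - x / (math.sqrt(2.0) * s)
    b_plus = s / (math.sqrt(2.0) * lam) + x / (math.sqrt(2.0) * s)
    core = np.exp(-(x**2) / (2.0 * s**2))

    def term(b: np.ndarray, sign: float) -> np.ndarray:
        # e^{A}·erfc(b) with A = s²/2λ² + sign·x/λ; note A − b² = −x²/2s².
        out = np.empty_like(b)
        pos = b >= 0
        out[pos] = erfcx(b[pos]) * core[pos]
        # b < 0 ⇒ A < −s²/2λ² ≤ 0: direct evaluation is safe there.
        a_neg = s**2 / (2.0 * lam**2) + sign * x[~pos] / lam
        out[~pos] = np.exp(a_neg) * erfc(b[~pos])
        return out

    return (term(b_minus, -1.0) + term(b_plus, +1.0)) / (4.0 * lam)


def transition_pdf(x, t_prime: float, lambda0: float, DeffL: float,
                   rescale_to: float | None = None):
    """Laplace initial law relaxing under free diffusion, μm⁻¹.

    Exact convolution of Laplace(λ0) with a Gaussian of variance
    s² = 2·DeffL·t′.  ``t_prime=0`` returns the Laplace law itself.
    ``rescale_to`` optionally rescales the result to a target variance by
    an affine change of variable (shape preserving).
    """
    if t_prime < 0:
        raise InvalidParameterError(f"t_prime must be nonnegative, got {t_prime!r}")
    if not lambda0 > 0:
        raise InvalidParameterError(f"lambda0 must be positive, got {lambda0!r}")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    scale = 1.0
    if rescale_to is not None:
        if not rescale_to > 0:
            raise InvalidParameterError("rescale_to must be positive")
        scale = math.sqrt(rescale_to / transition_variance(lambda0, DeffL, t_prime))
    x_eval = x / scale
    if t_prime == 0.0:
        density = np.exp(-np.abs(x_eval) / lambda0) / (2.0 * lambda0)
    else:
        s = math.sqrt(2.0 * DeffL * t_prime)
        density = _laplace_gauss_density(x_eval, lambda0, s)
    return density / scale


def msd(t: float, phase: PhaseParams, dims: int = 1) -> float:
    """Mean squared displacement 2·Davg·t (1-D) or 6·Davg·t (3-D), μm²."""
    if t < 0:
        raise InvalidParameterError(f"t must be nonnegative, got {t!r}")
    if dims == 1:
        return 2.0 * phase.Davg * t
    if dims == 3:
        return 6.0 * phase.Davg * t
    raise InvalidParameterError(f"unsupported dims {dims!r}; use 1 or 3")


def observed_pdf(x, t: float, phase: PhaseParams):
    """Observed displacement density at time ``t``, μm⁻¹.

    Dispatches on the critical time: the rescaled Laplace law for
    ``t ≤ tc``; for later times the transition density built from the bare
    gas scale λ0 = sqrt(DeffG·tc), evolved for t − tc with DeffL and
    rescaled to variance 2·Davg·t.  Both branches carry variance
    2·Davg·t by construction.
    """
    if not t > 0:
        raise InvalidParameterError(f"t must be positive, got {t!r}")
    if t <= phase.tc:
        return laplace_pdf(x, t, phase, rescale=True)
    lambda0 = math.sqrt(phase.DeffG * phase.tc)
    return transition_pdf(x, t - phase.tc, lambda0, phase.DeffL,
                          rescale_to=msd(t, phase, dims=1))


def observed_curve(t: float, phase: PhaseParams, x_max: float | None = None,
                   n: int = 2**14 + 1) -> DisplacementPDF:
    """Evaluate :func:`observed_pdf` on a symmetric grid.

    Default half-width is sixteen standard deviations of the observed law
    (the Laplace tail still carries ~1e-5 beyond eight), with a grid fine
    enough that the trapezoidal mass is 1 within 1e-6.
    """
    if x_max is None:
        x_max = 16.0 * math.sqrt(msd(t, phase, dims=1))
    grid = np.linspace(-x_max, x_max, n)
    label = "gas" if t <= phase.tc else "transition"
    return DisplacementPDF(grid=grid, density=observed_pdf(grid, t, phase),
                           time=t, regime_label=label)


def gaussianity_time(phase: PhaseParams, threshold: float = 0.05) -> float:
    """Time past tc at which the transition law is effectively Gaussian, s.

    Smallest t′ with excess kurtosis 3·(2λ0²)²/(2λ0² + 2·DeffL·t′)² below
    ``threshold``, solved in closed form:
    t′ = λ0²·(sqrt(3/threshold) − 1)/DeffL with λ0² = DeffG·tc.
    """
    if not threshold > 0:
        raise InvalidParameterError("threshold must be positive")
    lambda0_sq = phase.DeffG * phase.tc
    if lambda0_sq == 0.0:
        return 0.0
    t_prime = lambda0_sq * (math.sqrt(3.0 / threshold) - 1.0) / phase.DeffL
    return max(t_prime, 0.0)


def rms_relative_distance(t: float, D: float, Z: float) -> float:
    """Root-mean-squared relative distance sqrt(2·(D/Z²)·t), μm."""
    if t < 0:
        raise InvalidParameterError(f"t must be nonnegative, got {t!r}")
    if Z == 0:
        raise InvalidParameterError("Z must be nonzero")
    return math.sqrt(2.0 * (D / Z**2) * t)
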