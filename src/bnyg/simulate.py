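"""Seeded Euler–Maruyama simulator of the two-regime Langevin process.

Each path is assigned to the gas-like or liquid state with probability 1/2
(the equal-weight state average), permanently: per-step switching would
change the mixture MSD.  Gas paths follow overdamped dry friction,
``dx = −μ(t)·sgn(x)·dt + sqrt(2·D_m)·dW``, with the drift magnitude
updated adiabatically so the instantaneous stationary scale is
λ(t) = sqrt(DeffG·t); at the critical time tc the drift is dropped and
they diffuse freely with DeffL.  Liquid paths diffuse freely with DeffL
throughout.

Only the ratio D_m/μ = λ is observable at the level of the displacement
law, so the simulator sets the microscopic diffusivity D_m equal to the
phase's effective diffusivity and derives μ(t) = D_m/λ(t).  λ(t) is
floored at λ(10·dt) so that the drift step μ·dt never exceeds a tenth of
the instantaneous stationary scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import InvalidParameterError, PhaseParams

__all__ = [
    "SimulationConfig",
    "TrajectoryEnsemble",
    "StabilityError",
    "simulate",
    "ensemble_stats",
    "fit_davg",
]

GAS, LIQUID = 0, 1
REGIME_NAMES = {GAS: "gas", LIQUID: "liquid"}

#: Drift step must stay below this fraction of the stationary scale.
DRIFT_STEP_FRACTION = 0.1


class StabilityError(ValueError):
    """The time step is too large for the dry-friction drift."""


@dataclass(frozen=True)
class SimulationConfig:
    """Ensemble simulation settings.

    ``drift_mode="adiabatic"`` is the full two-regime process;
    ``drift_mode="fixed"`` runs every path as dry friction with a constant
    scale ``lambda_fixed`` and no regime switch — the stationary-law test
    harness.
    """

    n_paths: int
    dt: float
    t_max: float
    seed: int
    phase: PhaseParams
    drift_mode: str = "adiabatic"
    record_stride: int = 1
    lambda_fixed: float | None = None

    def __post_init__(self) -> None:
        if self.n_paths < 1:
            raise InvalidParameterError("n_paths must be at least 1")
        if not self.dt > 0:
            raise InvalidParameterError("dt must be positive")
        if not self.t_max > 0:
            raise InvalidParameterError("t_max must be positive")
        if self.record_stride < 1:
            raise InvalidParameterError("record_stride must be at least 1")
        if self.drift_mode not in ("adiabatic", "fixed"):
            raise InvalidParameterError(
                f"drift_mode must be 'adiabatic' or 'fixed', got {self.drift_mode!r}"
            )
        if self.drift_mode == "adiabatic" and self.dt > 0.01 * self.phase.tc:
            raise InvalidParameterError(
                f"dt={self.dt} exceeds 0.01·tc={0.01 * self.phase.tc}"
            )
        if self.drift_mode == "fixed":
            if self.lambda_fixed is None or not self.lambda_fixed > 0:
                raise InvalidParameterError(
                    "drift_mode='fixed' requires a positive lambda_fixed"
                )
            # μ·dt = D_m·dt/λ must stay below DRIFT_STEP_FRACTION·λ
            if self.phase.DeffG * self.dt > (
                DRIFT_STEP_FRACTION * self.lambda_fixed**2
            ):
                suggested = DRIFT_STEP_FRACTION * self.lambda_fixed**2 / self.phase.DeffG
                raise StabilityError(
                    f"dt={self.dt} too large for drift scale "
                    f"lambda_fixed={self.lambda_fixed}; use dt <= {suggested:g}"
                )


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Recorded ensemble: ``positions`` is (n_paths, n_times) in μm."""

    times: np.ndarray
    positions: np.ndarray
    regime: np.ndarray  # int codes, see REGIME_NAMES
    seed: int

    def __post_init__(self) -> None:
        if self.positions.shape != (self.regime.size, self.times.size):
            raise InvalidParameterError("positions shape mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise InvalidParameterError("positions must be finite")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")

    @property
    def regime_labels(self) -> np.ndarray:
        return np.vectorize(REGIME_NAMES.get)(self.regime)


def simulate(config: SimulationConfig) -> TrajectoryEnsemble:
    """Run the seeded Euler–Maruyama ensemble."""
    rng = np.random.default_rng(config.seed)
    phase = config.phase
    n = config.n_paths
    dt = config.dt
    sqrt_dt = math.sqrt(dt)
    n_steps = int(round(config.t_max / dt))
    if n_steps < 1:
        raise InvalidParameterError("t_max must cover at least one step")

    fixed = config.drift_mode == "fixed"
    if fixed:
        regime = np.full(n, GAS, dtype=np.int8)
    else:
        regime = np.where(rng.random(n) < 0.5, GAS, LIQUID).astype(np.int8)
    gas = regime == GAS

    x = np.zeros(n)
    record_idx = np.arange(0, n_steps + 1, config.record_stride)
    if record_idx[-1] != n_steps:
        record_idx = np.append(record_idx, n_steps)
    times = record_idx * dt
    positions = np.empty((n, record_idx.size))
    positions[:, 0] = 0.0
    next_record = 1

    d_gas = phase.DeffG   # microscopic diffusivity of the dry-friction phase
    d_liq = phase.DeffL
    lam_floor = math.sqrt(d_gas * 10.0 * dt)
    noise_gas = math.sqrt(2.0 * d_gas)
    noise_liq = math.sqrt(2.0 * d_liq)

    for step in range(1, n_steps + 1):
        t_pre = (step - 1) * dt
        dw = rng.standard_normal(n) * sqrt_dt
        if fixed:
            lam = config.lambda_fixed
            mu = d_gas / lam
            x += -mu * np.sign(x) * dt + noise_gas * dw
        else:
            in_gas_regime = gas & (t_pre < phase.tc)
            lam = max(math.sqrt(d_gas * max(t_pre, 0.0)), lam_floor)
            mu = d_gas / lam
            drift = np.where(in_gas_regime, -mu * np.sign(x), 0.0)
            noise = np.where(in_gas_regime, noise_gas, noise_liq)
            x += drift * dt + noise * dw
        if next_record < record_idx.size and step == record_idx[next_record]:
            positions[:, next_record] = x
            next_record += 1

    return TrajectoryEnsemble(times=times, positions=positions,
                              regime=regime, seed=config.seed)


def ensemble_stats(ens: TrajectoryEnsemble, times, n_bins: int = 61) -> dict:
    """Per-time pooled summaries: MSD, excess kurtosis, histogram.

    ``times`` must match recorded times (within half a recording step).
    Returns ``{t: {"msd": ..., "excess_kurtosis": ..., "histogram":
    (bin_edges, density)}}``; histogram densities integrate to 1.
    """
    if ens.positions.size == 0:
        raise InvalidParameterError("empty ensemble")
    out = {}
    for t in np.atleast_1d(np.asarray(times, dtype=float)):
        idx = int(np.argmin(np.abs(ens.times - t)))
        tol = 1e-6 * max(1.0, abs(t))
        if abs(ens.times[idx] - t) > tol:
            raise InvalidParameterError(f"time {t} not among recorded times")
        x = ens.positions[:, idx]
        m2 = float(np.mean(x**2))
        kurt = float(np.mean(x**4) / m2**2 - 3.0) if m2 > 0 else 0.0
        density, edges = np.histogram(x, bins=n_bins, density=True)
        out[float(t)] = {
            "msd": m2,
            "excess_kurtosis": kurt,
            "histogram": (edges, density),
        }
    return out


def fit_davg(ens: TrajectoryEnsemble) -> tuple[float, float]:
    """Recover the average diffusivity from the pooled MSD curve.

    Ordinary least squares of MSD(t) against the predictor 2t through the
    origin.  Returns (estimate, standard error) in μm²/s.
    """
    mask = ens.times > 0
    t = ens.times[mask]
    if t.size < 2:
        raise InvalidParameterError("need at least 2 recorded times past 0")
    msd_emp = np.mean(ens.positions[:, mask] ** 2, axis=0)
    predictor = 2.0 * t
    denom = float(np.dot(predictor, predictor))
    if denom == 0.0:
        raise InvalidParameterError("degenerate time grid")
    estimate = float(np.dot(predictor, msd_emp)) / denom
    residuals = msd_emp - estimate * predictor
    dof = max(t.size - 1, 1)
    se = math.sqrt(float(np.dot(residuals, residuals)) / dof / denom)
    return estimate, se
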