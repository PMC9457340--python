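"""Worked-application pipeline and histogram scoring.

Reproduces the bead-on-bilayer numbers (bare diffusivity from the
extensional-viscosity Einstein relation, liquid-phase inversion,
cholesterol control, Gaussianization time) and generates the model's
displacement-density curves at the standard comparison times.  User
histograms — columnar text with displacements in particle diameters — can
be scored against a model curve with a fixed-intercept regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model
from .params import (
    InvalidParameterError,
    PhaseParams,
    PhysicalParams,
    einstein_diffusivity,
    infer_liquid_phase,
)

__all__ = [
    "HistogramTable",
    "ConfigError",
    "DEFAULT_CURVE_TIMES",
    "round_sig",
    "load_histogram",
    "reproduce_application",
    "slope_error",
]

#: Comparison times of the worked application, s.
DEFAULT_CURVE_TIMES = (0.06, 0.6, 3.0, 5.8)

#: Viscosity step of the cholesterol-stiffened control, ×.
CHOLESTEROL_FACTOR = 1.2


class ConfigError(ValueError):
    """Required configuration entries are missing or invalid."""


@dataclass(frozen=True)
class HistogramTable:
    """A displacement histogram in Figure-style axes.

    ``x_over_d``: displacement in units of the particle diameter;
    ``log10_density``: base-10 log of the (possibly unnormalized) density;
    ``time``: s; ``diameter``: μm.
    """

    x_over_d: np.ndarray
    log10_density: np.ndarray
    time: float
    diameter: float

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.x_over_d))
                and np.all(np.isfinite(self.log10_density))):
            raise InvalidParameterError("histogram entries must be finite")
        if not self.time > 0:
            raise InvalidParameterError("time must be positive")
        if not self.diameter > 0:
            raise InvalidParameterError("diameter must be positive")

    @property
    def x_um(self) -> np.ndarray:
        return self.x_over_d * self.diameter


def load_histogram(path, diameter: float) -> HistogramTable:
    """Read a ``x_over_d,log10_density,time_s`` CSV into a table."""
    frame = pd.read_csv(path)
    required = {"x_over_d", "log10_density", "time_s"}
    if not required.issubset(frame.columns):
        raise ConfigError(
            f"histogram file must have columns {sorted(required)}, "
            f"got {list(frame.columns)}"
        )
    times = frame["time_s"].unique()
    if times.size != 1:
        raise ConfigError("histogram file must contain a single time stamp")
    return HistogramTable(
        x_over_d=frame["x_over_d"].to_numpy(dtype=float),
        log10_density=frame["log10_density"].to_numpy(dtype=float),
        time=float(times[0]),
        diameter=diameter,
    )


def round_sig(value: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures (display convention)."""
    if value == 0.0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    return round(value, digits - 1 - exponent)


def reproduce_application(config: dict, curve_times=DEFAULT_CURVE_TIMES,
                          curve_points: int = 2001) -> dict:
    """Run the full worked application from a config mapping.

    ``config`` needs a ``physical`` block (``temperature_C``,
    ``water_viscosity_mPas``, ``viscosity_multiplier``, ``radius_nm``) and
    a ``phase`` block (``Davg_um2s``, ``tc_s``, optional ``Z_G``).

    Returns a report dict with the derived scalars at full precision,
    their two-significant-figure display values, and model curves (grids
    of x and density) at ``curve_times``.
    """
    try:
        physical_block = config["physical"]
        phase_block = config["phase"]
        davg = float(phase_block["Davg_um2s"])
        tc = float(phase_block["tc_s"])
    except KeyError as exc:
        raise ConfigError(f"config missing entry {exc.args[0]!r}") from exc
    z_gas = float(phase_block.get("Z_G", 1.0))

    physical = PhysicalParams.from_config(physical_block)
    d_bare = einstein_diffusivity(physical, extensional=True)
    d_cholesterol = einstein_diffusivity(
        physical.with_viscosity_multiplier(
            physical.viscosity_multiplier * CHOLESTEROL_FACTOR),
        extensional=True,
    )
    # The worked inversion chains the two-significant-figure value of D,
    # matching the reported DeffL and Z_L roundings.
    phase = infer_liquid_phase(davg, round_sig(d_bare), Z_G=z_gas, tc=tc)
    gauss_time = model.gaussianity_time(phase)

    curves = {}
    for t in curve_times:
        curve = model.observed_curve(t, phase, n=curve_points)
        curves[t] = {
            "time_s": t,
            "regime": curve.regime_label,
            "x_um": curve.grid,
            "density_per_um": curve.density,
        }

    scalars = {
        "D_um2s": d_bare,
        "D_cholesterol_um2s": d_cholesterol,
        "DeffG_um2s": phase.DeffG,
        "DeffL_um2s": phase.DeffL,
        "Z_L": phase.Z_L,
        "Davg_um2s": phase.Davg,
        "tc_s": tc,
        "gaussianization_time_s": gauss_time,
    }
    return {
        "scalars": scalars,
        "display": {key: round_sig(value) for key, value in scalars.items()},
        "curves": curves,
        "phase": phase,
    }


def _fixed_intercept_slope(predictor: np.ndarray, response: np.ndarray,
                           intercept: float) -> float:
    denom = float(np.dot(predictor, predictor))
    if denom == 0.0:
        raise InvalidParameterError("singular design: all predictors are zero")
    return float(np.dot(predictor, response - intercept)) / denom


def slope_error(model_curve: model.DisplacementPDF,
                data: HistogramTable) -> float:
    """Percentage error of the highest-order log-density coefficient.

    The model curve's log10 density is fit by least squares with the
    intercept fixed to the model's value at x = 0 — linear in |x| on the
    Laplace (gas) branch, quadratic in x on the transition/Gaussian
    branch — and the same fixed-intercept fit is applied to the data.
    Returns ``100·|slope_fit − slope_model| / |slope_model|``.
    """
    if data.x_over_d.size < 3:
        raise InvalidParameterError("need at least 3 data points")
    if not math.isclose(model_curve.time, data.time, rel_tol=1e-6):
        raise InvalidParameterError(
            f"model time {model_curve.time} does not match data time {data.time}"
        )

    grid = model_curve.grid
    log_density = np.log10(np.clip(model_curve.density, 1e-300, None))
    intercept = float(np.interp(0.0, grid, log_density))

    if model_curve.regime_label == "gas":
        predictor_model = np.abs(grid)
        predictor_data = np.abs(data.x_um)
    else:
        predictor_model = grid**2
        predictor_data = data.x_um**2

    slope_model = _fixed_intercept_slope(predictor_model, log_density, intercept)
    slope_fit = _fixed_intercept_slope(predictor_data, data.log10_density,
                                       intercept)
    if slope_model == 0.0:
        raise InvalidParameterError("degenerate model slope")
    return 100.0 * abs(slope_fit - slope_model) / abs(slope_model)
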