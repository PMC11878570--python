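"""Confocal-volume calibration from dye-standard autocorrelation traces.

The effective detection volume V_eff converts the fitted molecule count N
into a concentration.  It is obtained by fitting the free-diffusion model
to traces of a dye with a known diffusion coefficient, averaging the
dwell time τ_diff, and applying

    ω₁   = sqrt(4·D·τ_diff)          (lateral 1/e² waist)
    V_eff = π^{3/2}·ω₁³ / s          (3D Gaussian volume)

Literature D values are tabulated at 25 °C and corrected to the
measurement temperature via the Stokes–Einstein relation
D(T) = D(25 °C)·T/η(T)·2.985×10⁻⁶ Pa·s/K.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .models import AcfCurve, CONSTANTS, PhysicalConstants, DEFAULT_STRUCTURE_FACTOR
from .fitting import fit_curve

__all__ = [
    "DyeStandard",
    "DYE_REGISTRY",
    "FocalVolume",
    "temp_correct_diffusion",
    "lateral_waist",
    "effective_volume",
    "calibrate_from_standard",
]

logger = logging.getLogger(__name__)

CM3_PER_LITER = 1e3  # 1 l = 1000 cm^3
V_EFF_EXPECTED_RANGE_FL = (0.25, 0.4)  # typical range for this optical setup


@dataclass(frozen=True)
class DyeStandard:
    """A calibration dye with a literature diffusion coefficient at 25 °C."""

    name: str
    d25: float  # cm^2/s

    def __post_init__(self) -> None:
        if not (self.d25 > 0):
            raise ValueError("d25 must be > 0")

    def d_at(self, t_celsius: float, constants: PhysicalConstants = CONSTANTS) -> float:
        return temp_correct_diffusion(self.d25, t_celsius, constants)

    @property
    def d37(self) -> float:
        return self.d_at(37.0)


#: Editable dye registry (name -> standard); extend for other dyes.
DYE_REGISTRY: dict[str, DyeStandard] = {
    "alexa_594": DyeStandard("alexa_594", 3.88e-6),
    "alexa_488": DyeStandard("alexa_488", 4.14e-6),
}


@dataclass
class FocalVolume:
    """Calibration result: waist, volume, and provenance of the fit."""

    structure_factor: float
    omega1_cm: float
    v_eff_l: float
    source_tau_diff_s: float
    n_calibration_traces: int
    out_of_range: bool = field(default=False)

    def __post_init__(self) -> None:
        if not (self.v_eff_l > 0):
            raise ValueError("v_eff must be > 0")
        lo, hi = V_EFF_EXPECTED_RANGE_FL
        self.out_of_range = not (lo <= self.v_eff_fl <= hi)

    @property
    def omega1_um(self) -> float:
        return self.omega1_cm * 1e4

    @property
    def v_eff_fl(self) -> float:
        return self.v_eff_l * 1e15


def temp_correct_diffusion(
    d25: float, t_celsius: float, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Correct a 25 °C diffusion coefficient to temperature ``t_celsius``.

    D(T) = D(25°C) · (t + 273.15)/η(t) · 2.985×10⁻⁶; the identity at 25 °C.
    """
    if not (d25 > 0):
        raise ValueError("d25 must be > 0")
    eta = constants.viscosity(t_celsius)  # raises outside [0, 60] C
    return d25 * (t_celsius + 273.15) / eta * constants.stokes_constant


def lateral_waist(d: float, tau_diff: float) -> float:
    """Lateral 1/e² extension ω₁ = sqrt(4·D·τ_diff), in cm."""
    if not (d > 0 and tau_diff > 0):
        raise ValueError("d and tau_diff must be > 0")
    return math.sqrt(4.0 * d * tau_diff)


def effective_volume(omega1: float, s: float) -> float:
    """Effective volume V_eff = π^{3/2}·ω₁³/s, returned in liters.

    ``omega1`` in cm; the cm³ result is converted with 1 l = 1000 cm³.
    """
    if not (omega1 > 0):
        raise ValueError("omega1 must be > 0")
    if not (0.0 < s < 1.0):
        raise ValueError("s must be in (0, 1)")
    v_cm3 = math.pi**1.5 * omega1**3 / s
    return v_cm3 / CM3_PER_LITER


def calibrate_from_standard(
    curves: list[AcfCurve],
    dye: DyeStandard,
    t_celsius: float = 37.0,
    s: float = DEFAULT_STRUCTURE_FACTOR,
    constants: PhysicalConstants = CONSTANTS,
) -> FocalVolume:
    """Determine the focal volume from dye-standard ACF traces.

    Each curve is fitted with the free-diffusion model (s fixed); curves
    whose fit fails (non-convergence, non-finite amplitudes) are excluded
    with a logged reason.  The surviving dwell times are averaged and
    propagated through the temperature correction, waist, and volume
    relations.  At least 3 surviving fits are required.
    """
    if len(curves) < 3:
        raise ValueError("calibration requires at least 3 curves")
    taus = []
    for i, curve in enumerate(curves):
        if not np.all(np.isfinite(curve.g)):
            logger.warning("calibration curve %d excluded: non-finite amplitudes", i)
            continue
        fit = fit_curve(curve, model="one_component", s_fixed=s)
        if not fit.converged:
            logger.warning("calibration curve %d excluded: fit did not converge", i)
            continue
        taus.append(fit.params.tau_diff)
    if len(taus) < 3:
        raise RuntimeError(
            f"calibration failed: only {len(taus)} of {len(curves)} curves usable"
        )
    tau_mean = float(np.mean(taus))
    d = temp_correct_diffusion(dye.d25, t_celsius, constants)
    omega1 = lateral_waist(d, tau_mean)
    v_eff = effective_volume(omega1, s)
    fv = FocalVolume(
        structure_factor=s,
        omega1_cm=omega1,
        v_eff_l=v_eff,
        source_tau_diff_s=tau_mean,
        n_calibration_traces=len(taus),
    )
    if fv.out_of_range:
        logger.warning(
            "V_eff = %.3f fl outside the expected %.2f-%.2f fl range",
            fv.v_eff_fl,
            *V_EFF_EXPECTED_RANGE_FL,
        )
    return fv
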