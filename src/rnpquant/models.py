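"""Closed-form fluorescence-correlation model functions and shared types.

FCS measures the normalized autocorrelation G(τ) of fluorescence
fluctuations produced by molecules diffusing through a 3D Gaussian focal
volume.  Three models are provided:

* a one-component free (Brownian) diffusion model,
* a one-component anomalous (subdiffusive) model with an additive offset,
* a two-component model mixing a fast freely diffusing population with a
  slow, anomalously diffusing (DNA-bound) population.

All models share the structure factor ``s`` — the ratio of the radial to
axial 1/e² extension of the focal volume — which is measured once from a
dye standard and held fixed (default 0.17) in every fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "DEFAULT_STRUCTURE_FACTOR",
    "PhysicalConstants",
    "CONSTANTS",
    "AcfCurve",
    "OneComponentParams",
    "AnomalousParams",
    "TwoComponentParams",
    "eval_one_component",
    "eval_anomalous",
    "eval_two_component",
]

DEFAULT_STRUCTURE_FACTOR = 0.17

_T25_K = 298.15
_T37_K = 310.15


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants used throughout the pipeline.

    ``stokes_constant`` is the lumped Stokes–Einstein prefactor
    (k_B / 6πr expressed per molecule) that converts D·η/T between
    temperatures: D(T) = D(25°C) · T/η(T) · stokes_constant, with the
    pinned viscosities making the relation the identity at 25°C.
    """

    avogadro: float = 6.02214076e23  # mol^-1
    eta_25c: float = 8.90e-4  # Pa s, water at 25 C
    eta_37c: float = 6.913e-4  # Pa s, water at 37 C
    stokes_constant: float = 2.985e-6  # Pa s / K
    hela_nuclear_volume_l: float = 6.90e-13  # liters (= 690 um^3)

    def viscosity(self, t_celsius: float) -> float:
        """Viscosity of water at ``t_celsius`` (Pa s).

        Arrhenius-form interpolation η(T) = A·exp(B/T) pinned exactly at
        the 25 °C and 37 °C reference values; valid for 0–60 °C.
        """
        if not (0.0 <= t_celsius <= 60.0):
            raise ValueError(
                f"temperature {t_celsius} °C outside supported range [0, 60] °C"
            )
        t_k = t_celsius + 273.15
        b = math.log(self.eta_25c / self.eta_37c) / (1.0 / _T25_K - 1.0 / _T37_K)
        a = self.eta_25c / math.exp(b / _T25_K)
        return a * math.exp(b / t_k)


CONSTANTS = PhysicalConstants()


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class AcfCurve:
    """One autocorrelation measurement.

    Parameters
    ----------
    lags : array of float
        Lag times τ in seconds, strictly increasing, all > 0.
    g : array of float
        Correlation amplitudes G(τ), dimensionless, finite.
    g_se : array of float, optional
        Per-lag standard error of g (all > 0 when present).
    n_traces : int
        Number of averaged sub-traces this curve was built from.
    trace_duration : float
        Duration of the underlying measurement in seconds.
    meta : dict
        Free-form acquisition labels (cell id, condition, dose ...).
    """

    lags: np.ndarray
    g: np.ndarray
    g_se: Optional[np.ndarray] = None
    n_traces: int = 1
    trace_duration: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lags.ndim != 1 or self.g.shape != self.lags.shape:
            raise ValueError("lags and g must be 1-D arrays of equal length")
        if self.lags.size and self.lags[0] <= 0:
            raise ValueError("lags must be positive")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("g contains non-finite values")
        if self.g_se is not None:
            self.g_se = np.asarray(self.g_se, dtype=float)
            if self.g_se.shape != self.lags.shape:
                raise ValueError("g_se must match lags in length")
            if np.any(self.g_se <= 0):
                raise ValueError("g_se entries must be > 0")

    def __len__(self) -> int:
        return self.lags.size


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0):
            raise ValueError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class OneComponentParams:
    """Free 3D diffusion: mean occupancy N and dwell time τ_diff."""

    n_molecules: float
    tau_diff: float
    structure_factor: float = DEFAULT_STRUCTURE_FACTOR

    def __post_init__(self) -> None:
        _check_positive(n_molecules=self.n_molecules, tau_diff=self.tau_diff)
        if not (0.0 < self.structure_factor < 1.0):
            raise ValueError("structure_factor must be in (0, 1)")


@dataclass(frozen=True)
class AnomalousParams:
    """Anomalous 3D diffusion with exponent α and offset G(∞).

    ``placement`` selects where α enters the denominator:
    ``"standard"`` raises τ/τ_diff to α inside the parentheses (the usual
    anomalous-FCS form, and the form of the slow term in the two-component
    model); ``"printed"`` raises the whole parenthesized factors to α.
    """

    n_molecules: float
    tau_diff: float
    alpha: float = 1.0
    g_inf: float = 0.0
    structure_factor: float = DEFAULT_STRUCTURE_FACTOR
    placement: str = "standard"

    def __post_init__(self) -> None:
        _check_positive(n_molecules=self.n_molecules, tau_diff=self.tau_diff)
        if not (0.0 < self.alpha <= 1.5):
            raise ValueError("alpha must be in (0, 1.5]")
        if not (0.0 < self.structure_factor < 1.0):
            raise ValueError("structure_factor must be in (0, 1)")
        if self.placement not in ("standard", "printed"):
            raise ValueError("placement must be 'standard' or 'printed'")


@dataclass(frozen=True)
class TwoComponentParams:
    """Fast free component plus slow anomalous component.

    ``f_fast`` is the fraction of molecules in the rapidly diffusing
    (free) population; 1 − f_fast approximates the DNA-bound fraction.
    ``form="sum"`` is the standard additive mixture; ``"literal_product"``
    multiplies the two bracketed terms instead (kept for fidelity checks,
    physically inconsistent with N's meaning).
    """

    n_molecules: float
    tau_diff1: float
    tau_diff2: float
    alpha: float = 1.0
    f_fast: float = 0.5
    structure_factor: float = DEFAULT_STRUCTURE_FACTOR
    form: str = "sum"

    def __post_init__(self) -> None:
        _check_positive(
            n_molecules=self.n_molecules,
            tau_diff1=self.tau_diff1,
            tau_diff2=self.tau_diff2,
        )
        if not self.tau_diff1 < self.tau_diff2:
            raise ValueError("tau_diff1 must be < tau_diff2 (fast < slow)")
        if not (0.0 < self.alpha <= 1.5):
            raise ValueError("alpha must be in (0, 1.5]")
        if not (0.0 <= self.f_fast <= 1.0):
            raise ValueError("f_fast must be in [0, 1]")
        if not (0.0 < self.structure_factor < 1.0):
            raise ValueError("structure_factor must be in (0, 1)")
        if self.form not in ("sum", "literal_product"):
            raise ValueError("form must be 'sum' or 'literal_product'")


# ---------------------------------------------------------------------------
# model kernels
# ---------------------------------------------------------------------------


def _as_tau(tau) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be > 0")
    return tau


def _kernel_free(x: np.ndarray, s: float) -> np.ndarray:
    """Normalized 3D free-diffusion kernel; x = τ/τ_diff."""
    return 1.0 / ((1.0 + x) * np.sqrt(1.0 + s * s * x))


def _kernel_anomalous(x: np.ndarray, s: float, alpha: float, placement: str) -> np.ndarray:
    if placement == "standard":
        xa = x**alpha
        return 1.0 / ((1.0 + xa) * np.sqrt(1.0 + s * s * xa))
    # printed: whole factors raised to alpha
    return 1.0 / ((1.0 + x) ** alpha * (np.sqrt(1.0 + s * s * x)) ** alpha)


def eval_one_component(params: OneComponentParams, tau) -> np.ndarray:
    """G(τ) for one freely diffusing species.

    G(τ) = (1/N) / [(1 + τ/τ_d)·sqrt(1 + s²·τ/τ_d)]
    """
    tau = _as_tau(tau)
    x = tau / params.tau_diff
    return _kernel_free(x, params.structure_factor) / params.n_molecules


def eval_anomalous(params: AnomalousParams, tau) -> np.ndarray:
    """G(τ) for one anomalously diffusing species, plus the G(∞) offset."""
    tau = _as_tau(tau)
    x = tau / params.tau_diff
    g = _kernel_anomalous(x, params.structure_factor, params.alpha, params.placement)
    return g / params.n_molecules + params.g_inf


def eval_two_component(params: TwoComponentParams, tau) -> np.ndarray:
    """G(τ) for a fast free plus slow anomalous mixture.

    In ``form="sum"``:
        G(τ) = (1/N)·[F_fast·g_free(τ/τ₁) + (1−F_fast)·g_anom(τ/τ₂; α)]
    In ``form="literal_product"`` the two bracketed terms are multiplied.
    """
    tau = _as_tau(tau)
    s = params.structure_factor
    fast = params.f_fast * _kernel_free(tau / params.tau_diff1, s)
    slow = (1.0 - params.f_fast) * _kernel_anomalous(
        tau / params.tau_diff2, s, params.alpha, "standard"
    )
    if params.form == "sum":
        return (fast + slow) / params.n_molecules
    return (fast * slow) / params.n_molecules
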