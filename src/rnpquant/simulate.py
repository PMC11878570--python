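"""Seeded simulators for every input the pipeline consumes.

No public raw data accompany the measurements this pipeline targets, so
each stage is exercised against generators with known ground truth:

* a Brownian-dynamics photon-trace simulator (particles diffusing through
  a 3D Gaussian detection profile, Poisson photon statistics),
* a fast analytic ACF generator (model curve + seeded noise) for fitting
  and QC tests,
* a droplet generator with a true break fraction for the ddPCR statistic,
* 4PL dose-response tables and two-compartment editing time courses.

All generators are bit-reproducible from (config, seed).

Subdiffusion in the particle simulator is approximated by Gaussian
increments with time-rescaled variance (cumulative MSD ∝ t^α), not true
fractional Brownian motion; the analytic generator is the primary test
path for anomalous fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .correlator import PhotonTrace
from .ddpcr import DropletWell
from .dose import TimeCourse
from .models import (
    AcfCurve,
    AnomalousParams,
    CONSTANTS,
    DEFAULT_STRUCTURE_FACTOR,
    OneComponentParams,
    TwoComponentParams,
    eval_anomalous,
    eval_one_component,
    eval_two_component,
)

__all__ = [
    "SimSpecies",
    "FcsSimConfig",
    "DdpcrSimConfig",
    "simulate_fcs_trace",
    "simulate_acf_direct",
    "simulate_droplets",
    "simulate_dose_response",
    "simulate_timecourse",
]

MAX_PARTICLES = 100_000  # desk-scale guard


@dataclass(frozen=True)
class SimSpecies:
    """One diffusing species: concentration, mobility, and brightness.

    Mobility is given either as ``tau_diff_s`` (dwell time through the
    focal volume, the quantity fits report) or ``d_cm2_s``; the missing
    one is derived from ω₁ at simulation time.  ``alpha`` = 1 is Brownian.
    """

    concentration_m: float
    tau_diff_s: float | None = None
    d_cm2_s: float | None = None
    alpha: float = 1.0
    brightness_cps: float = 30_000.0

    def __post_init__(self) -> None:
        if not (self.concentration_m > 0):
            raise ValueError("concentration must be > 0")
        if (self.tau_diff_s is None) == (self.d_cm2_s is None):
            raise ValueError("give exactly one of tau_diff_s or d_cm2_s")
        if not (0.0 < self.alpha <= 1.5):
            raise ValueError("alpha must be in (0, 1.5]")
        if self.brightness_cps < 0:
            raise ValueError("brightness must be >= 0")


@dataclass(frozen=True)
class FcsSimConfig:
    """Brownian-dynamics acquisition emulating a nuclear FCS measurement.

    Defaults mirror the acquisition convention this pipeline assumes:
    ω₁ = 0.204 μm with s = 0.17 (V_eff ≈ 0.28 fl) and a 100-s measurement
    recorded as ten 10-s sub-traces when segmented downstream.  The box is
    periodic with half-width ``box_multiplier``·ω_z per axis.
    """

    species: tuple[SimSpecies, ...]
    omega1_cm: float = 2.04e-5
    structure_factor: float = DEFAULT_STRUCTURE_FACTOR
    box_multiplier: float = 3.0
    duration_s: float = 100.0
    bin_time_s: float = 2e-4
    background_cps: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species or len(self.species) > 2:
            raise ValueError("1 or 2 species required (two-component model)")
        for name in ("omega1_cm", "duration_s", "bin_time_s"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.structure_factor < 1):
            raise ValueError("structure_factor must be in (0, 1)")


@dataclass(frozen=True)
class DdpcrSimConfig:
    """Droplet population with a known true break fraction."""

    n_droplets: int = 20_000
    lambda_hex: float = 0.3
    true_dsb_fraction: float = 0.0
    neg_mean: float = 1000.0
    neg_sd: float = 100.0
    pos_mean: float = 8000.0
    pos_sd: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets < 1000:
            raise ValueError("n_droplets must be >= 1000")
        if not (self.lambda_hex > 0):
            raise ValueError("lambda_hex must be > 0")
        if not (0.0 <= self.true_dsb_fraction <= 1.0):
            raise ValueError("true_dsb_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# Brownian-dynamics photon traces
# ---------------------------------------------------------------------------


@njit(cache=True)
def _bd_chunk(pos, steps, a_lat, a_ax, half, out):  # pragma: no cover
    """Advance particles through one time chunk, accumulating detected signal.

    ``steps`` holds pre-scaled Gaussian displacements (chunk, particle, 3);
    periodic wrapping assumes single-bin steps are small against the box.
    """
    n_bins = steps.shape[0]
    n_part = pos.shape[0]
    width = 2.0 * half
    for t in range(n_bins):
        acc = 0.0
        for p in range(n_part):
            x = pos[p, 0] + steps[t, p, 0]
            y = pos[p, 1] + steps[t, p, 1]
            z = pos[p, 2] + steps[t, p, 2]
            if x > half:
                x -= width
            elif x < -half:
                x += width
            if y > half:
                y -= width
            elif y < -half:
                y += width
            if z > half:
                z -= width
            elif z < -half:
                z += width
            pos[p, 0] = x
            pos[p, 1] = y
            pos[p, 2] = z
            q = a_lat * (x * x + y * y) + a_ax * z * z
            if q < 30.0:
                acc += math.exp(-q)
        out[t] += acc


def simulate_fcs_trace(config: FcsSimConfig) -> PhotonTrace:
    """Photon-count trace from particles crossing a 3D Gaussian focus.

    Particle counts are Poisson-drawn from concentration × box volume,
    positions evolve by (variance-rescaled) Gaussian increments with
    periodic wrapping, per-bin expected counts follow the Gaussian
    detection profile exp(−2r²/ω₁² − 2z²/ω_z²), and realized counts are
    Poisson-distributed.  Fully reproducible from the config seed.
    """
    rng = np.random.default_rng(config.seed)
    w1 = config.omega1_cm
    wz = w1 / config.structure_factor
    half = config.box_multiplier * wz
    vol_l = (2.0 * half) ** 3 / 1e3  # cm^3 -> liters
    n_bins = int(round(config.duration_s / config.bin_time_s))
    dt = config.bin_time_s
    expected = np.zeros(n_bins)
    total_p = 0
    for i, sp in enumerate(config.species):
        n_part = int(rng.poisson(sp.concentration_m * CONSTANTS.avogadro * vol_l))
        total_p += n_part
        if total_p > MAX_PARTICLES:
            raise ResourceWarning(
                f"simulation would require {total_p} particles (> {MAX_PARTICLES}); "
                "reduce concentration or box size"
            )
        if n_part == 0:
            continue
        # anomalous transport coefficient from the dwell time: MSD_1d = 2 D t^a
        # with w1^2/4 = D tau_d^a  (reduces to D = w1^2/(4 tau_d) at a = 1)
        if sp.tau_diff_s is not None:
            d_alpha = w1**2 / (4.0 * sp.tau_diff_s**sp.alpha)
        else:
            d_alpha = sp.d_cm2_s
        t_edges = np.arange(n_bins + 1) * dt
        var_inc = 2.0 * d_alpha * np.diff(t_edges**sp.alpha)
        stds = np.sqrt(var_inc).astype(np.float32)
        pos = rng.uniform(-half, half, size=(n_part, 3))
        sub = np.zeros(n_bins)
        # chunked over time: fast vectorized normal draws feed the numba kernel
        chunk = max(1, min(n_bins, int(4e7 // max(n_part, 1))))
        start = 0
        while start < n_bins:
            stop = min(start + chunk, n_bins)
            steps = rng.standard_normal((stop - start, n_part, 3), dtype=np.float32)
            steps *= stds[start:stop, None, None]
            _bd_chunk(pos, steps, 2.0 / w1**2, 2.0 / wz**2, half, sub[start:stop])
            start = stop
        expected += sp.brightness_cps * dt * sub
    expected += config.background_cps * dt
    counts = rng.poisson(expected)
    return PhotonTrace(
        counts=counts,
        bin_time=dt,
        meta={"seed": config.seed, "n_particles": total_p},
    )


# ---------------------------------------------------------------------------
# analytic ACF curves
# ---------------------------------------------------------------------------


def _eval_params(params, lags: np.ndarray) -> np.ndarray:
    if isinstance(params, OneComponentParams):
        return eval_one_component(params, lags)
    if isinstance(params, AnomalousParams):
        return eval_anomalous(params, lags)
    if isinstance(params, TwoComponentParams):
        return eval_two_component(params, lags)
    raise TypeError(f"unsupported params type {type(params)!r}")


def simulate_acf_direct(
    params,
    noise_sd: float = 0.0,
    n_curves: int = 1,
    seed: int = 0,
    lag_min: float = 1e-5,
    lag_max: float = 1.0,
    points_per_decade: int = 40,
    meta: dict | None = None,
) -> list[AcfCurve]:
    """Model-evaluated ACF curves with seeded multiplicative noise.

    Noise is Gaussian, relative to the model value, scaled by
    ``noise_sd`` and by a lag-dependent factor growing from 1× at
    ``lag_min`` to 3× at ``lag_max`` (mimicking the larger correlator
    variance at long lags).  ``noise_sd=0`` returns exact model curves.
    """
    decades = math.log10(lag_max / lag_min)
    n_points = int(round(decades * points_per_decade)) + 1
    lags = np.logspace(math.log10(lag_min), math.log10(lag_max), n_points)
    g0 = _eval_params(params, lags)
    rel = noise_sd * (1.0 + 2.0 * np.log10(lags / lag_min) / decades)
    rng = np.random.default_rng(seed)
    curves = []
    for i in range(n_curves):
        if noise_sd > 0:
            g = g0 * (1.0 + rel * rng.standard_normal(n_points))
            g_se = np.abs(g0) * rel + 1e-12
        else:
            g = g0.copy()
            g_se = None
        curves.append(
            AcfCurve(
                lags=lags,
                g=g,
                g_se=g_se,
                n_traces=1,
                trace_duration=0.0,
                meta={"replicate": i, **(meta or {})},
            )
        )
    return curves


# ---------------------------------------------------------------------------
# ddPCR droplets
# ---------------------------------------------------------------------------


def simulate_droplets(config: DdpcrSimConfig, well_id: str = "sim", is_reference: bool = False) -> DropletWell:
    """Droplet population with occupancy λ_hex and true break fraction f.

    Template copies per droplet are Poisson(λ_hex); each copy's cut-site
    amplicon survives independently with probability 1−f, so FAM copies
    are Binomial(copies, 1−f) and the FAM concentration is λ_hex·(1−f)
    exactly — the Poisson-mode %DSB estimator is unbiased at any λ.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_droplets
    hex_copies = rng.poisson(config.lambda_hex, size=n)
    fam_copies = rng.binomial(hex_copies, 1.0 - config.true_dsb_fraction)
    hex_amp = np.where(
        hex_copies > 0,
        rng.normal(config.pos_mean, config.pos_sd, size=n),
        rng.normal(config.neg_mean, config.neg_sd, size=n),
    )
    fam_amp = np.where(
        fam_copies > 0,
        rng.normal(config.pos_mean, config.pos_sd, size=n),
        rng.normal(config.neg_mean, config.neg_sd, size=n),
    )
    return DropletWell(
        hex_amplitude=hex_amp,
        fam_amplitude=fam_amp,
        well_id=well_id,
        is_reference=is_reference,
    )


# ---------------------------------------------------------------------------
# dose-response tables and editing time courses
# ---------------------------------------------------------------------------


def simulate_dose_response(
    bottom: float,
    top: float,
    ec50: float,
    hill: float,
    doses,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    condition: str = "sim",
    seed: int = 0,
) -> pd.DataFrame:
    """4PL responses at the given doses plus seeded Gaussian noise.

    Noise is additive in percentage points (SD = ``noise_sd``); responses
    are clamped to [0, 100].
    """
    doses = np.asarray(doses, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        resp = bottom + (top - bottom) / (1.0 + (ec50 / doses) ** hill)
        if noise_sd > 0:
            resp = resp + rng.normal(0.0, noise_sd, size=doses.size)
        resp = np.clip(resp, 0.0, 100.0)
        for d, r in zip(doses, resp):
            rows.append(
                {
                    "dose_per_cell": d,
                    "response_pct": r,
                    "condition": condition,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)


def simulate_timecourse(
    k_cut: float,
    k_repair: float,
    plateau: float,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
    condition: str = "sim",
    dose_per_cell: float = math.nan,
) -> tuple[TimeCourse, TimeCourse]:
    """Two-compartment editing kinetics: uncut → cut (DSB) → indel.

    Closed forms of the linear chain with rates ``k_cut`` and
    ``k_repair`` (both per hour), scaled so indels plateau at ``plateau``
    percent.  Returns (dsb_course, indel_course).  As k_repair → ∞ the
    indel course approaches the saturating exponential
    plateau·(1 − e^(−k_cut·t)) with half-max at ln2/k_cut.
    """
    if not (k_cut > 0 and k_repair > 0):
        raise ValueError("rates must be > 0")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if abs(k_repair - k_cut) < 1e-12 * max(k_cut, k_repair):
        dsb_frac = k_cut * t * np.exp(-k_cut * t)
    else:
        dsb_frac = (
            k_cut / (k_repair - k_cut) * (np.exp(-k_cut * t) - np.exp(-k_repair * t))
        )
    uncut = np.exp(-k_cut * t)
    indel_frac = 1.0 - uncut - dsb_frac
    dsb = plateau * dsb_frac
    indel = plateau * indel_frac
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dsb = dsb + rng.normal(0.0, noise_sd, size=t.size)
        indel = indel + rng.normal(0.0, noise_sd, size=t.size)
    dsb = np.clip(dsb, 0.0, 100.0)
    indel = np.clip(indel, 0.0, 100.0)
    return (
        TimeCourse(times=t, values=dsb, condition=f"{condition}_dsb", dose_per_cell=dose_per_cell),
        TimeCourse(times=t, values=indel, condition=f"{condition}_indel", dose_per_cell=dose_per_cell),
    )
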