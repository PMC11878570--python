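"""Droplet digital PCR quantification of double-strand breaks.

Two probes read each droplet: a reference amplicon (HEX) that is always
present when the target locus is in the droplet, and a second amplicon
(FAM) spanning the cut site that is lost when the break is unrepaired or
the chromosome is lost.  Channel thresholds are derived from untreated
reference wells; per-channel concentrations use Poisson statistics
λ = −ln(1 − positives/n), and the break fraction is

    %DSB = 100 × (1 − [FAM]/[HEX]),

clamped to [0, 100] (negative values from noise are clamped with a
warning, never silently).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DropletWell",
    "ChannelThresholds",
    "DsbResult",
    "set_thresholds",
    "quantify_well",
    "bootstrap_dsb",
]

logger = logging.getLogger(__name__)

MIN_DROPLETS_DEFAULT = 1000


@dataclass
class DropletWell:
    """Per-droplet two-channel fluorescence amplitudes for one well."""

    hex_amplitude: np.ndarray
    fam_amplitude: np.ndarray
    well_id: str = ""
    is_reference: bool = False

    def __post_init__(self) -> None:
        self.hex_amplitude = np.asarray(self.hex_amplitude, dtype=float)
        self.fam_amplitude = np.asarray(self.fam_amplitude, dtype=float)
        if self.hex_amplitude.shape != self.fam_amplitude.shape:
            raise ValueError("channel arrays must have equal length")

    @property
    def n_droplets(self) -> int:
        return self.hex_amplitude.size


@dataclass
class ChannelThresholds:
    hex_threshold: float
    fam_threshold: float
    hex_fallback: bool = False
    fam_fallback: bool = False

    def __iter__(self):
        yield self.hex_threshold
        yield self.fam_threshold


@dataclass
class DsbResult:
    well_id: str
    hex_positive: int
    fam_positive: int
    n_droplets: int
    hex_conc: float  # copies per droplet (lambda)
    fam_conc: float
    pct_dsb: float
    clamped: bool = False
    warnings: list = field(default_factory=list)


def _two_means_1d(x: np.ndarray, max_iter: int = 100) -> tuple[float, float, float, float]:
    """Deterministic 1-D two-means: (mu_lo, sd_lo, mu_hi, sd_hi).

    Centers start at the 5th/95th percentiles, so the result is invariant
    to droplet order.
    """
    lo = float(np.percentile(x, 5))
    hi = float(np.percentile(x, 95))
    if lo == hi:
        return lo, 0.0, hi, 0.0
    for _ in range(max_iter):
        cut = (lo + hi) / 2.0
        low = x[x <= cut]
        high = x[x > cut]
        if not low.size or not high.size:
            break
        new_lo, new_hi = float(low.mean()), float(high.mean())
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    cut = (lo + hi) / 2.0
    low = x[x <= cut]
    high = x[x > cut]
    sd_lo = float(low.std(ddof=1)) if low.size > 1 else 0.0
    sd_hi = float(high.std(ddof=1)) if high.size > 1 else 0.0
    return lo, sd_lo, hi, sd_hi


def _channel_threshold(x: np.ndarray, k: float) -> tuple[float, bool]:
    mu_lo, sd_lo, mu_hi, sd_hi = _two_means_1d(x)
    neg_edge = mu_lo + k * sd_lo
    pos_edge = mu_hi - k * sd_hi
    if pos_edge <= neg_edge or (mu_hi - mu_lo) < k * (sd_lo + sd_hi):
        # unimodal (or overlapping) channel: fall back to mean + k.SD
        thr = float(x.mean() + k * x.std(ddof=1 if x.size > 1 else 0))
        logger.warning(
            "channel appears unimodal; falling back to mean + %.1f*SD threshold", k
        )
        return thr, True
    return (neg_edge + pos_edge) / 2.0, False


def set_thresholds(
    reference_wells: list[DropletWell], k: float = 5.0
) -> ChannelThresholds:
    """Derive per-channel thresholds from untreated reference wells.

    Amplitudes of all reference wells are pooled per channel and split by
    two-means clustering; the threshold is the midpoint between the
    negative-cluster upper edge (mean + k·SD of the lower mode) and the
    positive-cluster lower edge (mean − k·SD of the upper mode).  A
    channel without two separated modes falls back to mean + k·SD.
    """
    if not reference_wells:
        raise ValueError("at least one reference well is required")
    hex_amp = np.concatenate([w.hex_amplitude for w in reference_wells])
    fam_amp = np.concatenate([w.fam_amplitude for w in reference_wells])
    hex_thr, hex_fb = _channel_threshold(hex_amp, k)
    fam_thr, fam_fb = _channel_threshold(fam_amp, k)
    return ChannelThresholds(hex_thr, fam_thr, hex_fb, fam_fb)


def _poisson_lambda(positives: int, n: int) -> float:
    if positives >= n:
        # saturated channel: bound lambda using a half-droplet correction
        positives = n - 0.5
    return -math.log(1.0 - positives / n)


def quantify_well(
    well: DropletWell,
    thresholds: ChannelThresholds,
    mode: str = "poisson",
    min_droplets: int = MIN_DROPLETS_DEFAULT,
) -> DsbResult:
    """Compute the %DSB statistic for one well.

    ``poisson`` mode (default) converts positive fractions to copies per
    droplet with λ = −ln(1 − p) before taking the [FAM]/[HEX] ratio;
    ``raw_counts`` uses the positive fractions directly (occupancy-biased
    at high λ, kept for sensitivity analysis).
    """
    if mode not in ("poisson", "raw_counts"):
        raise ValueError("mode must be 'poisson' or 'raw_counts'")
    n = well.n_droplets
    warnings: list[str] = []
    if n < min_droplets:
        warnings.append(f"only {n} droplets (< {min_droplets})")
        logger.warning("well %s: %s", well.well_id, warnings[-1])
    hex_pos = int(np.count_nonzero(well.hex_amplitude > thresholds.hex_threshold))
    fam_pos = int(np.count_nonzero(well.fam_amplitude > thresholds.fam_threshold))
    if hex_pos == 0:
        raise ZeroDivisionError("no HEX-positive droplets: %DSB undefined")
    if mode == "poisson":
        hex_conc = _poisson_lambda(hex_pos, n)
        fam_conc = _poisson_lambda(fam_pos, n)
    else:
        hex_conc = hex_pos / n
        fam_conc = fam_pos / n
    if fam_conc > hex_conc:
        warnings.append("[FAM] exceeds [HEX]; %DSB clamped to 0")
        logger.warning("well %s: %s", well.well_id, warnings[-1])
    pct = 100.0 * (1.0 - fam_conc / hex_conc)
    clamped = pct < 0.0 or pct > 100.0
    pct = float(min(max(pct, 0.0), 100.0))
    return DsbResult(
        well_id=well.well_id,
        hex_positive=hex_pos,
        fam_positive=fam_pos,
        n_droplets=n,
        hex_conc=hex_conc,
        fam_conc=fam_conc,
        pct_dsb=pct,
        clamped=clamped,
        warnings=warnings,
    )


def bootstrap_dsb(
    well: DropletWell,
    thresholds: ChannelThresholds,
    mode: str = "poisson",
    n_boot: int = 200,
    ci: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Bootstrap confidence interval for %DSB by droplet resampling."""
    rng = np.random.default_rng(seed)
    n = well.n_droplets
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bw = DropletWell(
            hex_amplitude=well.hex_amplitude[idx],
            fam_amplitude=well.fam_amplitude[idx],
            well_id=well.well_id,
        )
        try:
            vals.append(quantify_well(bw, thresholds, mode, min_droplets=1).pct_dsb)
        except ZeroDivisionError:
            continue
    lo = (1.0 - ci) / 2.0
    return (
        float(np.quantile(vals, lo)),
        float(np.quantile(vals, 1.0 - lo)),
    )
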