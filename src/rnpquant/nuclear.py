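"""Nuclear concentrations and copy numbers from accepted FCS fits.

The fitted molecule count N in the calibrated focal volume V_eff gives
the nuclear concentration C = N/(N_A·V_eff); multiplying by the nuclear
volume (default 6.90×10⁻¹³ l, i.e. 690 μm³ for HeLa) gives the absolute
number of molecules per nucleus.  The slow (DNA-bound) fraction of that
concentration is C_bound = (1−F_fast)·C in the default ``complement``
mode; a ``literal`` mode computing C/F_fast is retained for comparison
and flagged whenever it exceeds C (it cannot describe a sub-population).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .models import CONSTANTS, PhysicalConstants
from .fitting import FitResult

__all__ = [
    "NuclearQuant",
    "concentration_from_n",
    "molecules_per_nucleus",
    "bound_concentration",
    "per_cell_fraction",
    "quantify_fits",
    "condition_table",
    "two_sig_figs",
]

logger = logging.getLogger(__name__)


@dataclass
class NuclearQuant:
    """Per-cell nuclear quantification."""

    concentration_m: float  # molar
    n_nucleus: float  # molecules per nucleus
    c_bound_m: float  # molar
    f_fast: Optional[float] = None
    nuclear_volume_l: float = CONSTANTS.hela_nuclear_volume_l
    dose_per_cell: Optional[float] = None
    nuclear_fraction: Optional[float] = None

    @property
    def concentration_nm(self) -> float:
        return self.concentration_m * 1e9

    @property
    def c_bound_nm(self) -> float:
        return self.c_bound_m * 1e9


def concentration_from_n(
    n_molecules: float, v_eff_l: float, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Concentration C = N/(N_A·V_eff), in molar."""
    if not (v_eff_l > 0):
        raise ValueError("v_eff must be > 0")
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    return n_molecules / (constants.avogadro * v_eff_l)


def molecules_per_nucleus(
    c_molar: float,
    nuclear_volume_l: float = CONSTANTS.hela_nuclear_volume_l,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """N_nucleus = C·V_nuc·N_A."""
    if c_molar < 0:
        raise ValueError("concentration must be >= 0")
    return c_molar * nuclear_volume_l * constants.avogadro


def bound_concentration(c_molar: float, f_fast: float, mode: str = "complement") -> float:
    """DNA-bound concentration from the fast fraction.

    ``complement`` (default): C_bound = (1−F_fast)·C, the slow
    sub-population.  ``literal``: C_bound = C/F_fast; logged as flagged
    whenever the result exceeds C.
    """
    if mode not in ("complement", "literal"):
        raise ValueError("mode must be 'complement' or 'literal'")
    if c_molar < 0:
        raise ValueError("concentration must be >= 0")
    if mode == "complement":
        if not (0.0 <= f_fast <= 1.0):
            raise ValueError("f_fast must be in [0, 1]")
        return (1.0 - f_fast) * c_molar
    if not (0.0 < f_fast <= 1.0):
        raise ValueError("literal mode requires f_fast in (0, 1]")
    c_bound = c_molar / f_fast
    if c_bound > c_molar:
        logger.warning(
            "literal-mode C_bound (%.3g M) exceeds C (%.3g M); "
            "not interpretable as a sub-population",
            c_bound,
            c_molar,
        )
    return c_bound


def per_cell_fraction(n_nucleus: float, dose_per_cell: float) -> float:
    """Fraction of the delivered per-cell dose found in the nucleus."""
    if not (dose_per_cell > 0):
        raise ValueError("dose_per_cell must be > 0")
    if n_nucleus < 0:
        raise ValueError("n_nucleus must be >= 0")
    return n_nucleus / dose_per_cell


def two_sig_figs(x: float) -> float:
    """Round to two significant figures (reporting convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp + 1)


def quantify_fits(
    fits: list[FitResult],
    v_eff_l: float,
    nuclear_volume_l: float = CONSTANTS.hela_nuclear_volume_l,
    bound_mode: str = "complement",
    constants: PhysicalConstants = CONSTANTS,
) -> list[NuclearQuant]:
    """Convert QC-passing fits into per-cell nuclear quantities.

    ``dose_per_cell`` is picked up from each fit's metadata when present
    and used for the nuclear delivered fraction.
    """
    out = []
    for fit in fits:
        if fit.qc_status != "pass" or fit.params is None:
            continue
        c = concentration_from_n(fit.params.n_molecules, v_eff_l, constants)
        n_nuc = molecules_per_nucleus(c, nuclear_volume_l, constants)
        f_fast = fit.f_fast if fit.f_fast is not None else 1.0
        c_bound = bound_concentration(c, f_fast, bound_mode)
        dose = fit.meta.get("dose_per_cell")
        frac = per_cell_fraction(n_nuc, float(dose)) if dose else None
        out.append(
            NuclearQuant(
                concentration_m=c,
                n_nucleus=n_nuc,
                c_bound_m=c_bound,
                f_fast=fit.f_fast,
                nuclear_volume_l=nuclear_volume_l,
                dose_per_cell=float(dose) if dose else None,
                nuclear_fraction=frac,
            )
        )
    return out


def condition_table(
    quants_by_condition: dict[str, list[NuclearQuant]]
) -> pd.DataFrame:
    """Per-condition summary: n, mean ± SEM concentration (nM), copies, C_bound."""
    rows = []
    for cond, quants in sorted(quants_by_condition.items()):
        c_nm = np.array([q.concentration_nm for q in quants])
        n_nuc = np.array([q.n_nucleus for q in quants])
        c_bound = np.array([q.c_bound_nm for q in quants])
        fracs = [q.nuclear_fraction for q in quants if q.nuclear_fraction is not None]
        rows.append(
            {
                "condition": cond,
                "n_cells_accepted": len(quants),
                "mean_conc_nM": c_nm.mean() if c_nm.size else math.nan,
                "sem_conc_nM": (
                    c_nm.std(ddof=1) / math.sqrt(c_nm.size) if c_nm.size > 1 else math.nan
                ),
                "mean_molecules_per_nucleus": (
                    two_sig_figs(float(n_nuc.mean())) if n_nuc.size else math.nan
                ),
                "mean_c_bound_nM": c_bound.mean() if c_bound.size else math.nan,
                "mean_nuclear_fraction": (
                    float(np.mean(fracs)) if fracs else math.nan
                ),
            }
        )
    return pd.DataFrame(rows)
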