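"""Dose-response (4PL) fits, fold-changes, and editing-kinetics summaries.

Editing efficiency versus delivered Cas9 dose is modeled with the
four-parameter logistic

    response(x) = bottom + (top − bottom) / (1 + (EC50/x)^hill),

fitted on log10(dose) internally for conditioning, with bottom ≥ 0 and
top ≤ 100 because responses are percentages.  EC-levels other than 50
(e.g. EC90, the saturating-dose definition) are obtained by closed-form
inversion of the fitted curve.  Dose-to-nuclear-concentration mapping is
an ordinary linear regression, and time courses are summarized by the
half-maximal time (relative to the fitted plateau) and finite-difference
editing rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DoseResponseFit",
    "DoseToConcRegression",
    "TimeCourse",
    "NonIdentifiableError",
    "fit_4pl",
    "ec_at",
    "fold_change",
    "fit_dose_to_conc",
    "dose_to_conc",
    "halfmax_time",
    "editing_rate",
]


class NonIdentifiableError(RuntimeError):
    """The sigmoidal transition is not identifiable from the data."""


@dataclass
class DoseResponseFit:
    bottom: float  # % response
    top: float  # % response
    ec50: float  # dose units (molecules/cell) or hours for time fits
    hill: float
    r2: float
    n_points: int

    def __post_init__(self) -> None:
        if not (self.bottom < self.top):
            raise ValueError("bottom must be < top")
        if not (self.ec50 > 0):
            raise ValueError("ec50 must be > 0")

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.bottom + (self.top - self.bottom) / (1.0 + (self.ec50 / x) ** self.hill)


@dataclass
class DoseToConcRegression:
    slope: float  # nM per (molecules/cell)
    intercept: float  # nM
    r2: float
    dose_min: float = 0.0
    dose_max: float = math.inf


@dataclass
class TimeCourse:
    times: np.ndarray  # hours
    values: np.ndarray  # percent
    condition: str = ""
    dose_per_cell: float = math.nan
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any((self.values < 0) | (self.values > 100)):
            raise ValueError("values must be in [0, 100] percent")


def _4pl_log(logx: np.ndarray, bottom: float, top: float, log_ec50: float, hill: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - logx)))


def fit_4pl(doses, responses, max_response: float = 100.0) -> DoseResponseFit:
    """Least-squares 4PL fit of percent response versus dose.

    Requires ≥5 positive dose levels that actually span the transition;
    flat data raise :class:`NonIdentifiableError`.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    mask = doses > 0
    doses, responses = doses[mask], responses[mask]
    if np.unique(doses).size < 5:
        raise ValueError("need at least 5 positive dose levels")
    span = float(np.ptp(responses))
    if span < 1e-9:
        raise NonIdentifiableError("responses are flat: no transition in range")
    logx = np.log10(doses)
    p0 = [
        max(float(responses.min()), 0.0),
        min(float(responses.max()), max_response),
        float(np.median(logx)),
        1.0,
    ]
    if p0[1] - p0[0] < 1e-6:
        p0[1] = p0[0] + 1.0
    bounds = (
        [0.0, 0.0, logx.min() - 3.0, 0.05],
        [max_response, max_response, logx.max() + 3.0, 10.0],
    )
    try:
        popt, _ = optimize.curve_fit(
            _4pl_log, logx, responses, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        raise NonIdentifiableError(f"4PL fit did not converge: {exc}") from exc
    bottom, top, log_ec50, hill = popt
    if top - bottom < 1e-9:
        raise NonIdentifiableError("fitted span is zero: no transition identifiable")
    pred = _4pl_log(logx, *popt)
    ss_res = float(np.sum((responses - pred) ** 2))
    ss_tot = float(np.sum((responses - responses.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return DoseResponseFit(
        bottom=float(bottom),
        top=float(top),
        ec50=float(10.0**log_ec50),
        hill=float(hill),
        r2=r2,
        n_points=int(doses.size),
    )


def ec_at(fit: DoseResponseFit, level: float) -> float:
    """Dose producing ``level`` % of the fitted span (EC50 at level=50).

    Closed-form inversion: x = EC50·(level/(100−level))^(1/hill).
    """
    if not (0.0 < level < 100.0):
        raise ValueError("level must be in (0, 100)")
    return fit.ec50 * (level / (100.0 - level)) ** (1.0 / fit.hill)


def fold_change(ec50_reference: float, ec50_test: float) -> float:
    """Dose reduction factor: reference EC50 over test EC50."""
    if not (ec50_reference > 0 and ec50_test > 0):
        raise ValueError("EC50 values must be > 0")
    return ec50_reference / ec50_test


def fit_dose_to_conc(doses, conc_nm) -> DoseToConcRegression:
    """Linear regression of nuclear concentration (nM) on per-cell dose."""
    doses = np.asarray(doses, dtype=float)
    conc_nm = np.asarray(conc_nm, dtype=float)
    if doses.size < 3:
        raise ValueError("regression requires at least 3 points")
    res = stats.linregress(doses, conc_nm)
    return DoseToConcRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        dose_min=float(doses.min()),
        dose_max=float(doses.max()),
    )


def dose_to_conc(regression: DoseToConcRegression, dose: float) -> tuple[float, bool]:
    """Predicted nuclear concentration (nM) and an extrapolation flag.

    The flag is set when the dose lies beyond twice the fitted range.
    """
    pred = regression.slope * dose + regression.intercept
    extrapolated = dose > 2.0 * regression.dose_max or dose < regression.dose_min / 2.0
    return pred, extrapolated


def _interp_crossing(times: np.ndarray, values: np.ndarray, target: float) -> float:
    above = values >= target
    idx = np.nonzero(above)[0]
    if not idx.size:
        raise ValueError("course never crosses the target level")
    i = idx[0]
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    v0, v1 = values[i - 1], values[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (target - v0) / (v1 - v0) * (t1 - t0))


def halfmax_time(tc: TimeCourse) -> float:
    """Time (h) at half the fitted plateau of an editing time course.

    Fits a 4PL in time and returns its EC50 (half-max is defined relative
    to the fitted plateau, not to 100%); falls back to linear
    interpolation between the bracketing time points when the sigmoidal
    fit is not identifiable.
    """
    if tc.values.size == 0 or tc.values[-1] <= 0:
        raise ValueError("final value must be > 0")
    try:
        fit = fit_4pl(tc.times, tc.values)
        # closed-form crossing of the fitted curve at half its plateau;
        # equals the fitted EC50 when the fitted baseline is zero
        target = fit.top / 2.0
        if fit.bottom < target:
            ratio = (fit.top - fit.bottom) / (target - fit.bottom) - 1.0
            if ratio > 0:
                t_half = fit.ec50 / ratio ** (1.0 / fit.hill)
                if tc.times.min() <= t_half <= tc.times.max():
                    return float(t_half)
    except (NonIdentifiableError, ValueError):
        pass
    plateau = float(tc.values.max())
    return _interp_crossing(tc.times, tc.values, plateau / 2.0)


def editing_rate(tc: TimeCourse, window: tuple[float, float]) -> float:
    """Finite-difference editing rate (% per hour) over a time window.

    Values at the window endpoints are obtained by linear interpolation.
    """
    h_start, h_end = window
    if not (h_end > h_start):
        raise ValueError("window must have h_end > h_start")
    if h_start < tc.times.min() or h_end > tc.times.max():
        raise ValueError("window endpoints must lie within the time course")
    v_start = float(np.interp(h_start, tc.times, tc.values))
    v_end = float(np.interp(h_end, tc.times, tc.values))
    return (v_end - v_start) / (h_end - h_start)
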