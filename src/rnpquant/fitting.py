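"""Model fitting, model selection, and quality-control filtering.

Autocorrelation curves are fitted by weighted least squares (lmfit,
Levenberg–Marquardt) with the structure factor held fixed.  One- and
two-component fits are compared by χ² and the accepted two-component
fits are filtered by the dwell-time, anomaly-exponent and χ² rules used
for live-cell nuclear measurements:

* τ_diff1 < 0.5 ms  → free RNA (uncomplexed guide)
* τ_diff1 > 10 ms   → aggregation
* α < 0.3           → low_alpha
* χ² > 30           → high_chi2
* one-component fit selected where two components were required
                    → no_second_component

χ² is by default the *reduced* statistic — sum of squared weighted
residuals divided by (n_lags − n_params) — so the cutoff is comparable
across lag-grid sizes; a raw (unreduced) mode is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import lmfit

from .models import (
    AcfCurve,
    AnomalousParams,
    OneComponentParams,
    TwoComponentParams,
    DEFAULT_STRUCTURE_FACTOR,
    eval_anomalous,
    eval_one_component,
    eval_two_component,
)

__all__ = [
    "FitResult",
    "QcThresholds",
    "fit_curve",
    "select_model",
    "qc_filter",
    "fit_and_select",
    "condition_summary",
]

# parameter bounds shared by all models
_N_BOUNDS = (1e-3, 1e4)
_TAU_BOUNDS = (1e-6, 1.0)
_ALPHA_BOUNDS = (0.05, 1.5)

_MODELS = ("one_component", "anomalous", "two_component")


@dataclass
class QcThresholds:
    """Acceptance thresholds for nuclear two-component fits (all configurable)."""

    tau1_min_s: float = 0.5e-3
    tau1_max_s: float = 10e-3
    alpha_min: float = 0.3
    chi2_max: float = 30.0
    require_second_component: bool = True


@dataclass
class FitResult:
    model: str
    params: Optional[object]  # the matching *Params dataclass, None if not converged
    chi2: float
    converged: bool
    chi2_mode: str = "reduced"
    has_second_component: bool = True
    qc_status: Optional[str] = None  # "pass" / "fail" after qc_filter
    qc_reasons: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def tau_diff1(self) -> Optional[float]:
        if self.params is None:
            return None
        if self.model == "two_component":
            return self.params.tau_diff1
        return self.params.tau_diff

    @property
    def tau_diff2(self) -> Optional[float]:
        if self.model == "two_component" and self.params is not None:
            return self.params.tau_diff2
        return None

    @property
    def alpha(self) -> Optional[float]:
        if self.params is None or self.model == "one_component":
            return None
        return self.params.alpha

    @property
    def f_fast(self) -> Optional[float]:
        if self.model == "two_component" and self.params is not None:
            return self.params.f_fast
        return None

    def mean_tau_diff(self) -> Optional[float]:
        """Amplitude-weighted mean dwell time of a two-component fit."""
        if self.model != "two_component" or self.params is None:
            return self.tau_diff1
        p = self.params
        return p.f_fast * p.tau_diff1 + (1.0 - p.f_fast) * p.tau_diff2


def _eval(model: str, lmpars: lmfit.Parameters, lags: np.ndarray, s: float) -> np.ndarray:
    v = lmpars.valuesdict()
    if model == "one_component":
        return eval_one_component(
            OneComponentParams(v["n"], v["tau1"], s), lags
        )
    if model == "anomalous":
        return eval_anomalous(
            AnomalousParams(v["n"], v["tau1"], v["alpha"], v["g_inf"], s), lags
        )
    tau2 = v["tau1"] * (1.0 + v["delta"])
    return eval_two_component(
        TwoComponentParams(v["n"], v["tau1"], tau2, v["alpha"], v["f_fast"], s), lags
    )


def _initial_guess(curve: AcfCurve) -> tuple[float, float]:
    """(N0, tau0) from the early plateau and its half-fall lag."""
    g = curve.g
    lags = curve.lags
    plateau = float(np.mean(g[: max(3, len(g) // 20)]))
    if plateau <= 0:
        plateau = max(float(np.max(g)), 1e-3)
    n0 = min(max(1.0 / plateau, _N_BOUNDS[0] * 1.01), _N_BOUNDS[1] * 0.99)
    below = np.nonzero(g < plateau / 2.0)[0]
    if below.size:
        tau0 = float(lags[below[0]])
    else:
        tau0 = float(np.median(lags))
    tau0 = min(max(tau0, _TAU_BOUNDS[0] * 1.01), _TAU_BOUNDS[1] * 0.99)
    return n0, tau0


def _build_params(model: str, n0: float, tau0: float, f0: float = 0.5) -> lmfit.Parameters:
    p = lmfit.Parameters()
    p.add("n", value=n0, min=_N_BOUNDS[0], max=_N_BOUNDS[1])
    p.add("tau1", value=tau0, min=_TAU_BOUNDS[0], max=_TAU_BOUNDS[1])
    if model in ("anomalous", "two_component"):
        p.add("alpha", value=0.8, min=_ALPHA_BOUNDS[0], max=_ALPHA_BOUNDS[1])
    if model == "anomalous":
        p.add("g_inf", value=0.0, min=-0.5, max=0.5)
    if model == "two_component":
        # tau2 = tau1*(1+delta) keeps the fast/slow ordering by construction
        p.add("delta", value=4.0, min=1e-2, max=1e4)
        p.add("f_fast", value=f0, min=0.0, max=1.0)
    return p


def fit_curve(
    curve: AcfCurve,
    model: str = "two_component",
    s_fixed: float = DEFAULT_STRUCTURE_FACTOR,
    chi2_mode: str = "reduced",
    n_restarts: int = 3,
    restart_seed: int = 0,
) -> FitResult:
    """Weighted least-squares fit of one ACF curve.

    Weights are 1/g_se when per-lag errors are present, otherwise the fit
    is unweighted.  ``n_restarts`` jittered initializations (seeded) guard
    against local minima; the best-χ² converged start wins.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}")
    if chi2_mode not in ("reduced", "raw"):
        raise ValueError("chi2_mode must be 'reduced' or 'raw'")
    if len(curve) < 20:
        raise ValueError("curve must have at least 20 lag points")
    if curve.lags[-1] / curve.lags[0] < 1e3:
        raise ValueError("curve must span at least 3 decades of lag time")

    w = 1.0 / curve.g_se if curve.g_se is not None else np.ones_like(curve.g)
    n0, tau0 = _initial_guess(curve)
    rng = np.random.default_rng(restart_seed)

    def residual(lmpars):
        return (_eval(model, lmpars, curve.lags, s_fixed) - curve.g) * w

    starts = [_build_params(model, n0, tau0)]
    for _ in range(max(0, n_restarts - 1)):
        jn = n0 * math.exp(rng.normal(0.0, 0.5))
        jt = tau0 * math.exp(rng.normal(0.0, 0.7))
        jn = min(max(jn, _N_BOUNDS[0] * 1.01), _N_BOUNDS[1] * 0.99)
        jt = min(max(jt, _TAU_BOUNDS[0] * 1.01), _TAU_BOUNDS[1] * 0.99)
        starts.append(_build_params(model, jn, jt, f0=float(rng.uniform(0.2, 0.8))))

    best = None
    for p0 in starts:
        try:
            res = lmfit.minimize(residual, p0, method="leastsq")
        except Exception:
            continue
        if not res.success or not np.all(np.isfinite(list(res.params.valuesdict().values()))):
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res

    if best is None:
        return FitResult(
            model=model,
            params=None,
            chi2=math.inf,
            converged=False,
            chi2_mode=chi2_mode,
            qc_reasons=["no_convergence"],
            meta=dict(curve.meta),
        )

    v = best.params.valuesdict()
    nvary = best.nvarys
    chi2 = float(best.chisqr)
    if chi2_mode == "reduced":
        dof = max(len(curve) - nvary, 1)
        chi2 = chi2 / dof

    if model == "one_component":
        params = OneComponentParams(v["n"], v["tau1"], s_fixed)
        second = False
    elif model == "anomalous":
        params = AnomalousParams(v["n"], v["tau1"], v["alpha"], v["g_inf"], s_fixed)
        second = False
    else:
        tau2 = v["tau1"] * (1.0 + v["delta"])
        params = TwoComponentParams(
            v["n"], v["tau1"], tau2, v["alpha"], v["f_fast"], s_fixed
        )
        # degenerate mixtures are not a genuine second component
        second = (0.01 < v["f_fast"] < 0.99) and (tau2 / v["tau1"] > 1.05)

    return FitResult(
        model=model,
        params=params,
        chi2=chi2,
        converged=True,
        chi2_mode=chi2_mode,
        has_second_component=second,
        meta=dict(curve.meta),
    )


def select_model(fit_1c: FitResult, fit_2c: FitResult) -> FitResult:
    """Pick the better of two fits of the same curve by χ².

    Ties within 1e-9 relative favor the one-component model (parsimony).
    """
    if not fit_1c.converged and not fit_2c.converged:
        raise ValueError("both fits failed to converge")
    if not fit_1c.converged:
        return fit_2c
    if not fit_2c.converged:
        return fit_1c
    scale = max(abs(fit_1c.chi2), abs(fit_2c.chi2), 1e-300)
    if (fit_1c.chi2 - fit_2c.chi2) / scale <= 1e-9:
        return fit_1c
    return fit_2c


def qc_filter(fit: FitResult, thresholds: QcThresholds | None = None) -> FitResult:
    """Apply the acceptance thresholds; reasons cover *all* failing rules.

    Pure function: returns a copy with ``qc_status``/``qc_reasons`` set.
    """
    if thresholds is None:
        thresholds = QcThresholds()
    if not fit.converged:
        return replace(fit, qc_status="fail", qc_reasons=["no_convergence"])
    reasons = []
    tau1 = fit.tau_diff1
    if tau1 is not None and tau1 < thresholds.tau1_min_s:
        reasons.append("free_rna")
    if tau1 is not None and tau1 > thresholds.tau1_max_s:
        reasons.append("aggregation")
    alpha = fit.alpha
    if alpha is not None and alpha < thresholds.alpha_min:
        reasons.append("low_alpha")
    if fit.chi2 > thresholds.chi2_max:
        reasons.append("high_chi2")
    if thresholds.require_second_component and not (
        fit.model == "two_component" and fit.has_second_component
    ):
        reasons.append("no_second_component")
    status = "pass" if not reasons else "fail"
    return replace(fit, qc_status=status, qc_reasons=reasons)


def fit_and_select(
    curve: AcfCurve,
    s_fixed: float = DEFAULT_STRUCTURE_FACTOR,
    thresholds: QcThresholds | None = None,
    chi2_mode: str = "reduced",
    restart_seed: int = 0,
) -> FitResult:
    """Fit one- and two-component models, select by χ², and QC-filter."""
    f1 = fit_curve(curve, "one_component", s_fixed, chi2_mode, restart_seed=restart_seed)
    f2 = fit_curve(curve, "two_component", s_fixed, chi2_mode, restart_seed=restart_seed)
    if not f1.converged and not f2.converged:
        return qc_filter(f2, thresholds)
    chosen = select_model(f1, f2)
    return qc_filter(chosen, thresholds)


def condition_summary(fits: list[FitResult], min_pass: int = 20) -> pd.DataFrame:
    """Per-condition pass counts and mean ± SEM of the fitted parameters.

    Conditions with fewer than ``min_pass`` accepted curves are flagged
    ``insufficient_n``; the default of 20 reflects the minimum number of
    accepted concentration values required per condition.
    """
    rows = []
    by_cond: dict[str, list[FitResult]] = {}
    for f in fits:
        by_cond.setdefault(str(f.meta.get("condition", "default")), []).append(f)
    for cond, flist in sorted(by_cond.items()):
        passed = [f for f in flist if f.qc_status == "pass"]
        row = {
            "condition": cond,
            "n_total": len(flist),
            "n_pass": len(passed),
            "insufficient_n": len(passed) < min_pass,
        }
        for name, getter in [
            ("n_molecules", lambda f: f.params.n_molecules),
            ("tau_diff1_s", lambda f: f.tau_diff1),
            ("tau_diff2_s", lambda f: f.tau_diff2),
            ("f_fast", lambda f: f.f_fast),
        ]:
            vals = np.array(
                [getter(f) for f in passed if getter(f) is not None], dtype=float
            )
            row[f"mean_{name}"] = float(vals.mean()) if vals.size else math.nan
            row[f"sem_{name}"] = (
                float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else math.nan
            )
        rows.append(row)
    if not rows:
        rows.append(
            {"condition": "default", "n_total": 0, "n_pass": 0, "insufficient_n": True}
        )
    return pd.DataFrame(rows)
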