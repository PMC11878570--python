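"""Curve fitting, model selection, and QC filtering."""

import math

import numpy as np
import pytest

from rnpquant.fitting import (
    FitResult,
    QcThresholds,
    condition_summary,
    fit_and_select,
    fit_curve,
    qc_filter,
    select_model,
)
from rnpquant.models import (
    AcfCurve,
    AnomalousParams,
    OneComponentParams,
    TwoComponentParams,
)
from rnpquant.simulate import simulate_acf_direct


def _noiseless(params, **kw):
    return simulate_acf_direct(params, noise_sd=0.0, n_curves=1, **kw)[0]


class TestRoundTrip:
    def test_one_component_exact_recovery(self):
        curve = _noiseless(OneComponentParams(5.0, 2e-3))
        fit = fit_curve(curve, model="one_component")
        assert fit.converged
        assert fit.params.n_molecules == pytest.approx(5.0, rel=1e-6)
        assert fit.params.tau_diff == pytest.approx(2e-3, rel=1e-6)
        assert fit.chi2 < 1e-12

    def test_anomalous_exact_recovery(self):
        curve = _noiseless(AnomalousParams(8.0, 3e-3, alpha=0.7, g_inf=0.0))
        fit = fit_curve(curve, model="anomalous")
        assert fit.params.n_molecules == pytest.approx(8.0, rel=1e-4)
        assert fit.params.alpha == pytest.approx(0.7, rel=1e-3)

    def test_two_component_exact_recovery(self):
        truth = TwoComponentParams(5.0, 1e-3, 5e-3, alpha=0.8, f_fast=0.6)
        fit = fit_curve(_noiseless(truth), model="two_component")
        assert fit.params.n_molecules == pytest.approx(5.0, rel=1e-4)
        assert fit.params.tau_diff1 == pytest.approx(1e-3, rel=1e-3)
        assert fit.params.tau_diff2 == pytest.approx(5e-3, rel=1e-2)
        assert fit.params.f_fast == pytest.approx(0.6, abs=1e-3)

    def test_noisy_two_component_recovery(self):
        truth = TwoComponentParams(5.0, 1e-3, 5e-3, alpha=0.8, f_fast=0.6)
        curve = simulate_acf_direct(truth, noise_sd=0.02, n_curves=1, seed=11)[0]
        fit = fit_curve(curve, model="two_component")
        assert fit.params.n_molecules == pytest.approx(5.0, rel=0.10)
        assert fit.params.f_fast == pytest.approx(0.6, abs=0.15)

    def test_fit_requires_enough_lags_and_decades(self):
        short = AcfCurve(lags=np.logspace(-4, -1, 10), g=np.ones(10) * 0.1)
        with pytest.raises(ValueError):
            fit_curve(short)
        narrow = AcfCurve(lags=np.linspace(1e-3, 5e-3, 30), g=np.ones(30) * 0.1)
        with pytest.raises(ValueError):
            fit_curve(narrow)

    def test_white_noise_curve_fails_qc(self):
        rng = np.random.default_rng(5)
        lags = np.logspace(-5, 0, 100)
        g = rng.normal(0.0, 0.05, size=100)
        g_se = np.full(100, 1e-4)  # errors far smaller than the scatter
        curve = AcfCurve(lags=lags, g=g, g_se=g_se)
        fit = fit_curve(curve, model="two_component")
        res = qc_filter(fit)
        assert res.qc_status == "fail"
        assert {"no_convergence", "high_chi2"} & set(res.qc_reasons)


class TestSelectModel:
    def test_two_component_data_selects_two_component(self):
        truth = TwoComponentParams(5.0, 0.8e-3, 8e-3, alpha=0.8, f_fast=0.5)
        curve = simulate_acf_direct(truth, noise_sd=0.02, n_curves=1, seed=2)[0]
        f1 = fit_curve(curve, "one_component")
        f2 = fit_curve(curve, "two_component")
        assert select_model(f1, f2).model == "two_component"

    def test_tie_prefers_one_component(self):
        f1 = FitResult("one_component", OneComponentParams(5, 1e-3), 1.0, True)
        f2 = FitResult(
            "two_component", TwoComponentParams(5, 1e-3, 5e-3), 1.0 + 1e-12, True
        )
        assert select_model(f1, f2).model == "one_component"

    def test_nonconverged_fit_yields_the_other(self):
        good = FitResult("one_component", OneComponentParams(5, 1e-3), 1.0, True)
        bad = FitResult("two_component", None, math.inf, False)
        assert select_model(good, bad) is good
        assert select_model(bad, good) is good
        with pytest.raises(ValueError):
            select_model(bad, bad)


def _passing_fit(**overrides):
    defaults = dict(
        model="two_component",
        params=TwoComponentParams(5.0, 2e-3, 8e-3, alpha=0.8, f_fast=0.6),
        chi2=5.0,
        converged=True,
        has_second_component=True,
    )
    defaults.update(overrides)
    return FitResult(**defaults)


class TestQcFilter:
    def test_all_thresholds_satisfied_passes(self):
        res = qc_filter(_passing_fit())
        assert res.qc_status == "pass"
        assert res.qc_reasons == []

    @pytest.mark.parametrize(
        "fit,reason",
        [
            (
                _passing_fit(params=TwoComponentParams(5, 0.4e-3, 8e-3, alpha=0.8, f_fast=0.6)),
                "free_rna",
            ),
            (
                _passing_fit(params=TwoComponentParams(5, 12e-3, 40e-3, alpha=0.8, f_fast=0.6)),
                "aggregation",
            ),
            (
                _passing_fit(params=TwoComponentParams(5, 2e-3, 8e-3, alpha=0.2, f_fast=0.6)),
                "low_alpha",
            ),
            (_passing_fit(chi2=31.0), "high_chi2"),
            (
                _passing_fit(
                    model="one_component",
                    params=OneComponentParams(5, 2e-3),
                    has_second_component=False,
                ),
                "no_second_component",
            ),
        ],
        ids=["free_rna", "aggregation", "low_alpha", "high_chi2", "no_second_component"],
    )
    def test_each_threshold_triggers_named_reason(self, fit, reason):
        res = qc_filter(fit)
        assert res.qc_status == "fail"
        assert reason in res.qc_reasons

    def test_reasons_are_exhaustive_not_first_only(self):
        fit = _passing_fit(
            params=TwoComponentParams(5, 0.4e-3, 8e-3, alpha=0.2, f_fast=0.6),
            chi2=40.0,
        )
        res = qc_filter(fit)
        assert set(res.qc_reasons) == {"free_rna", "low_alpha", "high_chi2"}

    def test_pure_function_same_input_same_output(self):
        fit = _passing_fit(chi2=31.0)
        r1, r2 = qc_filter(fit), qc_filter(fit)
        assert (r1.qc_status, r1.qc_reasons) == (r2.qc_status, r2.qc_reasons)
        assert fit.qc_status is None  # input untouched

    def test_thresholds_configurable(self):
        fit = _passing_fit(chi2=31.0)
        res = qc_filter(fit, QcThresholds(chi2_max=50.0))
        assert res.qc_status == "pass"

    def test_nonconverged_fit_fails(self):
        res = qc_filter(FitResult("two_component", None, math.inf, False))
        assert res.qc_status == "fail"
        assert res.qc_reasons == ["no_convergence"]


class TestConditionSummary:
    def _fits(self, n_pass, n_fail, condition="c1"):
        out = []
        for i in range(n_pass):
            f = qc_filter(_passing_fit())
            f.meta = {"condition": condition}
            out.append(f)
        for i in range(n_fail):
            f = qc_filter(_passing_fit(chi2=40.0))
            f.meta = {"condition": condition}
            out.append(f)
        return out

    def test_sufficient_condition_accepted(self):
        df = condition_summary(self._fits(25, 5))
        assert df.loc[0, "n_pass"] == 25
        assert not df.loc[0, "insufficient_n"]

    def test_undersampled_condition_flagged(self):
        df = condition_summary(self._fits(15, 15))
        assert df.loc[0, "insufficient_n"]

    def test_empty_input(self):
        df = condition_summary([])
        assert df.loc[0, "n_pass"] == 0
        assert df.loc[0, "insufficient_n"]

    def test_reports_mean_and_sem(self):
        df = condition_summary(self._fits(25, 0))
        assert df.loc[0, "mean_f_fast"] == pytest.approx(0.6)
        assert df.loc[0, "sem_f_fast"] == pytest.approx(0.0)


class TestFitAndSelect:
    def test_pipeline_on_two_component_data(self):
        truth = TwoComponentParams(5.0, 1e-3, 5e-3, alpha=0.8, f_fast=0.6)
        curve = simulate_acf_direct(truth, noise_sd=0.02, n_curves=1, seed=7)[0]
        curve.meta["condition"] = "rnp"
        res = fit_and_select(curve)
        assert res.model == "two_component"
        assert res.qc_status == "pass"
        assert res.meta["condition"] == "rnp"

    def test_mean_tau_diff_is_amplitude_weighted(self):
        fit = _passing_fit()
        expected = 0.6 * 2e-3 + 0.4 * 8e-3
        assert fit.mean_tau_diff() == pytest.approx(expected)
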