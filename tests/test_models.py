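"""Closed-form autocorrelation models: frozen hand values and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnpquant.models import (
    AcfCurve,
    AnomalousParams,
    OneComponentParams,
    TwoComponentParams,
    eval_anomalous,
    eval_one_component,
    eval_two_component,
)

LOG_GRID = np.logspace(-6, 1, 120)


class TestOneComponent:
    def test_amplitude_limit_is_inverse_n(self):
        p = OneComponentParams(n_molecules=1.0, tau_diff=1e-3)
        assert eval_one_component(p, 1e-9) == pytest.approx(1.0, rel=1e-3)

    def test_hand_value_at_tau_equals_tau_diff(self):
        # (1/5) / (2 * sqrt(1 + 0.17^2)) = 0.0985856
        p = OneComponentParams(n_molecules=5.0, tau_diff=1e-3)
        assert eval_one_component(p, 1e-3) == pytest.approx(0.09858558, abs=1e-7)

    def test_decays_to_zero(self):
        p = OneComponentParams(n_molecules=2.0, tau_diff=1e-3)
        assert eval_one_component(p, 1e6 * 1e-3) < 1e-4

    def test_rejects_nonpositive_tau(self):
        p = OneComponentParams(n_molecules=1.0, tau_diff=1e-3)
        with pytest.raises(ValueError):
            eval_one_component(p, 0.0)

    def test_rejects_nonpositive_params(self):
        with pytest.raises(ValueError):
            OneComponentParams(n_molecules=-1.0, tau_diff=1e-3)
        with pytest.raises(ValueError):
            OneComponentParams(n_molecules=1.0, tau_diff=0.0)


class TestAnomalous:
    def test_alpha_one_reduces_to_free_diffusion(self):
        pa = AnomalousParams(n_molecules=3.0, tau_diff=2e-3, alpha=1.0, g_inf=0.0)
        p1 = OneComponentParams(n_molecules=3.0, tau_diff=2e-3)
        np.testing.assert_allclose(
            eval_anomalous(pa, LOG_GRID), eval_one_component(p1, LOG_GRID), rtol=1e-12
        )

    def test_hand_value_standard_placement(self):
        # x = 1 so x^alpha = 1: (1/10)/(2*sqrt(1.0289)) = 0.04929279
        p = AnomalousParams(n_molecules=10.0, tau_diff=2e-3, alpha=0.8, g_inf=0.0)
        assert eval_anomalous(p, 2e-3) == pytest.approx(0.04929279, abs=1e-7)

    def test_hand_value_printed_placement(self):
        # 1 / (10 * 2^0.8 * (1 + 0.17^2)^0.4) = 0.05678410 (30-digit arithmetic)
        p = AnomalousParams(
            n_molecules=10.0, tau_diff=2e-3, alpha=0.8, g_inf=0.0, placement="printed"
        )
        assert eval_anomalous(p, 2e-3) == pytest.approx(0.056784099, abs=1e-8)

    def test_long_lag_limit_is_g_inf(self):
        p = AnomalousParams(n_molecules=2.0, tau_diff=1e-3, alpha=0.7, g_inf=0.013)
        assert eval_anomalous(p, 1e5) == pytest.approx(0.013, abs=1e-4)

    def test_rejects_bad_alpha(self):
        with pytest.raises(ValueError):
            AnomalousParams(n_molecules=1.0, tau_diff=1e-3, alpha=0.0)
        with pytest.raises(ValueError):
            AnomalousParams(n_molecules=1.0, tau_diff=1e-3, alpha=1.6)


class TestTwoComponent:
    def test_degenerate_fractions_reduce_to_single_species(self):
        base = dict(n_molecules=4.0, tau_diff1=1e-3, tau_diff2=5e-3, alpha=0.8)
        p_fast = TwoComponentParams(**base, f_fast=1.0)
        np.testing.assert_allclose(
            eval_two_component(p_fast, LOG_GRID),
            eval_one_component(OneComponentParams(4.0, 1e-3), LOG_GRID),
            rtol=1e-12,
        )
        p_slow = TwoComponentParams(**base, f_fast=0.0)
        np.testing.assert_allclose(
            eval_two_component(p_slow, LOG_GRID),
            eval_anomalous(AnomalousParams(4.0, 5e-3, 0.8, 0.0), LOG_GRID),
            rtol=1e-12,
        )

    def test_equal_mixture_hand_value(self):
        p = TwoComponentParams(5.0, 1e-3, 2e-3, alpha=1.0, f_fast=0.5)
        g1 = eval_one_component(OneComponentParams(1.0, 1e-3), 1e-3)
        g2 = eval_one_component(OneComponentParams(1.0, 2e-3), 1e-3)
        assert eval_two_component(p, 1e-3) == pytest.approx((g1 + g2) / 2 / 5.0, rel=1e-12)

    def test_sum_form_is_weighted_mixture(self):
        p = TwoComponentParams(7.0, 0.8e-3, 6e-3, alpha=0.9, f_fast=0.37)
        fast = eval_one_component(OneComponentParams(1.0, 0.8e-3), LOG_GRID)
        slow = eval_anomalous(AnomalousParams(1.0, 6e-3, 0.9, 0.0), LOG_GRID)
        expected = (0.37 * fast + 0.63 * slow) / 7.0
        np.testing.assert_allclose(eval_two_component(p, LOG_GRID), expected, rtol=1e-12)

    def test_literal_product_amplitude(self):
        # printed product form: G(0+) -> F*(1-F)/N, not 1/N
        p = TwoComponentParams(
            5.0, 1e-3, 5e-3, alpha=1.0, f_fast=0.5, form="literal_product"
        )
        assert eval_two_component(p, 1e-9) == pytest.approx(0.25 / 5.0, rel=1e-3)

    def test_enforces_tau_ordering(self):
        with pytest.raises(ValueError):
            TwoComponentParams(5.0, 5e-3, 1e-3)
        with pytest.raises(ValueError):
            TwoComponentParams(5.0, 1e-3, 1e-3)

    def test_rejects_fraction_outside_unit_interval(self):
        with pytest.raises(ValueError):
            TwoComponentParams(5.0, 1e-3, 5e-3, f_fast=1.2)


class TestSharedInvariants:
    @pytest.mark.parametrize("alpha", [0.5, 0.8, 1.0])
    def test_sum_form_strictly_decreasing_for_subdiffusion(self, alpha):
        p = TwoComponentParams(3.0, 1e-3, 5e-3, alpha=alpha, f_fast=0.6)
        g = eval_two_component(p, LOG_GRID)
        assert np.all(np.diff(g) < 0)

    def test_zero_lag_amplitude_all_models(self):
        tau_probe = 1e-6 * 1e-3
        p1 = OneComponentParams(8.0, 1e-3)
        assert eval_one_component(p1, tau_probe) == pytest.approx(1 / 8.0, rel=1e-3)
        pa = AnomalousParams(8.0, 1e-3, 0.8, g_inf=0.02)
        assert eval_anomalous(pa, tau_probe) == pytest.approx(1 / 8.0 + 0.02, rel=1e-3)
        p2 = TwoComponentParams(8.0, 1e-3, 5e-3, alpha=0.8, f_fast=0.6)
        assert eval_two_component(p2, tau_probe) == pytest.approx(1 / 8.0, rel=1e-3)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        n=st.floats(0.1, 100.0),
        tau1=st.floats(1e-4, 5e-3),
        ratio=st.floats(1.5, 50.0),
        alpha=st.floats(0.3, 1.5),
        f=st.floats(0.05, 0.95),
    )
    def test_parameter_continuity(self, n, tau1, ratio, alpha, f):
        """1e-8 relative parameter perturbations move G by < 1e-4 relative."""
        tau = np.logspace(-5, 0, 30)
        base = TwoComponentParams(n, tau1, tau1 * ratio, alpha=alpha, f_fast=f)
        g0 = eval_two_component(base, tau)
        bumped = TwoComponentParams(
            n * (1 + 1e-8),
            tau1 * (1 + 1e-8),
            tau1 * ratio * (1 + 1e-8),
            alpha=min(alpha * (1 + 1e-8), 1.5),
            f_fast=min(f * (1 + 1e-8), 1.0),
        )
        g1 = eval_two_component(bumped, tau)
        assert np.max(np.abs(g1 - g0) / np.abs(g0)) < 1e-4


class TestAcfCurve:
    def test_validates_monotone_lags(self):
        with pytest.raises(ValueError):
            AcfCurve(lags=[1e-3, 1e-3, 2e-3], g=[1.0, 0.5, 0.2])

    def test_validates_g_se_positive(self):
        with pytest.raises(ValueError):
            AcfCurve(lags=[1e-3, 2e-3], g=[1.0, 0.5], g_se=[0.1, 0.0])

    def test_validates_finite_g(self):
        with pytest.raises(ValueError):
            AcfCurve(lags=[1e-3, 2e-3], g=[1.0, np.nan])
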