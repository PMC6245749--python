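import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import aerotree as at
from aerotree.analysis import (
    EfficiencyCurve, NoInteriorPeakError, StokesContext, optimal_sizes,
)
from aerotree.transport import DepositionResult


class TestSlipCorrection:
    @pytest.mark.parametrize("dp_um,expected", [(1.0, 1.166), (10.0, 1.017)])
    def test_reference_values(self, dp_um, expected):
        assert at.slip_correction(dp_um * 1e-6) == pytest.approx(expected,
                                                                 abs=1e-3)

    def test_continuum_limit(self):
        assert at.slip_correction(1e-3) == pytest.approx(1.0, abs=1e-3)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            at.slip_correction(0.0)


class TestStokesNumber:
    def test_zero_diameter(self):
        ctx = StokesContext(um=7.02, do=0.011)
        assert at.stokes_number(0.0, ctx) == 0.0

    def test_age5_dpi_optimum(self):
        """5.5 um at the age-5 DPI velocity scale sits near Stk 0.061."""
        ctx = StokesContext(um=7.02, do=0.011)
        assert at.stokes_number(5.5e-6, ctx) == pytest.approx(0.061, abs=1e-3)

    def test_age5_nebulizer_optimum(self):
        ctx = StokesContext(um=0.91, do=0.011)
        assert at.stokes_number(12e-6, ctx) == pytest.approx(0.037, abs=1e-3)


class TestReynolds:
    def test_zero_flow(self):
        assert at.reynolds_number(0.0, 0.011) == 0.0

    @pytest.mark.parametrize("q_lpm,d,expected", [
        (40.0, 0.011, 5.1e3), (90.0, 0.019, 6.7e3)])
    def test_dpi_pifr_values(self, q_lpm, d, expected):
        re = at.reynolds_number(q_lpm / 60e3, d)
        assert re == pytest.approx(expected, rel=0.02)


class TestRoundTrip:
    @settings(max_examples=60, deadline=None)
    @given(dp_um=st.floats(1.0, 20.0),
           age=st.sampled_from([5.0, 10.0, 25.0]),
           device=st.sampled_from([at.Device.DPI, at.Device.NEBULIZER]))
    def test_diameter_stokes_inversion(self, contexts, dp_um, age, device):
        """optimal_diameter inverts stokes_number to 1e-4 relative."""
        ctx = contexts[(age, device)]
        dp = dp_um * 1e-6
        back = at.optimal_diameter(at.stokes_number(dp, ctx), ctx)
        assert abs(back - dp) / dp < 1e-4

    def test_zero_stokes_limit(self, contexts):
        assert at.optimal_diameter(0.0, contexts[(5.0, at.Device.DPI)]) == 0.0


def _gaussian_curve(a, mu, sigma, stk, rng=None):
    eff = a * np.exp(-((stk - mu) ** 2) / (2 * sigma ** 2))
    if rng is not None:
        eff = np.clip(eff + rng.uniform(-0.02, 0.02, size=stk.size), 0.0, 1.0)
    return EfficiencyCurve(stk=stk, efficiency=eff, dp=stk, age=np.zeros_like(stk),
                           region="conducting", device=at.Device.DPI)


class TestGaussianFit:
    def test_noiseless_recovery(self):
        stk = np.linspace(0.01, 0.12, 20)
        fit = at.fit_gaussian(_gaussian_curve(0.8, 0.06, 0.02, stk))
        assert fit.amplitude == pytest.approx(0.8, abs=1e-6)
        assert fit.peak_stk == pytest.approx(0.06, abs=1e-6)
        assert fit.sigma_stk == pytest.approx(0.02, abs=1e-6)
        assert fit.rmse < 1e-8

    def test_noisy_recovery_100_replicates(self):
        """Uniform +/-0.02 noise: A within 0.05 and Stk* within 0.005."""
        rng = np.random.default_rng(42)
        stk = np.linspace(0.01, 0.12, 20)
        for _ in range(100):
            fit = at.fit_gaussian(_gaussian_curve(0.8, 0.06, 0.02, stk, rng))
            assert abs(fit.amplitude - 0.8) < 0.05
            assert abs(fit.peak_stk - 0.06) < 0.005

    def test_monotone_curve_rejected(self):
        stk = np.linspace(0.01, 0.2, 15)
        eta = at.mouth_throat_efficiency(stk)
        curve = EfficiencyCurve(stk=stk, efficiency=eta, dp=stk,
                                age=np.zeros_like(stk),
                                region="mouth_throat", device=at.Device.DPI)
        with pytest.raises(NoInteriorPeakError):
            at.fit_gaussian(curve)

    def test_too_few_points_rejected(self):
        stk = np.array([0.01, 0.05, 0.1])
        curve = _gaussian_curve(0.8, 0.05, 0.02, stk)
        with pytest.raises(ValueError, match="at least 5"):
            at.fit_gaussian(curve)


def _result(age, device, dp_um, conducting, escaped, n=1000):
    cond = int(round(conducting * n))
    esc = int(round(escaped * n))
    return DepositionResult(
        age=age, device=device, dp=dp_um * 1e-6,
        counts={"injected": n, "mouth_throat": n - cond - esc, "trachea": 0,
                "conducting": cond, "escaped": esc},
        escaped_by_lobe={}, segment_deposits={})


class TestEfficiencyCurve:
    def test_single_result_definition(self, contexts):
        ctx = {5.0: contexts[(5.0, at.Device.DPI)]}
        r = _result(5.0, at.Device.DPI, 5.0, conducting=0.6, escaped=0.2)
        curve = at.efficiency_curve([r], "conducting", ctx)
        assert len(curve) == 1
        assert curve.efficiency[0] == pytest.approx(0.6)

    def test_matched_stk_abscissas_coincide(self, contexts):
        """dp chosen per age to equalize Stk pools to equal abscissas."""
        ctx = {a: contexts[(a, at.Device.DPI)] for a in (5.0, 10.0, 25.0)}
        target = 0.06
        results = [
            _result(a, at.Device.DPI,
                    at.optimal_diameter(target, ctx[a]) * 1e6,
                    conducting=0.5, escaped=0.3)
            for a in ctx]
        curve = at.efficiency_curve(results, "conducting", ctx)
        assert np.allclose(curve.stk, target, rtol=1e-3)

    def test_mixed_devices_rejected(self, contexts):
        ctx = {5.0: contexts[(5.0, at.Device.DPI)]}
        results = [_result(5.0, at.Device.DPI, 5.0, 0.5, 0.3),
                   _result(5.0, at.Device.NEBULIZER, 5.0, 0.5, 0.3)]
        with pytest.raises(ValueError, match="mixed devices"):
            at.efficiency_curve(results, "conducting", ctx)

    def test_empty_rejected(self, contexts):
        with pytest.raises(ValueError):
            at.efficiency_curve([], "conducting", {})


class TestCollapse:
    def _curve(self, stk, eff, age):
        return EfficiencyCurve(stk=stk, efficiency=eff, dp=stk,
                               age=np.full_like(stk, age),
                               region="total", device=at.Device.DPI)

    def test_identical_curves_collapse_exactly(self):
        stk = np.linspace(0.01, 0.1, 10)
        eff = np.linspace(0.1, 0.9, 10)
        curves = [self._curve(stk, eff, a) for a in (5, 10, 25)]
        assert at.collapse_diagnostic(curves) == 0.0

    def test_offset_curves_report_the_offset(self):
        stk = np.linspace(0.01, 0.1, 10)
        eff = np.linspace(0.1, 0.8, 10)
        curves = [self._curve(stk, eff, 5), self._curve(stk, eff + 0.1, 10)]
        assert at.collapse_diagnostic(curves) == pytest.approx(0.1)

    def test_disjoint_ranges_rejected(self):
        a = self._curve(np.linspace(0.01, 0.02, 5), np.full(5, 0.5), 5)
        b = self._curve(np.linspace(0.05, 0.06, 5), np.full(5, 0.5), 10)
        with pytest.raises(ValueError, match="overlap"):
            at.collapse_diagnostic([a, b])


def test_optimal_sizes_orderings(contexts):
    """At fixed peak Stk, dp_opt grows with age (Do/Um increases)."""
    fit = at.GaussianFit(amplitude=0.8, peak_stk=0.06, sigma_stk=0.02,
                         rmse=0.01)
    ctxs = [contexts[(a, at.Device.DPI)] for a in (5.0, 10.0, 25.0)]
    opts = optimal_sizes(fit, ctxs)
    dps = [o.dp_opt for o in opts]
    assert dps == sorted(dps)
    assert all(o.dp_spread > 0 for o in opts)
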