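"""Two-state fitting, the van't Hoff plot, and route consolidation."""

import numpy as np
import pytest

from duplextherm import (
    NoTransitionError,
    ThermoParams,
    consolidate_parameters,
    fit_two_state,
    melting_temperature,
    tm_from_derivative,
    vant_hoff_regression,
)
from duplextherm.fitting import TwoStateFitResult, vant_hoff_from_fits
from duplextherm.simulate import MeltingCurve, SimulationConfig, generate_ct_series, generate_melting_curve


def grid_search_sse(curve, truth, cfg) -> float:
    """Coarse 6-parameter grid around truth; independent SSE oracle."""
    from duplextherm.fitting import _model_absorbance

    tm = melting_temperature(truth.dH, truth.dS, curve.Ct)
    best = np.inf
    for dh in truth.dH + np.array([-4.0, 0.0, 4.0]):
        for tmv in tm + np.array([-0.5, 0.0, 0.5]):
            for b_ds in cfg.b_ds + np.array([-0.005, 0.0, 0.005]):
                for b_ss in cfg.b_ss + np.array([-0.005, 0.0, 0.005]):
                    theta = np.array([dh, tmv, b_ds, cfg.m_ds, b_ss, cfg.m_ss])
                    sse = np.sum(
                        (_model_absorbance(theta, curve.temperatures, curve.Ct)
                         - curve.absorbance) ** 2
                    )
                    best = min(best, sse)
    return best


class TestFitTwoState:
    def test_noiseless_recovery_within_tenth_percent(self, noiseless_curve, truth):
        res = fit_two_state(noiseless_curve)
        assert res.converged
        assert abs(res.params.dH - truth.dH) < 0.1
        assert res.params.dH == pytest.approx(truth.dH, rel=1e-3)

    def test_tm_consistent_with_closed_form(self, noiseless_curve):
        res = fit_two_state(noiseless_curve)
        assert res.Tm == pytest.approx(
            melting_temperature(res.params.dH, res.params.dS, res.Ct), abs=0.01
        )

    def test_noisy_recovery_median_under_five_percent(self, truth):
        errs = []
        for seed in range(50):
            cfg = SimulationConfig(truth=truth, noise_sd=0.002, seed=seed)
            res = fit_two_state(generate_melting_curve(cfg, 1e-5))
            errs.append(abs(res.params.dH - truth.dH) / abs(truth.dH))
        assert np.median(errs) < 0.05

    def test_flat_line_raises_no_transition(self):
        t = np.arange(0.0, 95.5, 0.5)
        curve = MeltingCurve(temperatures=t, absorbance=np.full_like(t, 0.7), Ct=1e-5)
        with pytest.raises(NoTransitionError):
            fit_two_state(curve)

    def test_beats_grid_search_oracle(self, truth, rng):
        cfg_kwargs = dict(truth=truth, noise_sd=0.002)
        for seed in rng.integers(0, 2**31, size=10):
            cfg = SimulationConfig(seed=int(seed), **cfg_kwargs)
            curve = generate_melting_curve(cfg, 1e-5)
            res = fit_two_state(curve)
            assert res.sse <= grid_search_sse(curve, truth, cfg) + 1e-12


class TestTmFromDerivative:
    def test_tracks_closed_form_with_bimolecular_bias(self, truth):
        # the steepest point of a bimolecular transition sits ~R·Tm²/|dH|
        # (~1 K here) above the f = 1/2 temperature; with equal baseline
        # slopes the estimator should land on that physical optimum
        cfg = SimulationConfig(
            truth=truth, noise_sd=0.0, m_ds=2e-4, m_ss=2e-4, t_step=0.25, seed=0
        )
        curve = generate_melting_curve(cfg, 1e-5)
        tm = melting_temperature(truth.dH, truth.dS, 1e-5)
        estimate = tm_from_derivative(curve)
        assert estimate == pytest.approx(tm + 1.02, abs=0.5)
        assert abs(estimate - tm) < 1.5

    def test_monotone_baseline_only_raises(self):
        t = np.arange(0.0, 95.5, 0.5)
        curve = MeltingCurve(temperatures=t, absorbance=0.6 + 1e-3 * t, Ct=1e-5)
        with pytest.raises(NoTransitionError):
            tm_from_derivative(curve)

    def test_invariant_to_constant_offset(self, noiseless_curve):
        shifted = MeltingCurve(
            temperatures=noiseless_curve.temperatures,
            absorbance=noiseless_curve.absorbance + 0.35,
            Ct=noiseless_curve.Ct,
        )
        assert tm_from_derivative(shifted) == tm_from_derivative(noiseless_curve)


class TestVantHoffRegression:
    def test_exact_recovery_from_closed_form_points(self):
        dh, ds = -90.0, -250.0
        pts = [(ct, melting_temperature(dh, ds, ct)) for ct in (1e-6, 1e-5, 1e-4, 1e-3)]
        vh = vant_hoff_regression(pts)
        assert vh.params.dH == pytest.approx(dh, rel=1e-12)
        assert vh.params.dS == pytest.approx(ds, rel=1e-12)
        assert vh.r_squared == pytest.approx(1.0, abs=1e-12)
        # internal consistency of the derived parameters (2.303 = ln 10)
        assert vh.params.dH == pytest.approx(np.log(10.0) * 1.987e-3 / vh.slope, abs=1e-9)
        assert vh.params.dS == pytest.approx(1000.0 * vh.intercept * vh.params.dH, abs=1e-9)

    def test_duplicate_concentrations_rejected(self):
        pts = [(1e-5, 330.0), (1e-5, 331.0), (1e-5, 332.0)]
        with pytest.raises(ValueError, match="distinct"):
            vant_hoff_regression(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            vant_hoff_regression([(1e-5, 330.0), (1e-4, 334.0)])

    def test_rising_tm_with_dilution_rejected(self):
        # Tm falling with Ct implies dH >= 0: not a melting series
        pts = [(1e-6, 340.0), (1e-5, 335.0), (1e-4, 330.0)]
        with pytest.raises(ValueError, match="dH >= 0"):
            vant_hoff_regression(pts)

    def test_jittered_tm_recovers_dh_within_ten_percent(self, rng):
        dh, ds = -90.0, -250.0
        cts = np.logspace(-6, -4, 5)
        ok = 0
        n = 100
        for _ in range(n):
            pts = [
                (ct, melting_temperature(dh, ds, ct) + rng.normal(0.0, 0.2))
                for ct in cts
            ]
            vh = vant_hoff_regression(pts)
            ok += abs(vh.params.dH - dh) / abs(dh) < 0.10
        assert ok / n > 0.9


class TestConsolidateParameters:
    def _fit(self, params, converged=True, ct=1e-5):
        tm = melting_temperature(params.dH, params.dS, ct)
        return TwoStateFitResult(
            params=params, b_ds=0.6, m_ds=2e-4, b_ss=0.75, m_ss=3e-4,
            Tm=tm, Ct=ct, sse=0.0, converged=converged, n_iter=1,
        )

    def _vh(self, params):
        from duplextherm.fitting import VantHoffResult

        return VantHoffResult(
            params=params, slope=2.303 * 1.987e-3 / params.dH,
            intercept=params.dS / (1000.0 * params.dH), r_squared=1.0, n_points=4,
        )

    def test_identical_sources_idempotent(self, truth):
        cons = consolidate_parameters([self._fit(truth)], self._vh(truth))
        assert cons.params == truth
        assert cons.two_state_flag

    def test_large_discrepancy_flags_false(self):
        fit_p = ThermoParams(dH=-90.0, dS=-252.0)
        vh_p = ThermoParams(dH=-120.0, dS=-340.0)
        cons = consolidate_parameters([self._fit(fit_p)], self._vh(vh_p))
        assert not cons.two_state_flag
        assert cons.dh_discrepancy == pytest.approx(30.0 / 105.0, rel=1e-9)

    def test_non_converged_fits_excluded(self, truth):
        bogus = ThermoParams(dH=-500.0, dS=-1500.0)
        cons = consolidate_parameters(
            [self._fit(truth), self._fit(bogus, converged=False)], self._vh(truth)
        )
        assert cons.params == truth

    def test_no_converged_fits_raises(self, truth):
        with pytest.raises(ValueError, match="no converged"):
            consolidate_parameters([self._fit(truth, converged=False)], self._vh(truth))

    def test_two_state_flag_rate_on_synthetic_data(self, truth):
        flags = 0
        n = 40
        for seed in range(n):
            cfg = SimulationConfig(truth=truth, noise_sd=0.002, seed=seed)
            fits = [fit_two_state(c) for c in generate_ct_series(cfg)]
            vh = vant_hoff_from_fits(fits)
            flags += consolidate_parameters(fits, vh).two_state_flag
        assert flags / n >= 0.95
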