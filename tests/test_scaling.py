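"""Power-law fits, finite-size filtering, data collapse and the
universal-amplitude-ratio predictor."""

import numpy as np
import pandas as pd
import pytest

from stickerslab.scaling import (
    UNIVERSAL,
    InsufficientDataError,
    collapse_and_extent,
    finite_size_filter,
    fit_power_law,
    fit_power_law_free,
    fit_with_filter,
    gamma_from_universal_ratio,
    reduced_temperature,
    tau_star_sensitivity,
    validate_prediction,
)
from stickerslab.synth import gen_powerlaw_gamma
from stickerslab.units import KB_SI


class TestConstants:
    def test_exponent_identity(self):
        assert UNIVERSAL.nu == UNIVERSAL.mu / (UNIVERSAL.dims - 1)
        assert UNIVERSAL.nu == pytest.approx(0.63)

    def test_amplitude_ratio_coefficient(self):
        assert UNIVERSAL.surface_tension_prefactor == pytest.approx(1.6384)


class TestReducedTemperature:
    def test_arithmetic(self):
        assert reduced_temperature(300.0, 300.0) == 0.0
        assert reduced_temperature(240.0, 300.0) == pytest.approx(0.2)

    def test_supercritical_flagged(self):
        with pytest.warns(UserWarning, match="supercritical"):
            tau = reduced_temperature(310.0, 300.0)
        assert tau < 0


class TestFiniteSizeFilter:
    def test_threshold_arithmetic(self):
        keep = finite_size_filter(np.array([12.0, 13.0, 5.0, 1.0]), lx=250.0)
        assert keep.tolist() == [True, False, True, True]

    def test_all_excluded_raises(self):
        with pytest.raises(InsufficientDataError):
            finite_size_filter(np.array([20.0, 30.0, 40.0]), lx=250.0)


class TestFitPowerLaw:
    def test_noiseless_gamma_recovery(self):
        T = np.arange(240.0, 301.0, 10.0)
        y = 2.0 * (1 - T / 320.0) ** 1.26
        fit = fit_power_law(T, y, exponent=1.26, sign="growth")
        assert fit.tc == pytest.approx(320.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(2.0, rel=1e-7)

    def test_noiseless_width_recovery(self):
        T = np.arange(240.0, 301.0, 10.0)
        L = 4 * 0.5 * (1 - T / 320.0) ** (-0.63)
        fit = fit_power_law(T, L / 4.0, exponent=0.63, sign="decay")
        assert fit.tc == pytest.approx(320.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(0.5, rel=1e-7)

    def test_scale_equivariance(self):
        T = np.arange(240.0, 301.0, 10.0)
        y = 2.0 * (1 - T / 320.0) ** 1.26
        f1 = fit_power_law(T, y)
        f2 = fit_power_law(T, 7.5 * y)
        assert f2.tc == pytest.approx(f1.tc, rel=1e-9)
        assert f2.amplitude == pytest.approx(7.5 * f1.amplitude, rel=1e-7)

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            fit_power_law(np.array([250.0, 260.0]), np.array([1.0, 0.5]))

    def test_tc_recovery_monte_carlo(self):
        """5% noise per pseudo-repeat: Tc bias < 1 K and nominal-CI
        coverage >= 90% across replicates."""
        tcs, errs = [], []
        for seed in range(300):
            table, truth = gen_powerlaw_gamma(tc=320.0, gamma0=0.4,
                                              noise=0.05, seed=seed)
            fit = fit_power_law(table["T"].to_numpy(),
                                table["gamma"].to_numpy(),
                                sigma=table["sigma"].to_numpy())
            lo, hi = fit.tc_ci(0.95)
            tcs.append(fit.tc)
            errs.append(lo <= 320.0 <= hi)
        tcs = np.asarray(tcs)
        assert abs(tcs.mean() - 320.0) < 1.0
        coverage = np.mean(errs)
        assert coverage >= 0.90


class TestCollapse:
    def test_exact_power_law_collapses_fully(self):
        series, fits = {}, {}
        for ell, tc, g0 in ((2, 300.0, 0.3), (6, 340.0, 0.5)):
            T = np.linspace(0.7 * tc, 0.97 * tc, 8)
            y = g0 * (1 - T / tc) ** UNIVERSAL.mu
            series[ell] = pd.DataFrame({"T": T, "gamma": y})
            fits[ell] = fit_power_law(T, y)
        table, tau_star, pooled = collapse_and_extent(series, fits)
        assert pooled == pytest.approx(0.3, abs=1e-9)
        assert all(v == pytest.approx(0.3, abs=1e-9) for v in tau_star.values())
        # universality by construction: scaled curves agree where tau matches
        assert np.allclose(table["deviation"], 0.0, atol=1e-9)

    def test_crossover_locates_regime_edge(self):
        """An imposed 30% break above tau = 0.25 puts tau* in [0.2, 0.3]."""
        table, truth = gen_powerlaw_gamma(
            tc=320.0, gamma0=0.4, noise=0.0,
            t_grid=np.arange(208.0, 312.0, 6.0),
            crossover_tau=0.25, deviation=0.30, seed=0)
        # fit only the points below the crossover, as the filter would
        low = table[(1 - table["T"] / 320.0) < 0.2]
        fit = fit_power_law(low["T"].to_numpy(), low["gamma"].to_numpy())
        _, _, pooled = collapse_and_extent(
            {"x": table.rename(columns={})}, {"x": fit}, rel_tol=0.10)
        assert 0.2 <= pooled <= 0.3


class TestDiagnostics:
    def test_free_exponent_fit_recovers_generator(self):
        T = np.arange(240.0, 301.0, 10.0)
        y = 2.0 * (1 - T / 320.0) ** 1.26
        fit, e = fit_power_law_free(T, y)
        assert e == pytest.approx(1.26, abs=1e-5)
        assert fit.tc == pytest.approx(320.0, abs=1e-3)

    def test_tau_star_sensitivity_monotone(self):
        """tau* can only grow as the tolerance loosens."""
        table, _ = gen_powerlaw_gamma(
            tc=320.0, gamma0=0.4, noise=0.0,
            t_grid=np.arange(208.0, 312.0, 6.0),
            crossover_tau=0.25, deviation=0.30, seed=0)
        low = table[(1 - table["T"] / 320.0) < 0.2]
        fit = fit_power_law(low["T"].to_numpy(), low["gamma"].to_numpy())
        sweep = tau_star_sensitivity({"x": table}, {"x": fit},
                                     tolerances=(0.05, 0.10, 0.20, 0.50))
        ts = sweep["tau_star"].to_numpy()
        assert np.all(np.diff(ts) >= -1e-12)
        assert ts[-1] >= 0.3  # 50% tolerance swallows the imposed 30% break


class TestUniversalRatioPredictor:
    def test_coefficient_value(self):
        # 16 * R- = 1.6384, printed as 1.64
        assert round(16 * UNIVERSAL.r_minus, 2) == 1.64

    def test_wide_interface_nanonewton_scale(self):
        """Tc = 300 K and L = 100 nm give gamma ~ 6.8e-7 N/m."""
        pred = gamma_from_universal_ratio(300.0, 299.999999, 100.0)
        g_ref = 16 * UNIVERSAL.r_minus * KB_SI * 300.0 / (100e-9) ** 2
        # at T -> Tc the curve value at T_ref equals the closed form
        assert g_ref == pytest.approx(6.786e-7, rel=1e-3)
        grid = np.array([299.999999])
        pred = gamma_from_universal_ratio(300.0, 299.999999, 100.0,
                                          t_grid=grid)
        assert pred["curve"]["gamma_si"].iloc[0] == pytest.approx(g_ref,
                                                                  rel=1e-6)

    def test_gamma_vanishes_at_tc(self):
        pred = gamma_from_universal_ratio(300.0, 260.0, 12.0,
                                          t_grid=np.array([260.0, 300.0]))
        assert pred["curve"]["gamma_si"].iloc[-1] == 0.0

    def test_reference_point_identity(self):
        """gamma(T_ref) = 16 R- kB Tc / L_ref^2 independent of tau_ref
        (holds exactly because mu = 2 nu)."""
        for t_ref in (220.0, 260.0, 290.0):
            pred = gamma_from_universal_ratio(300.0, t_ref, 12.0,
                                              t_grid=np.array([t_ref]))
            expected = 16 * UNIVERSAL.r_minus * KB_SI * 300.0 / (12e-9) ** 2
            assert pred["curve"]["gamma_si"].iloc[0] == pytest.approx(
                expected, rel=1e-12)

    def test_rejects_supercritical_reference(self):
        with pytest.raises(ValueError):
            gamma_from_universal_ratio(300.0, 300.0, 12.0)

    def test_pipeline_closure(self):
        """Fitting the predictor's own output returns its inputs."""
        tc = 315.0
        pred = gamma_from_universal_ratio(tc, 260.0, 10.0,
                                          t_grid=np.linspace(220, 305, 12))
        curve = pred["curve"]
        fit = fit_power_law(curve["T_K"].to_numpy(),
                            curve["gamma_si"].to_numpy())
        assert fit.tc == pytest.approx(tc, rel=1e-6)
        assert fit.amplitude == pytest.approx(pred["gamma0_si"], rel=1e-6)


class TestValidatePrediction:
    def _direct(self, factor=1.0, noise=0.0, seed=0):
        tc = 320.0
        pred = gamma_from_universal_ratio(tc, 260.0, 10.0,
                                          t_grid=np.linspace(230, 300, 8))
        curve = pred["curve"]
        rng = np.random.default_rng(seed)
        g = factor * curve["gamma_sim"].to_numpy()
        g_obs = g * (1 + noise * rng.standard_normal(len(g)))
        sigma = np.maximum(noise * g, 1e-12)
        direct = pd.DataFrame({"T": curve["T_K"], "gamma": g_obs,
                               "sigma": sigma})
        return direct, curve

    def test_identical_data_consistent(self):
        direct, curve = self._direct()
        report, summary = validate_prediction(direct, curve)
        assert np.allclose(report["ratio"], 1.0)
        assert summary["consistent"]

    def test_generated_from_relation_consistent(self):
        direct, curve = self._direct(noise=0.03, seed=4)
        _, summary = validate_prediction(direct, curve)
        assert summary["consistent"]

    def test_inflated_amplitude_flagged(self):
        direct, curve = self._direct(factor=3.0, noise=0.03, seed=5)
        _, summary = validate_prediction(direct, curve)
        assert not summary["consistent"]


class TestFitWithFilter:
    def test_iterative_filter_converges(self):
        """Near-critical points (large implied xi) are excluded and the fit
        stabilizes on the remainder."""
        tc, g0 = 320.0, 0.4
        T = np.arange(230.0, 318.0, 8.0)
        y = g0 * (1 - T / tc) ** UNIVERSAL.mu
        fit, keep = fit_with_filter(T, y, None, lx=250.0)
        assert keep.sum() >= 3
        assert fit.tc == pytest.approx(tc, rel=1e-3)
        # points dropped (if any) are the hottest ones
        if (~keep).any():
            assert T[~keep].min() > T[keep].max() - 1e-9
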