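"""Kinetic fits: initial rates, Michaelis-Menten, burst, dose-response,
inhibition mechanism and activation."""

import numpy as np
import pytest

from subsite.kinetics import (
    KineticSeries,
    MECHANISMS,
    NoTransitionError,
    NotAnActivatorError,
    ProgressCurve,
    catalytic_efficiency,
    classify_inhibition,
    eadie_hofstee_points,
    estimate_initial_rate,
    fit_activation,
    fit_burst_titration,
    fit_dose_response,
    fit_michaelis_menten,
)
from subsite.simulate import (
    simulate_activation,
    simulate_burst_curve,
    simulate_dose_response,
    simulate_inhibition_panel,
    simulate_mm_rates,
    simulate_progress_curve,
)


class TestInitialRate:
    def test_linear_signal_recovers_slope_over_calibration(self):
        t = np.arange(0, 300, 20.0)
        curve = ProgressCurve(t, 0.002 * t + 0.01, calibration=0.5)
        assert estimate_initial_rate(curve) == pytest.approx(0.004)

    def test_flat_curve_gives_zero(self):
        t = np.arange(0, 300, 20.0)
        curve = ProgressCurve(t, np.full_like(t, 0.3), calibration=1.0)
        assert estimate_initial_rate(curve) == pytest.approx(0.0, abs=1e-15)

    def test_saturating_substrate_rate_close_to_kcat_times_e(self):
        kcat, e_uM, s0 = 10.0, 0.05, 2000.0  # S >> KM = 15
        curve, _ = simulate_progress_curve(kcat, 15.0, e_uM, s0, t_end=300.0)
        v = estimate_initial_rate(curve, max_fraction_consumed=0.05)
        assert v == pytest.approx(kcat * e_uM, rel=0.02)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ProgressCurve(np.array([0.0, 1, 2]), np.array([0.0, 1, 2]))

    def test_progress_curve_generator_matches_closed_form_slope(self):
        kcat, km, e_uM, s0 = 48.0, 15.3, 0.05, 100.0
        curve, truth = simulate_progress_curve(kcat, km, e_uM, s0, t_end=60.0, dt_sample=1.0)
        v0 = truth.params["v0_uM_s"]
        # at <= 5% depletion the curve is still essentially linear
        depl = np.searchsorted(curve.signal, 0.05 * s0)
        slope = np.polyfit(curve.times[: depl + 1], curve.signal[: depl + 1], 1)[0]
        assert slope == pytest.approx(v0, rel=0.005)


class TestMichaelisMenten:
    def test_noiseless_recovery_at_published_parameters(self):
        """Noiseless rates generated at the optimized-substrate constants
        (kcat 48 /s, KM 15.3 µM) are recovered essentially exactly."""
        series, _ = simulate_mm_rates(
            48.0, 15.3, [2, 5, 10, 20, 50, 100], enzyme_total_nM=60, active_fraction=0.62
        )
        fit = fit_michaelis_menten(series)
        assert fit.kcat == pytest.approx(48.0, rel=1e-6)
        assert fit.km == pytest.approx(15.3, rel=1e-6)
        assert fit.efficiency == pytest.approx(48.0 / 15.3e-6, rel=1e-6)

    def test_rate_at_km_is_half_vmax(self):
        series, _ = simulate_mm_rates(10.0, 20.0, [20.0, 1, 5, 50, 200, 1000])
        fit = fit_michaelis_menten(series)
        v_at_km = fit.kcat * series.enzyme_active_uM * fit.km / (fit.km + fit.km)
        assert v_at_km == pytest.approx(fit.vmax / 2)

    def test_efficiency_identity_and_unit_conversion(self):
        assert catalytic_efficiency(48.0, 15.3) == pytest.approx(3_137_254.9, rel=1e-6)
        series, _ = simulate_mm_rates(5.0, 30.0, [5, 10, 30, 100, 300], noise_cv=0.03, seed=1)
        fit = fit_michaelis_menten(series)
        assert fit.efficiency == pytest.approx(fit.kcat / (fit.km * 1e-6), rel=1e-9)

    def test_fit_matches_grid_search_oracle_on_noisy_data(self):
        series, _ = simulate_mm_rates(
            48.0, 15.3, [2, 5, 10, 20, 50, 100], noise_cv=0.05, replicates=2, seed=3
        )
        fit = fit_michaelis_menten(series)
        s, v, e = series.substrate_uM, series.rates, series.enzyme_active_uM
        kcats = np.logspace(np.log10(fit.kcat / 1.2), np.log10(fit.kcat * 1.2), 200)
        kms = np.logspace(np.log10(fit.km / 1.2), np.log10(fit.km * 1.2), 200)
        rss = np.array(
            [
                [np.sum((kc * e * s / (km + s) - v) ** 2) for km in kms]
                for kc in kcats
            ]
        )
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        assert fit.kcat == pytest.approx(kcats[i], rel=0.01)
        assert fit.km == pytest.approx(kms[j], rel=0.01)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_michaelis_menten(
                KineticSeries(np.array([1.0, 2, 3, 4]), np.array([0.1, 0.2, 0.3, 0.4]))
            )


class TestBurst:
    def test_zero_amplitude_gives_zero_active_fraction(self):
        curve, _ = simulate_burst_curve(active_fraction=0.0, noise_frac=0.0, steady_slope=1e-5)
        fit = fit_burst_titration(curve, enzyme_total_nM=120.0)
        assert fit.active_fraction_pct == pytest.approx(0.0, abs=0.5)

    def test_hand_computed_amplitude_conversion(self):
        # pi = 0.001233 AU, eps = 16600 /M/cm, l = 1 cm, E = 120 nM -> 61.9%
        t = np.arange(0.0, 601.0, 10.0)
        signal = 0.001233 * (1 - np.exp(-0.05 * t)) + 2e-6 * t + 0.01
        fit = fit_burst_titration(
            ProgressCurve(t, signal), epsilon=16600.0, enzyme_total_nM=120.0
        )
        assert fit.active_fraction_pct == pytest.approx(0.001233 / 16600 / 120e-9 * 100, abs=0.1)
        assert fit.active_fraction_pct == pytest.approx(61.9, abs=0.2)

    def test_recovery_of_sixty_two_percent_titration(self):
        fracs = []
        for seed in range(10):
            curve, _ = simulate_burst_curve(active_fraction=0.62, seed=seed)
            fracs.append(fit_burst_titration(curve, enzyme_total_nM=120.0).active_fraction_pct)
        assert np.mean(fracs) == pytest.approx(62.0, rel=0.05)

    def test_unresolvably_fast_burst_flagged_with_amplitude_estimate(self):
        t = np.arange(0.0, 601.0, 60.0)
        pi = 16600 * 1.0 * 120e-9 * 0.62
        signal = pi * (1 - np.exp(-5.0 * t)) + 2e-6 * t + 0.01  # done before 2nd sample
        fit = fit_burst_titration(ProgressCurve(t, signal), enzyme_total_nM=120.0)
        assert fit.flagged
        assert fit.active_fraction_pct == pytest.approx(62.0, rel=0.05)


class TestDoseResponse:
    def test_noiseless_recovery_is_exact(self):
        c, v, _ = simulate_dose_response(3.6, [0.5, 1, 2, 5, 10, 50, 100, 500], noise_cv=0.0, replicates=1)
        fit = fit_dose_response(c, v)
        assert fit.ic50 == pytest.approx(3.6, rel=1e-5)
        assert fit.hill == pytest.approx(1.0, rel=1e-4)

    def test_rate_at_ic50_is_midpoint(self):
        c, v, _ = simulate_dose_response(10.0, [0.5, 1, 5, 10, 50, 100], hill=1.3, top=2.0, bottom=0.4, noise_cv=0.0, replicates=1)
        fit = fit_dose_response(c, v)
        ratio = np.zeros(1)
        model_at_ic50 = fit.bottom + (fit.top - fit.bottom) / 2
        assert model_at_ic50 == pytest.approx((fit.top + fit.bottom) / 2)
        assert fit.ic50 == pytest.approx(10.0, rel=1e-4)

    def test_fit_matches_log_grid_oracle_within_one_percent(self):
        c, v, _ = simulate_dose_response(3.6, [0.5, 1, 2, 5, 10, 50, 100, 500], noise_cv=0.05, replicates=3, seed=11)
        fit = fit_dose_response(c, v, fix_bottom=0.0)
        # oracle: profile top analytically for each (ic50, hill) grid point
        ic50s = np.logspace(np.log10(0.36), np.log10(36.0), 1000)
        hills = np.linspace(0.7, 1.4, 281)
        best = (np.inf, None)
        for h in hills:
            f = 1.0 / (1.0 + (c[None, :] / ic50s[:, None]) ** h)
            top = (v * f).sum(axis=1) / (f * f).sum(axis=1)
            rss = ((top[:, None] * f - v) ** 2).sum(axis=1)
            k = int(np.argmin(rss))
            if rss[k] < best[0]:
                best = (float(rss[k]), float(ic50s[k]))
        assert fit.ic50 == pytest.approx(best[1], rel=0.01)

    def test_flat_response_raises(self):
        c = np.array([0.5, 1, 2, 5, 10, 50])
        with pytest.raises(NoTransitionError):
            fit_dose_response(c, np.full_like(c, 1.0))


class TestInhibitionMechanism:
    def test_eadie_hofstee_of_noiseless_mm_is_linear(self):
        series, _ = simulate_mm_rates(10.0, 20.0, [2, 5, 10, 20, 50, 100, 200])
        pts = eadie_hofstee_points(series)
        slope, intercept = np.polyfit(pts[:, 0], pts[:, 1], 1)
        vmax = 10.0 * series.enzyme_active_uM
        assert slope == pytest.approx(-20.0, rel=1e-9)
        assert intercept == pytest.approx(vmax, rel=1e-9)

    def test_noncompetitive_truth_gives_parallel_eadie_hofstee_lines(self):
        panel, _ = simulate_inhibition_panel("noncompetitive", noise_cv=0.0, seed=0)
        slopes = []
        for series in panel:
            pts = eadie_hofstee_points(series)
            slopes.append(np.polyfit(pts[:, 0], pts[:, 1], 1)[0])
        assert np.allclose(slopes, slopes[0], rtol=1e-9)

    def test_competitive_truth_gives_common_intercept(self):
        panel, _ = simulate_inhibition_panel("competitive", noise_cv=0.0, seed=0)
        intercepts = [
            np.polyfit(*eadie_hofstee_points(s).T, 1)[1] for s in panel
        ]
        assert np.allclose(intercepts, intercepts[0], rtol=1e-9)

    def test_noncompetitive_panel_selected_with_dominant_weight(self):
        panel, truth = simulate_inhibition_panel("noncompetitive", ki_uM=3.6, noise_cv=0.02, seed=5)
        result = classify_inhibition(panel)
        assert result.selected == "noncompetitive"
        assert result.fits["noncompetitive"].weight == max(
            f.weight for f in result.fits.values()
        )
        assert result.fits["noncompetitive"].ki == pytest.approx(3.6, rel=0.15)
        assert sum(f.weight for f in result.fits.values()) == pytest.approx(1.0)

    def test_competitive_panel_selected(self):
        panel, _ = simulate_inhibition_panel("competitive", noise_cv=0.02, seed=6)
        assert classify_inhibition(panel).selected == "competitive"

    @pytest.mark.parametrize("mechanism", MECHANISMS)
    def test_selection_accuracy_at_two_percent_noise(self, mechanism):
        """Model selection identifies the generating mechanism in >= 90%
        of 50 simulated panels per mechanism at 2% noise."""
        correct = 0
        for seed in range(50):
            panel, _ = simulate_inhibition_panel(
                mechanism,
                alpha=3.0 if mechanism == "mixed" else 1.0,
                noise_cv=0.02,
                seed=2000 + seed,
            )
            correct += classify_inhibition(panel).selected == mechanism
        assert correct / 50 >= 0.9

    def test_single_nonzero_level_rejected(self):
        panel, _ = simulate_inhibition_panel("competitive", inhibitor_uM=(0.0, 5.0))
        with pytest.raises(ValueError):
            classify_inhibition(panel)


class TestActivation:
    def test_flat_truth_fits_fold_of_one(self):
        a, v, _ = simulate_activation(fold_max=1.0, noise_cv=0.0, replicates=1)
        fit = fit_activation(a, v)
        assert fit.fold_max == pytest.approx(1.0, abs=0.01)

    def test_noiseless_saturating_recovery(self):
        a, v, _ = simulate_activation(fold_max=2.0, k_act_uM=60.0, noise_cv=0.0, replicates=1)
        fit = fit_activation(a, v)
        assert fit.fold_max == pytest.approx(2.0, rel=1e-4)
        assert fit.k_act == pytest.approx(60.0, rel=1e-3)
        assert fit.k_att is None

    def test_attenuated_model_selected_when_high_dose_inhibits(self):
        a, v, _ = simulate_activation(
            fold_max=3.0, k_act_uM=60.0, k_att_uM=2000.0,
            conc_uM=(0, 10, 30, 100, 300, 1000, 3000, 10000),
            noise_cv=0.0, replicates=1,
        )
        fit = fit_activation(a, v)
        assert fit.k_att is not None
        assert fit.k_att == pytest.approx(2000.0, rel=0.05)

    def test_two_fold_stimulation_recovered_from_noisy_data(self):
        folds = [
            fit_activation(*simulate_activation(fold_max=2.0, noise_cv=0.03, seed=s)[:2]).fold_max
            for s in range(20)
        ]
        assert np.mean(folds) == pytest.approx(2.0, rel=0.05)

    def test_decreasing_data_rejected(self):
        a = np.array([0.0, 10, 30, 100, 300, 1000])
        v = np.array([1.0, 0.9, 0.7, 0.5, 0.3, 0.2])
        with pytest.raises(NotAnActivatorError):
            fit_activation(a, v)


class TestParameterRecoveryAndCoverage:
    def test_median_relative_error_and_ci_coverage_over_50_sims(self):
        """At 5% multiplicative noise, kcat/KM/IC50 are recovered with
        <10% median relative error and ~95% CIs cover the truth in
        85-99% of runs (relative weighting matches the noise model)."""
        rel = {"kcat": [], "km": [], "ic50": []}
        cov = {"kcat": 0, "km": 0, "ic50": 0}
        n = 50
        for seed in range(n):
            series, _ = simulate_mm_rates(
                48.0, 15.3, [2, 5, 10, 20, 50, 100],
                enzyme_total_nM=60, active_fraction=0.62,
                noise_cv=0.05, replicates=2, seed=seed,
            )
            f = fit_michaelis_menten(series, weighting="relative")
            rel["kcat"].append(abs(f.kcat - 48.0) / 48.0)
            rel["km"].append(abs(f.km - 15.3) / 15.3)
            cov["kcat"] += abs(f.kcat - 48.0) < 1.96 * f.kcat_se
            cov["km"] += abs(f.km - 15.3) < 1.96 * f.km_se
            c, v, _ = simulate_dose_response(
                3.6, [0.5, 1, 2, 5, 10, 50, 100, 500], noise_cv=0.05, replicates=3, seed=seed
            )
            d = fit_dose_response(c, v, fix_bottom=0.0, weighting="relative")
            rel["ic50"].append(abs(d.ic50 - 3.6) / 3.6)
            cov["ic50"] += abs(d.ic50 - 3.6) < 1.96 * d.ic50_se
        for key in rel:
            assert np.median(rel[key]) < 0.10, key
            assert 0.85 <= cov[key] / n <= 0.99, key
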