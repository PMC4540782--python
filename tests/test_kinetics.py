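import numpy as np
import pytest

from auronekit import (
    AllostericModel,
    EXTINCTION_TABLE,
    ExtinctionEntry,
    InitialRateSet,
    KineticsWarning,
    ProgressCurve,
    absorbance_to_concentration,
    concentration_to_absorbance,
    estimate_critical_concentration,
    fit_michaelis_menten,
    fit_pseudo_first_order,
    fit_suicide,
    lag_time,
    simulate_latent_activation,
    simulate_suicide,
    synth_initial_rates,
    synth_progress_curves,
)


class TestBeerLambert:
    def test_butein_hand_division(self):
        assert absorbance_to_concentration(
            0.0932, EXTINCTION_TABLE["butein"]) == pytest.approx(10.0)

    def test_fisetin_threshold_absorbance(self):
        """120 mAU at the fisetin wavelength is ~23 µM product."""
        conc = absorbance_to_concentration(0.120, EXTINCTION_TABLE["fisetin"])
        assert conc == pytest.approx(22.45, abs=0.01)
        assert round(conc) == 22 or abs(conc - 23) < 1.0

    def test_zero_absorbance(self):
        assert absorbance_to_concentration(0.0, EXTINCTION_TABLE["butein"]) == 0.0

    def test_linear_and_invertible(self):
        entry = EXTINCTION_TABLE["catechol"]
        x = np.array([0.0, 0.05, 0.1, 0.4])
        back = concentration_to_absorbance(
            absorbance_to_concentration(x, entry), entry)
        assert np.allclose(back, x)

    def test_invalid_extinction_rejected(self):
        with pytest.raises(ValueError):
            ExtinctionEntry("bad", 400, -5.0)


class TestMichaelisMenten:
    @pytest.mark.parametrize("Km,Vmax", [(52.0, 489.0), (10.0, 3.0),
                                         (500.0, 2256.0)])
    def test_noiseless_exact_recovery(self, Km, Vmax):
        S = np.array([0.2, 0.5, 1.0, 2.0, 5.0]) * Km
        data = synth_initial_rates(Km, Vmax, S, cv=0.0, n_rep=1, seed=0)
        fit = fit_michaelis_menten(data)
        assert fit.converged
        assert fit.Km == pytest.approx(Km, rel=1e-6)
        assert fit.Vmax == pytest.approx(Vmax, rel=1e-6)

    def test_half_saturation_identity(self):
        data = synth_initial_rates(52.0, 489.0, [52.0], cv=0.0, seed=0)
        assert data.rate[0] == pytest.approx(489.0 / 2)

    def test_butein_parameter_recovery_with_noise(self):
        """3 % noise, 4 replicates over 10-75 µM recovers Km ~ 52 µM."""
        data = synth_initial_rates(52.0, 489.0, [10, 15, 20, 30, 40, 50, 60, 75],
                                   cv=0.03, n_rep=4, seed=2016)
        fit = fit_michaelis_menten(data)
        assert fit.converged
        combined_se = np.hypot(fit.Km_se, 3.0)
        assert abs(fit.Km - 52.0) < 3 * combined_se

    def test_unsaturated_data_flagged(self):
        """Km far beyond the substrate range is reported but not trusted."""
        data = synth_initial_rates(5000.0, 1255.0, [10, 20, 40, 75],
                                   cv=0.0, seed=0)
        with pytest.warns(KineticsWarning):
            fit = fit_michaelis_menten(data)
        assert not fit.converged

    def test_too_few_concentrations_rejected(self):
        data = InitialRateSet(np.array([1.0, 2.0, 3.0]), np.array([1, 2, 3.0]))
        with pytest.raises(ValueError):
            fit_michaelis_menten(data)

    def test_kcat_conversion_with_molarity(self):
        data = synth_initial_rates(52.0, 6.0, [10, 25, 52, 100, 200],
                                   cv=0.0, seed=0)
        fit = fit_michaelis_menten(data, enzyme_molar_nM=1.0)
        # Vmax 6 µM/min at 1 nM enzyme -> kcat = 6/(1e-3 µM)/60 s
        assert fit.kcat == pytest.approx(100.0, rel=1e-6)
        assert fit.kcat_over_Km == pytest.approx(100.0 / 0.052, rel=1e-6)


class TestPseudoFirstOrder:
    def test_exact_linear_slope(self):
        S = np.array([1.0, 2.0, 4.0, 8.0])
        data = InitialRateSet(S, 0.37 * S)
        fit = fit_pseudo_first_order(data)
        assert fit.slope == pytest.approx(0.37, rel=1e-12)
        assert fit.slope_se == pytest.approx(0.0, abs=1e-12)

    def test_slope_approximates_vmax_over_km(self):
        """[S] <= 0.075 Km gives the efficiency within the S/Km bound."""
        Km, Vmax = 1000.0, 100.0
        data = synth_initial_rates(Km, Vmax, [10, 25, 50, 75], cv=0.0, seed=0)
        with pytest.warns(KineticsWarning, match="curvature"):
            fit = fit_pseudo_first_order(data)
        # saturation biases the slope low by at most max(S)/Km = 7.5 %
        assert Vmax / Km * (1 - 0.075) < fit.slope < Vmax / Km

    def test_efficiency_units(self):
        S = np.array([1.0, 2.0, 4.0])
        data = InitialRateSet(S, 0.06 * S)      # slope 0.06 min^-1
        fit = fit_pseudo_first_order(data, enzyme_molar_nM=1.0)
        # 0.06 min^-1 / 1e-3 µM / 60 -> 1.0 µM^-1 s^-1 -> 1000 mM^-1 s^-1
        assert fit.kcat_over_Km == pytest.approx(1000.0, rel=1e-9)

    def test_curvature_warning(self):
        data = synth_initial_rates(50.0, 100.0, [10, 20, 40, 60, 75],
                                   cv=0.0, n_rep=2, seed=0)
        with pytest.warns(KineticsWarning, match="curvature"):
            fit_pseudo_first_order(data)

    def test_negative_rates_rejected(self):
        data = InitialRateSet(np.array([1.0, 2.0]), np.array([0.1, -0.2]))
        with pytest.raises(ValueError):
            fit_pseudo_first_order(data)


class TestSuicide:
    t = np.linspace(0.0, 50.0, 120)

    def test_linearity_in_enzyme(self):
        c1 = simulate_suicide(0.6, 5000.0, 0.12, self.t)
        c2 = simulate_suicide(1.2, 5000.0, 0.12, self.t)
        assert np.allclose(c2.signal, 2 * c1.signal)

    def test_plateau_ratios_follow_enzyme_ladder(self):
        """E0 = 1.2/0.6/0.3/0.15 nM gives plateaus in ratio 8:4:2:1."""
        plateaus = [simulate_suicide(E0, 5000.0, 0.2, self.t).signal[-1]
                    for E0 in (1.2, 0.6, 0.3, 0.15)]
        ratios = np.array(plateaus) / plateaus[-1]
        assert np.allclose(ratios, [8, 4, 2, 1], rtol=1e-9)

    def test_fast_kobs_instant_plateau(self):
        c = simulate_suicide(1.0, 100.0, 1e6, np.linspace(0.01, 10, 20))
        assert np.allclose(c.signal, 100.0 * 1.0e-3)

    def test_noiseless_fit_exact(self):
        c = simulate_suicide(1.2, 5000.0, 0.12, self.t)
        fit = fit_suicide(c)
        assert fit.P_inf == pytest.approx(6.0, rel=1e-6)
        assert fit.k_obs == pytest.approx(0.12, rel=1e-6)
        assert fit.r_partition == pytest.approx(5000.0, rel=1e-6)
        assert fit.warning is None

    def test_noisy_recovery_median_error(self):
        """2 % noise: median relative error of P_inf below 2 % over 50 reps."""
        rng = np.random.default_rng(99)
        errs = []
        for _ in range(50):
            c = simulate_suicide(1.2, 5000.0, 0.12, self.t)
            noisy = ProgressCurve(c.time,
                                  c.signal + rng.normal(0, 0.02 * 6.0,
                                                        len(c.time)),
                                  enzyme_conc=1.2)
            fit = fit_suicide(noisy)
            errs.append(abs(fit.P_inf - 6.0) / 6.0)
        assert np.median(errs) < 0.02

    def test_linear_curve_warns_no_plateau(self):
        t = np.linspace(0, 10, 30)
        curve = ProgressCurve(t, 0.5 * t, enzyme_conc=1.0)
        with pytest.warns(KineticsWarning, match="plateau"):
            fit = fit_suicide(curve)
        assert fit.warning is not None

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_suicide(-1.0, 10.0, 0.1, self.t)


MODEL = AllostericModel(c_star=23.0, a0=0.03, v_spec=2.0)


class TestLatentActivation:
    def test_steady_onset_at_cstar_for_every_enzyme_level(self):
        """The product level where the rate saturates equals c*."""
        for E0 in (7.2, 3.6, 1.8, 0.9):
            t = np.linspace(0, 80 / E0, 2000)
            c = simulate_latent_activation(E0, MODEL, True, t)
            s = np.gradient(c.signal, c.time)
            vE = MODEL.v_spec * E0
            onset = c.signal[np.argmax(s >= 0.999 * vE)]
            assert onset == pytest.approx(MODEL.c_star, rel=0.02)

    def test_lag_time_decreases_with_enzyme(self):
        lags = []
        for E0 in (0.9, 1.8, 3.6, 7.2):
            t = np.linspace(0, 120 / E0, 500)
            lags.append(lag_time(simulate_latent_activation(E0, MODEL, True, t)))
        assert all(a > b for a, b in zip(lags, lags[1:]))

    def test_non_activating_is_linear_basal(self):
        """A chalcone-type substrate stays at the basal rate."""
        t = np.linspace(0, 30, 100)
        c = simulate_latent_activation(3.6, MODEL, False, t)
        assert np.allclose(c.signal, MODEL.a0 * MODEL.v_spec * 3.6 * t)

    def test_fully_active_limit_is_straight_line(self):
        nearly_active = AllostericModel(23.0, 0.999, 2.0)
        t = np.linspace(0, 10, 100)
        c = simulate_latent_activation(2.0, nearly_active, True, t)
        assert np.allclose(c.signal, 2.0 * 2.0 * t, rtol=2e-3)

    def test_step_size_violation_rejected(self):
        with pytest.raises(ValueError, match="step"):
            simulate_latent_activation(7.2, MODEL, True,
                                       np.linspace(0, 10, 50), step=1.0)


class TestCriticalConcentration:
    def test_noiseless_family_recovers_cstar_within_2pct(self):
        curves = synth_progress_curves(
            "latent", dict(c_star=31.0, a0=0.05, v_spec=1.5),
            [6.0, 3.0, 1.5], noise_sd=0.0, seed=0)
        est = estimate_critical_concentration(curves)
        assert est.c_star == pytest.approx(31.0, rel=0.02)
        assert not est.inconsistent

    def test_fisetin_family_with_noise(self):
        """Published assay layout: c* = 23 µM, E0 ladder, 1 % noise."""
        curves = synth_progress_curves(
            "latent", dict(c_star=23.0, a0=0.03, v_spec=2.0),
            [7.2, 3.6, 1.8, 0.9], noise_sd=0.23, seed=5)
        est = estimate_critical_concentration(curves)
        assert est.c_star == pytest.approx(23.0, rel=0.10)

    def test_single_curve_rejected(self):
        curves = synth_progress_curves(
            "latent", dict(c_star=23.0, a0=0.03, v_spec=2.0), [3.6],
            noise_sd=0.0, seed=0)
        with pytest.raises(ValueError):
            estimate_critical_concentration(curves)

    def test_linear_curves_have_no_transition(self):
        t = np.linspace(0, 30, 200)
        curves = [ProgressCurve(t, 0.5 * E * t, enzyme_conc=E)
                  for E in (1.0, 2.0)]
        with pytest.warns(KineticsWarning):
            with pytest.raises(ValueError):
                estimate_critical_concentration(curves)


def test_progress_curve_csv_round_trip(tmp_path):
    c = simulate_suicide(1.2, 5000.0, 0.12, np.linspace(0, 20, 30),
                         substrate="sulfuretin", substrate_conc0=50.0)
    path = tmp_path / "curve.csv"
    c.write_csv(path)
    back = ProgressCurve.read_csv(path)
    assert back.enzyme_conc == 1.2
    assert back.substrate == "sulfuretin"
    assert np.allclose(back.time, c.time)
    assert np.allclose(back.signal, c.signal)
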