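import numpy as np
import pytest

from raftquant import (
    DegenerateDataError,
    SigmoidFit,
    ThermalGPSeries,
    boltzmann_gp,
    first_derivative_curve,
    fit_boltzmann_sigmoid,
    fit_lorentzian,
    get_preset,
    gp_thermal_series,
    synth_thermal_scan,
    transition_summary,
)
from raftquant.thermotropy import lorentzian

GRID = np.arange(27.0, 58.0, 5.0)


def make_sigmoid_fit(a1, a2, tm, dt, t_min=27.0, t_max=57.0):
    return SigmoidFit(gp_low_T=a1, gp_high_T=a2, tm_C=tm, slope_C=dt,
                      r_squared=1.0, covariance=np.zeros((4, 4)),
                      t_min_C=t_min, t_max_C=t_max)


class TestBoltzmannFit:
    def test_noiseless_parameters_recovered_to_machine_precision(self):
        gp = boltzmann_gp(GRID, 0.45, -0.15, 38.5, 3.0)
        fit = fit_boltzmann_sigmoid(ThermalGPSeries(GRID, gp))
        assert fit.gp_low_T == pytest.approx(0.45, abs=1e-6)
        assert fit.gp_high_T == pytest.approx(-0.15, abs=1e-6)
        assert fit.tm_C == pytest.approx(38.5, abs=1e-6)
        assert fit.slope_C == pytest.approx(3.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_boltzmann_sigmoid(ThermalGPSeries(GRID, np.full(GRID.size, 0.3)))

    def test_noisy_tm_within_replicate_uncertainty(self):
        rng = np.random.default_rng(42)
        gp = boltzmann_gp(GRID, 0.45, -0.15, 38.5, 3.0) \
            + rng.normal(0, 0.005, GRID.size)
        fit = fit_boltzmann_sigmoid(ThermalGPSeries(GRID, gp))
        assert fit.tm_C == pytest.approx(38.5, abs=0.3)

    @pytest.mark.parametrize("tm", [32.0, 38.5, 45.0])
    @pytest.mark.parametrize("dt", [1.5, 3.0, 6.0])
    def test_recovery_across_parameter_grid(self, tm, dt):
        gp = boltzmann_gp(GRID, 0.5, -0.1, tm, dt)
        fit = fit_boltzmann_sigmoid(ThermalGPSeries(GRID, gp))
        assert fit.tm_C == pytest.approx(tm, abs=1e-6)
        assert fit.slope_C == pytest.approx(dt, abs=1e-6)


class TestDerivativeCurve:
    def test_extremum_sits_at_tm(self):
        fit = make_sigmoid_fit(0.45, -0.15, 38.5, 3.0)
        t, dgp = first_derivative_curve(fit, grid_step_C=0.1)
        assert t[np.argmin(dgp)] == pytest.approx(38.5, abs=0.1)

    def test_falling_gp_gives_nonpositive_derivative(self):
        fit = make_sigmoid_fit(0.45, -0.15, 38.5, 3.0)
        _, dgp = first_derivative_curve(fit)
        assert np.all(dgp <= 0)

    def test_doubling_slope_halves_peak_height(self):
        # closed form: |peak| = |A1 - A2| / (4 dT)
        _, d1 = first_derivative_curve(make_sigmoid_fit(0.45, -0.15, 38.5, 2.0))
        _, d2 = first_derivative_curve(make_sigmoid_fit(0.45, -0.15, 38.5, 4.0))
        assert np.abs(d1).max() == pytest.approx(0.6 / 8.0, abs=1e-9)
        assert np.abs(d2).max() == pytest.approx(0.5 * np.abs(d1).max(),
                                                 abs=1e-9)


class TestLorentzianFit:
    def test_exact_lorentzian_samples_recovered(self):
        t = np.arange(27.0, 57.05, 0.1)
        y = lorentzian(t, 37.4, 17.4, -1.2, 0.01)
        fit = fit_lorentzian((t, y))
        assert fit.center_C == pytest.approx(37.4, abs=1e-6)
        assert fit.width_C == pytest.approx(17.4, abs=1e-6)
        assert fit.amplitude == pytest.approx(-1.2, abs=1e-6)
        assert fit.offset == pytest.approx(0.01, abs=1e-8)

    def test_symmetric_input_centers_on_symmetry_axis(self):
        t = np.arange(20.0, 55.05, 0.1)
        y = 1.0 / (1.0 + (t - 37.5) ** 2)
        assert fit_lorentzian((t, y)).center_C == pytest.approx(37.5, abs=1e-6)

    def test_logistic_derivative_center_and_width_mapping(self):
        # frozen pilot values: a logistic derivative with dT = 3 fitted over
        # 27-57 °C yields a Lorentzian centered at Tm (within 0.05 °C) with
        # FWHM 11.40 °C
        fit = make_sigmoid_fit(0.55, -0.08, 38.5, 3.0)
        lor = fit_lorentzian(first_derivative_curve(fit))
        assert lor.center_C == pytest.approx(38.5, abs=0.05)
        assert lor.width_C == pytest.approx(11.40, abs=0.05)
        assert lor.amplitude < 0  # GP falls with temperature

    def test_width_strictly_increasing_in_sigmoid_slope(self):
        widths = []
        for dt in [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0]:
            fit = make_sigmoid_fit(0.55, -0.08, 38.5, dt)
            widths.append(fit_lorentzian(first_derivative_curve(fit)).width_C)
        assert np.all(np.diff(widths) > 0)


class TestTransitionSummary:
    def test_noiseless_chain_tm_estimates_agree(self):
        series = gp_thermal_series(
            synth_thermal_scan(get_preset("SM_control"), noise_sd_gp=0.0))
        result = transition_summary(series)
        assert result.sigmoid.tm_C == pytest.approx(38.5, abs=1e-3)
        assert abs(result.sigmoid.tm_C - result.lorentzian.center_C) < 0.05

    def test_resv_dose_shifts_center_down_and_broadens(self):
        control = transition_summary(gp_thermal_series(
            synth_thermal_scan(get_preset("SM_control"), noise_sd_gp=0.0)))
        dosed = transition_summary(gp_thermal_series(
            synth_thermal_scan(get_preset("SM_resv500"), noise_sd_gp=0.0)))
        assert dosed.lorentzian.center_C < control.lorentzian.center_C
        assert dosed.lorentzian.width_C > control.lorentzian.width_C

    def test_temperature_order_invariance(self):
        gp = boltzmann_gp(GRID, 0.45, -0.15, 38.5, 3.0)
        fwd = transition_summary(ThermalGPSeries(GRID, gp))
        rev = transition_summary(ThermalGPSeries(GRID[::-1], gp[::-1]))
        assert rev.sigmoid.tm_C == pytest.approx(fwd.sigmoid.tm_C, abs=1e-9)
        assert rev.lorentzian.width_C == pytest.approx(fwd.lorentzian.width_C,
                                                       abs=1e-9)
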