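import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raftquant import (
    PDPC_CALIBRATION,
    POPC_CALIBRATION,
    CalibrationError,
    DegenerateDataError,
    QuenchingCalibration,
    UsageError,
    calibrate_ro,
    domain_radius,
    quenching_ratio,
    radius_uncertainty,
    relative_radius_change,
    synth_quenching_pair,
)

# published control rows: (Q, matrix calibration, radius)
CONTROL_ROWS = [
    (0.769, POPC_CALIBRATION, 24.3),
    (0.815, POPC_CALIBRATION, 30.9),
    (0.896, PDPC_CALIBRATION, 42.9),
    (0.898, PDPC_CALIBRATION, 43.1),
]


class TestQuenchingRatio:
    def test_no_quenching_gives_unity(self):
        assert quenching_ratio(1000.0, 1000.0).q == 1.0

    def test_published_popc_control_ratio(self):
        assert quenching_ratio(769.0, 1000.0).q == pytest.approx(0.769)

    def test_complete_quenching_gives_zero(self):
        assert quenching_ratio(0.0, 1000.0).q == 0.0

    def test_zero_reference_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            quenching_ratio(100.0, 0.0)


class TestDomainRadius:
    def test_baseline_q_maps_to_zero_radius(self):
        assert domain_radius(0.60, POPC_CALIBRATION).radius_A == 0.0

    def test_ceiling_q_maps_to_sensing_range(self):
        result = domain_radius(0.93, POPC_CALIBRATION)
        assert result.radius_A == pytest.approx(47.5)
        assert not result.clamped

    @pytest.mark.parametrize("q, cal, expected", CONTROL_ROWS)
    def test_published_control_radii(self, q, cal, expected):
        assert domain_radius(q, cal).radius_A == pytest.approx(expected,
                                                               abs=0.2)

    def test_out_of_range_q_is_clamped_and_flagged(self):
        result = domain_radius(0.95, POPC_CALIBRATION)
        assert result.clamped
        assert result.radius_A == pytest.approx(47.5)
        low = domain_radius(0.55, POPC_CALIBRATION)
        assert low.clamped and low.radius_A == 0.0

    def test_collapsed_baselines_are_a_calibration_error(self):
        with pytest.raises(CalibrationError):
            QuenchingCalibration(q_ld=0.6, q_lo=0.6)

    @given(q1=st.floats(0.601, 0.929), q2=st.floats(0.601, 0.929))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_ruler_is_strictly_increasing_in_q(self, q1, q2):
        r1 = domain_radius(q1, POPC_CALIBRATION).radius_A
        r2 = domain_radius(q2, POPC_CALIBRATION).radius_A
        if q1 < q2:
            assert r1 < r2
        elif q1 > q2:
            assert r1 > r2


class TestRoCalibration:
    def test_single_pair_hand_inversion(self):
        # 24.3 / ((0.769 - 0.60)/0.33) = 47.45
        cal = calibrate_ro([(0.769, 24.3)], (0.60, 0.93))
        assert cal.ro_A == pytest.approx(47.45, abs=0.01)

    def test_four_published_controls_agree_on_ro(self):
        controls = [(q, r) for q, _, r in CONTROL_ROWS]
        baselines = [(c.q_ld, c.q_lo) for _, c, _ in CONTROL_ROWS]
        cal = calibrate_ro(controls, baselines)
        assert cal.ro_A == pytest.approx(47.5, abs=0.1)
        assert cal.max_residual_A <= 0.1

    def test_calibrated_ruler_reproduces_its_controls(self):
        controls = [(q, r) for q, _, r in CONTROL_ROWS]
        baselines = [(c.q_ld, c.q_lo) for _, c, _ in CONTROL_ROWS]
        cal = calibrate_ro(controls, baselines)
        for (q, base, r) in CONTROL_ROWS:
            ruler = QuenchingCalibration(q_ld=base.q_ld, q_lo=base.q_lo,
                                         ro_A=cal.ro_A)
            assert domain_radius(q, ruler).radius_A == pytest.approx(
                r, abs=cal.max_residual_A + 1e-9)

    def test_q_on_baseline_is_a_usage_error(self):
        with pytest.raises(UsageError):
            calibrate_ro([(0.60, 10.0)], (0.60, 0.93))

    def test_empty_controls_are_a_usage_error(self):
        with pytest.raises(UsageError):
            calibrate_ro([], (0.60, 0.93))


class TestRelativeChangeAndUncertainty:
    def test_equal_radii_give_zero_percent(self):
        assert relative_radius_change(24.3, 24.3) == 0.0

    def test_published_popc_dose_response(self):
        assert relative_radius_change(34.4, 24.3) == pytest.approx(41.6,
                                                                   abs=0.1)

    def test_published_pdpc_dose_response(self):
        assert relative_radius_change(40.7, 42.9) == pytest.approx(-5.1,
                                                                   abs=0.1)

    def test_zero_baseline_radius_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            relative_radius_change(20.0, 0.0)

    def test_uncertainty_propagation(self):
        assert radius_uncertainty(0.0, POPC_CALIBRATION) == 0.0
        sd = radius_uncertainty(0.01, POPC_CALIBRATION)
        assert sd == pytest.approx(47.5 * 0.01 / 0.33, abs=1e-9)
        assert radius_uncertainty(0.02, POPC_CALIBRATION) == pytest.approx(
            2 * sd, abs=1e-12)

    def test_replicate_scatter_consistent_with_propagation(self):
        # Monte-Carlo: replicate radius SD within a factor 2 of first-order
        # propagation at 1% multiplicative quenching noise
        rng = np.random.default_rng(2024)
        radii = []
        for _ in range(200):
            f, f0 = synth_quenching_pair(24.3, POPC_CALIBRATION,
                                         noise_sd_fraction=0.01, rng=rng)
            radii.append(domain_radius(quenching_ratio(f, f0),
                                       POPC_CALIBRATION).radius_A)
        empirical = np.std(radii, ddof=1)
        q_true = 0.60 + (24.3 / 47.5) * 0.33
        propagated = radius_uncertainty(0.01 * q_true, POPC_CALIBRATION)
        assert propagated / 2 < empirical < propagated * 2


class TestRoundTrip:
    @pytest.mark.parametrize("radius", [0.0, 10.0, 24.3, 42.9, 47.5])
    def test_noiseless_synthesis_recovers_radius_exactly(self, radius):
        f, f0 = synth_quenching_pair(radius, POPC_CALIBRATION)
        measured = quenching_ratio(f, f0)
        assert domain_radius(measured, POPC_CALIBRATION).radius_A == \
            pytest.approx(radius, abs=1e-9)
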