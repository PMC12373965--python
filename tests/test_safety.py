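"""Light-safety budget: reference doses, limits, margins and invariants."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from transocular.safety import (
    BeamAtPlane,
    Plane,
    PulseSchedule,
    SpectralWeighting,
    WrongPlaneError,
    alternative_mode,
    assess_mode,
    corneal_exposure_limit,
    corneal_irradiance_time_avg,
    corneal_radiant_exposure,
    effective_area,
    retinal_exposure_limit_pulsed,
    retinal_irradiance_limit_cw,
    retinal_irradiance_time_avg,
    retinal_radiant_exposure,
    standard_mode,
)

RET = BeamAtPlane(Plane.RETINA, power=100.0, spot_diameter=1.7)
COR = BeamAtPlane(Plane.CORNEA, irradiance=5.0)
STD = PulseSchedule(0.01, 0.09)
ALT = PulseSchedule(1.0, 19.0)
ONE_SECOND = PulseSchedule(1.0, 0.0, assessment_time=1.0)


class TestEffectiveArea:
    """The budget's square-of-diameter area convention."""

    @pytest.mark.parametrize("d, expected", [(1.7, 0.0289), (10.0, 1.0), (1.5, 0.0225)])
    def test_square_convention(self, d, expected):
        assert effective_area(d) == pytest.approx(expected, rel=1e-12)

    def test_circular_variant(self):
        assert effective_area(2.0, circular=True) == pytest.approx(math.pi * 0.01)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            effective_area(0.0)


class TestRetinalChecks:
    def test_time_averaged_weighted_irradiance(self):
        assert retinal_irradiance_time_avg(RET, STD) == pytest.approx(220, abs=3)

    def test_alternative_mode_unweighted_irradiance(self):
        assert retinal_irradiance_time_avg(RET, ALT, weighted=False) == pytest.approx(
            170, abs=4
        )

    def test_zero_power_gives_zero(self):
        beam = BeamAtPlane(Plane.RETINA, power=0.0, spot_diameter=1.7)
        assert retinal_irradiance_time_avg(beam, STD) == 0.0

    def test_radiant_exposure_20s(self):
        assert retinal_radiant_exposure(RET, STD, t=20) == pytest.approx(4.4, abs=0.05)

    def test_radiant_exposure_single_second(self):
        assert retinal_radiant_exposure(RET, ONE_SECOND, t=1) == pytest.approx(2.2, abs=0.03)

    def test_child_spot_exposure(self):
        child = BeamAtPlane(Plane.RETINA, power=100.0, spot_diameter=1.5)
        assert retinal_radiant_exposure(child, ONE_SECOND, t=1) == pytest.approx(2.8, abs=0.03)

    def test_wrong_plane_rejected(self):
        with pytest.raises(WrongPlaneError):
            retinal_irradiance_time_avg(COR, STD)


class TestRetinalLimits:
    @pytest.mark.parametrize(
        "d, t, n, expected",
        [(1.7, 20, 200, 14.7), (1.7, 1, 1, 5.8), (1.5, 1, 1, 6.6)],
    )
    def test_pulsed_limits(self, d, t, n, expected):
        assert retinal_exposure_limit_pulsed(d, t, n) == pytest.approx(expected, abs=0.15)

    @pytest.mark.parametrize("d, expected", [(1.7, 700), (1.2, 1000), (2.4, 500)])
    def test_cw_irradiance_limits(self, d, expected):
        assert retinal_irradiance_limit_cw(d) == pytest.approx(expected, abs=7)

    def test_limit_monotonic_in_pulses_and_time(self):
        for n in (1, 10, 100):
            assert retinal_exposure_limit_pulsed(1.7, 20, n) > retinal_exposure_limit_pulsed(
                1.7, 20, n * 2
            )
        for t in (1, 5, 15):
            assert retinal_exposure_limit_pulsed(1.7, t, 10) < retinal_exposure_limit_pulsed(
                1.7, t * 1.5, 10
            )

    def test_invalid_pulse_count(self):
        with pytest.raises(ValueError):
            retinal_exposure_limit_pulsed(1.7, 20, 0)


class TestCornealChecks:
    def test_time_averaged_irradiance(self):
        assert corneal_irradiance_time_avg(COR, STD) == pytest.approx(50.0)
        assert corneal_irradiance_time_avg(COR, ALT) == pytest.approx(25.0)

    def test_continuous_duty_conversion(self):
        cw = PulseSchedule(1.0, 0.0, assessment_time=1.0)
        assert corneal_irradiance_time_avg(COR, cw) == pytest.approx(500.0)

    def test_exposure_and_limits(self):
        assert corneal_radiant_exposure(COR, 20, 0.1) == pytest.approx(1.0)
        assert corneal_exposure_limit(20) == pytest.approx(3.8, abs=0.05)
        assert corneal_radiant_exposure(COR, 1, 1.0) == pytest.approx(0.5)
        assert corneal_exposure_limit(1) == pytest.approx(1.8)

    def test_exposure_vanishes_at_short_time(self):
        assert corneal_radiant_exposure(COR, 1e-9, 0.1) == pytest.approx(0.0, abs=1e-9)

    def test_wrong_plane_rejected(self):
        with pytest.raises(WrongPlaneError):
            corneal_irradiance_time_avg(RET, STD)


class TestAssessMode:
    def test_standard_mode_compliant(self):
        assert assess_mode(standard_mode()).all_pass

    def test_alternative_mode_compliant(self):
        assert assess_mode(alternative_mode()).all_pass

    def test_child_margin(self):
        """Child geometry, 1 s exposure: ~2.4x below the pulsed retinal limit."""
        a = assess_mode(alternative_mode(spot_diameter=1.5))
        assert a.check("retinal_exposure_short").margin == pytest.approx(2.4, abs=0.1)

    def test_adult_margin(self):
        a = assess_mode(alternative_mode())
        assert a.check("retinal_exposure_short").margin == pytest.approx(2.6, abs=0.1)

    def test_sweep_never_violates(self):
        for mode in (standard_mode(), alternative_mode()):
            a = assess_mode(mode)
            assert a.check("retinal_exposure_sweep_worst").passed
            assert a.check("corneal_exposure_sweep_worst").passed

    @given(scale=st.floats(0.25, 4.0))
    @settings(max_examples=25, deadline=None)
    def test_margins_inverse_in_power(self, scale):
        """Doubling the power halves every margin."""
        base = assess_mode(standard_mode())
        mode = standard_mode()
        scaled_mode = type(mode)(
            name=mode.name,
            schedule=mode.schedule,
            retinal_beam=BeamAtPlane(Plane.RETINA, power=100.0 * scale, spot_diameter=1.7),
            corneal_beam=BeamAtPlane(Plane.CORNEA, irradiance=5.0 * scale),
            short_time_s=mode.short_time_s,
        )
        scaled = assess_mode(scaled_mode)
        for c0, c1 in zip(base.checks, scaled.checks):
            assert c1.margin * scale == pytest.approx(c0.margin, rel=1e-9)


def test_weighted_equals_unweighted_times_r():
    w = SpectralWeighting()
    weighted = retinal_irradiance_time_avg(RET, STD, w, weighted=True)
    unweighted = retinal_irradiance_time_avg(RET, STD, w, weighted=False)
    assert weighted == pytest.approx(unweighted * w.r_coefficient, rel=1e-12)


def test_duty_cycle_invariants():
    assert STD.duty == pytest.approx(0.1)
    assert STD.n_pulses(20) == 200
    with pytest.raises(ValueError):
        PulseSchedule(0.0, 0.1)
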