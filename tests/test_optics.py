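"""Closed-form optics: projection, scleral diffusion, NA chain, resolution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from transocular import optics
from transocular.optics import (
    DetectionConfig,
    EYE_PRESETS,
    EyeGeometry,
    IlluminationTrain,
    InvalidConfiguration,
    effective_na,
    illumination_na,
    project_source_to_sclera,
    resolution_chain,
    resolution_dof,
    scleral_broadening,
)


@pytest.mark.parametrize(
    "train, eye_fl, expected",
    [
        (IlluminationTrain(), 17.0, 1.7),
        (IlluminationTrain(objective_focal_length=10.0), 17.0, 3.06),
        (
            IlluminationTrain(relay_f1=50, relay_f2=50, aperture_diameter=0.2),
            25.0,
            0.2 * 25 / 18,
        ),
        (IlluminationTrain(relay_f1=8, relay_f2=50), 25.0, 1.8 * 50 / 8 * 25 / 18),
    ],
)
def test_spot_projection(train, eye_fl, expected):
    eye = EyeGeometry(eye_focal_length=eye_fl)
    assert project_source_to_sclera(train, eye) == pytest.approx(expected, rel=1e-12)


def test_spot_projection_reference_values():
    """The four prototype illumination configurations land on 1.7, 3, ~0.3 and ~15 mm."""
    adult = EyeGeometry()
    model = EYE_PRESETS["artificial_model"]
    assert round(project_source_to_sclera(IlluminationTrain(), adult), 1) == 1.7
    assert round(
        project_source_to_sclera(IlluminationTrain(objective_focal_length=10), adult), 1
    ) == pytest.approx(3.1)  # quoted to one significant figure as 3 mm
    assert project_source_to_sclera(
        IlluminationTrain(relay_f1=50, relay_f2=50, aperture_diameter=0.2), model
    ) == pytest.approx(0.3, abs=0.03)
    assert project_source_to_sclera(
        IlluminationTrain(relay_f1=8, relay_f2=50), model
    ) == pytest.approx(15, abs=0.7)


def test_invalid_focal_length_rejected():
    with pytest.raises(InvalidConfiguration):
        IlluminationTrain(relay_f1=-40)


class TestScleralBroadening:
    def test_reference_diffusion_values(self, adult_eye):
        assert scleral_broadening(1.7, adult_eye) == pytest.approx(2.4, abs=0.05)
        assert scleral_broadening(3.0, adult_eye) == pytest.approx(3.4, abs=0.05)

    def test_no_sclera_no_diffusion(self):
        thin = EyeGeometry(sclera_thickness=1e-12)
        assert scleral_broadening(2.0, thin) == pytest.approx(2.0, abs=1e-5)

    def test_negative_diameter_rejected(self, adult_eye):
        with pytest.raises(ValueError):
            scleral_broadening(-1.0, adult_eye)

    @given(
        d=st.floats(0, 20),
        d2=st.floats(0, 20),
        z=st.floats(0.1, 3),
        z2=st.floats(0.1, 3),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_broadening(self, d, d2, z, z2):
        """Diffusion only enlarges the spot, monotonically in both arguments."""
        eye = EyeGeometry(sclera_thickness=z)
        assert scleral_broadening(d, eye) >= d
        if d2 >= d:
            assert scleral_broadening(d2, eye) >= scleral_broadening(d, eye)
        if z2 >= z:
            eye2 = EyeGeometry(sclera_thickness=z2)
            assert scleral_broadening(d, eye2) >= scleral_broadening(d, eye)


class TestIlluminationNA:
    def test_reference_na_values(self, adult_eye):
        assert illumination_na(0.3, adult_eye) == pytest.approx(0.01, abs=0.002)
        assert illumination_na(15.0, adult_eye) == pytest.approx(0.43, abs=0.005)
        assert illumination_na(0.0, adult_eye) == 0.0

    @given(d=st.floats(0, 200))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_index(self, d):
        eye = EyeGeometry()
        assert 0 <= illumination_na(d, eye) < eye.n_cornea_lens

    def test_strictly_increasing(self, adult_eye):
        d = np.linspace(0, 30, 100)
        na = [illumination_na(x, adult_eye) for x in d]
        assert np.all(np.diff(na) > 0)


class TestEffectiveNA:
    def test_identity_when_equal(self, detection_03):
        assert effective_na(0.3, detection_03) == pytest.approx(0.3)

    def test_mean_of_apertures(self, detection_03):
        assert effective_na(0.0730, detection_03) == pytest.approx(0.18650, abs=1e-4)

    def test_clamps_at_detection_na(self, detection_03):
        """Illumination outside the acceptance cone is not collected."""
        assert effective_na(0.43, detection_03) == pytest.approx(0.3)


class TestResolutionDof:
    def test_clinical_03_chain(self, adult_eye, detection_03, clinical_train):
        rep = resolution_chain(clinical_train, adult_eye, detection_03)
        assert round(rep.lateral_resolution, 1) == 2.8
        assert round(rep.depth_of_field) == 34

    def test_high_resolution_04_chain(self, adult_eye):
        rep = resolution_chain(
            IlluminationTrain(objective_focal_length=10),
            adult_eye,
            DetectionConfig(na_detection=0.4),
        )
        assert rep.lateral_resolution == pytest.approx(2.0, abs=0.1)
        assert rep.depth_of_field == pytest.approx(19, abs=0.5)

    def test_rayleigh_value(self, adult_eye):
        det = DetectionConfig(na_detection=0.3)
        rep = resolution_dof(0.3, det, adult_eye)
        assert rep.lateral_resolution == pytest.approx(0.61 * 0.85 / 0.3, rel=1e-12)

    def test_nonpositive_na_rejected(self, adult_eye, detection_03):
        with pytest.raises(ValueError):
            resolution_dof(0.0, detection_03, adult_eye)

    @given(na=st.floats(0.05, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_unit_consistency(self, na):
        """dx·NA = 0.61·lambda and DOF·NA^2 = n·lambda exactly."""
        eye = EyeGeometry()
        det = DetectionConfig(na_detection=na)
        rep = resolution_dof(na, det, eye)
        assert rep.lateral_resolution * na == pytest.approx(0.61 * det.wavelength, rel=1e-12)
        assert rep.depth_of_field * na**2 == pytest.approx(
            eye.n_cornea_lens * det.wavelength, rel=1e-12
        )


def test_full_chain_matches_straight_line_oracle(rng):
    """100 random configurations agree with an inline recomputation to 1e-12."""
    for _ in range(100):
        eye = EyeGeometry(
            eye_length=rng.uniform(18, 28),
            eye_focal_length=rng.uniform(14, 26),
            n_cornea_lens=rng.uniform(1.3, 1.5),
            sclera_thickness=rng.uniform(0.5, 1.5),
            reduced_scattering=rng.uniform(10, 60),
        )
        train = IlluminationTrain(
            led_visible_size=rng.uniform(0.5, 3),
            relay_f1=rng.uniform(8, 60),
            relay_f2=rng.uniform(8, 60),
            objective_focal_length=rng.uniform(5, 30),
        )
        det = DetectionConfig(na_detection=rng.uniform(0.1, 0.6),
                              wavelength=rng.uniform(0.4, 1.0))
        rep = resolution_chain(train, eye, det)

        # independent straight-line recomputation of the model formulas
        spot = train.led_visible_size * train.relay_f2 / train.relay_f1 \
            * eye.eye_focal_length / train.objective_focal_length
        lstar = 10.0 / eye.reduced_scattering
        diff = 2 * math.sqrt((spot / 2) ** 2 + 2 * eye.sclera_thickness * lstar)
        na_i = eye.n_cornea_lens * math.sin(math.atan(diff / 2 / eye.eye_length))
        na_eff = (min(na_i, det.na_detection) + det.na_detection) / 2
        dx = 0.61 * det.wavelength / na_eff
        dof = eye.n_cornea_lens * det.wavelength / na_eff**2
        assert rep.na_effective == pytest.approx(na_eff, rel=1e-12)
        assert rep.lateral_resolution == pytest.approx(dx, rel=1e-12)
        assert rep.depth_of_field == pytest.approx(dof, rel=1e-12)


def test_etendue_bound_positive():
    assert optics.etendue_bound(1.8, 0.5, 0.1) > 1.8
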