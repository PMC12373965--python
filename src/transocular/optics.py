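"""Closed-form optics of scleral retroillumination.

In the transmission geometry the eye illuminates itself: a spot of light is
projected through the pupil onto the sclera, the sclera back-scatters it, and
the diffuse patch acts as a *secondary source* located one eye length behind
the anterior-segment structures being imaged.  The size of that patch plays
the role of a condenser aperture in a classical transmission microscope — a
small patch means low illumination NA, high spatial coherence and strong
interference contrast; a large patch washes the contrast out but sharpens the
effective resolution.

This module chains the three pieces of arithmetic that govern the trade-off:

1. geometric projection of the LED (or aperture) image onto the sclera
   through the relay pair, objective and the eye's own optics;
2. broadening of that spot by diffuse scattering inside the sclera,
   ``D = 2·sqrt(sigma0^2 + 2·z·l*)`` with ``l* = 1/mu_s'``;
3. the resulting illumination NA, effective NA, lateral resolution
   ``0.61·lambda/NA_eff`` and depth of field ``n·lambda/NA_eff^2``.

Lengths are millimetres throughout except wavelengths and the final
resolution report, which are micrometres (the units in which these numbers
are conventionally quoted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class InvalidConfiguration(ValueError):
    """Raised when an optical configuration violates its invariants."""


@dataclass(frozen=True)
class EyeGeometry:
    """Simplified single-surface eye model.

    Parameters
    ----------
    eye_length : float
        Axial length, mm.  The secondary source sits this far behind the
        anterior segment.
    eye_focal_length : float
        Effective focal length of the cornea + crystalline lens, mm
        (adult ≈ 17, young child ≈ 15, artificial model eye 25).
    n_cornea_lens : float
        Bulk refractive index of the cornea/lens media (≈ 1.4).
    sclera_thickness : float
        Scleral wall thickness traversed by the diffusing light, mm.
    reduced_scattering : float
        Reduced scattering coefficient mu_s' of the sclera, cm^-1.
    """

    eye_length: float = 23.0
    eye_focal_length: float = 17.0
    n_cornea_lens: float = 1.4
    sclera_thickness: float = 1.0
    reduced_scattering: float = 30.0

    def __post_init__(self) -> None:
        for name in (
            "eye_length",
            "eye_focal_length",
            "n_cornea_lens",
            "sclera_thickness",
            "reduced_scattering",
        ):
            if getattr(self, name) <= 0:
                raise InvalidConfiguration(f"{name} must be strictly positive")
        if self.n_cornea_lens < 1:
            raise InvalidConfiguration("n_cornea_lens must be >= 1")

    @property
    def transport_mean_free_path(self) -> float:
        """Transport mean free path l* = 1/mu_s', in mm."""
        return 10.0 / self.reduced_scattering


#: Preset eye geometries.  ``child`` shortens the focal length (≈15 mm focal
#: length and a proportionally shorter globe); ``artificial_model`` is the
#: bench model eye with a flatter cornea.
EYE_PRESETS: dict[str, EyeGeometry] = {
    "adult": EyeGeometry(),
    "child": EyeGeometry(eye_length=20.5, eye_focal_length=15.0),
    "artificial_model": EyeGeometry(eye_length=23.0, eye_focal_length=25.0),
}


@dataclass(frozen=True)
class IlluminationTrain:
    """LED, relay lens pair and objective feeding the eye.

    The visible LED size defaults to 1.8 mm (die magnified by its dome);
    ``aperture_diameter``, when set, is a physical stop in front of the LED
    that replaces the LED as the object being imaged onto the sclera.
    """

    led_visible_size: float = 1.8
    relay_f1: float = 40.0
    relay_f2: float = 40.0
    objective_focal_length: float = 18.0
    aperture_diameter: float | None = None

    def __post_init__(self) -> None:
        if self.relay_f1 <= 0 or self.relay_f2 <= 0 or self.objective_focal_length <= 0:
            raise InvalidConfiguration("focal lengths must be strictly positive")
        if self.led_visible_size <= 0:
            raise InvalidConfiguration("led_visible_size must be strictly positive")
        if self.aperture_diameter is not None and self.aperture_diameter <= 0:
            raise InvalidConfiguration("aperture_diameter must be positive when set")

    @property
    def source_size(self) -> float:
        """Effective object size imaged to the sclera, mm."""
        if self.aperture_diameter is not None:
            return self.aperture_diameter
        return self.led_visible_size


@dataclass(frozen=True)
class DetectionConfig:
    """Detection-side aperture and wavelength (µm)."""

    na_detection: float
    wavelength: float = 0.85

    def __post_init__(self) -> None:
        if not 0 < self.na_detection:
            raise InvalidConfiguration("na_detection must be positive")
        if self.wavelength <= 0:
            raise InvalidConfiguration("wavelength must be positive")


@dataclass(frozen=True)
class SecondarySource:
    """The diffuse scleral patch acting as the condenser of the eye."""

    incident_diameter: float
    diffused_diameter: float
    na_illumination: float

    def __post_init__(self) -> None:
        if self.diffused_diameter < self.incident_diameter:
            raise InvalidConfiguration("diffusion cannot shrink the spot")
        if self.na_illumination < 0:
            raise InvalidConfiguration("na_illumination must be >= 0")


@dataclass(frozen=True)
class ResolutionReport:
    """Effective NA with the lateral resolution and DOF it implies (µm)."""

    na_effective: float
    lateral_resolution: float
    depth_of_field: float
    wavelength: float = 0.85
    secondary_source: SecondarySource | None = field(default=None, compare=False)

    def rounded(self) -> "ResolutionReport":
        """Copy with display rounding (one decimal), raw values discarded."""
        return ResolutionReport(
            na_effective=round(self.na_effective, 3),
            lateral_resolution=round(self.lateral_resolution, 1),
            depth_of_field=round(self.depth_of_field, 1),
            wavelength=self.wavelength,
            secondary_source=self.secondary_source,
        )


def project_source_to_sclera(train: IlluminationTrain, eye: EyeGeometry) -> float:
    """Incident spot diameter on the sclera, mm.

    The relay pair magnifies by f2/f1 and the objective + eye demagnify by
    f_eye/f_obj, so the spot is ``source × (f2/f1) × (f_eye/f_obj)``.
    """
    return (
        train.source_size
        * (train.relay_f2 / train.relay_f1)
        * (eye.eye_focal_length / train.objective_focal_length)
    )


def scleral_broadening(incident_diameter: float, eye: EyeGeometry) -> float:
    """Diffused spot diameter after a double pass through the sclera, mm.

    Gaussian random-walk broadening: sigma_total^2 = sigma0^2 + 2·z·l*,
    returned as the diameter 2·sigma_total.
    """
    if incident_diameter < 0:
        raise ValueError("incident_diameter must be >= 0")
    sigma0 = incident_diameter / 2.0
    lstar = eye.transport_mean_free_path
    return 2.0 * math.sqrt(sigma0**2 + 2.0 * eye.sclera_thickness * lstar)


def illumination_na(source_diameter: float, eye: EyeGeometry) -> float:
    """NA of the secondary scleral source seen from the anterior segment.

    ``NA_i = n · sin(arctan(radius / eye length))`` — purely geometric; any
    clamping by the detection cone happens in :func:`effective_na`.
    """
    if source_diameter < 0:
        raise ValueError("source_diameter must be >= 0")
    return eye.n_cornea_lens * math.sin(
        math.atan((source_diameter / 2.0) / eye.eye_length)
    )


def effective_na(na_i: float, det: DetectionConfig) -> float:
    """Mean of illumination and detection NA, clamping NA_i at NA_d.

    Illumination outside the acceptance cone of the objective is never
    collected, so NA_i saturates at the detection NA before averaging.
    """
    if na_i < 0:
        raise ValueError("na_i must be >= 0")
    return (min(na_i, det.na_detection) + det.na_detection) / 2.0


def resolution_dof(
    na_eff: float,
    det: DetectionConfig,
    eye: EyeGeometry,
    secondary_source: SecondarySource | None = None,
) -> ResolutionReport:
    """Rayleigh lateral resolution and depth of field for ``na_eff``, in µm."""
    if na_eff <= 0:
        raise ValueError("na_eff must be > 0")
    dx = 0.61 * det.wavelength / na_eff
    dof = eye.n_cornea_lens * det.wavelength / na_eff**2
    return ResolutionReport(
        na_effective=na_eff,
        lateral_resolution=dx,
        depth_of_field=dof,
        wavelength=det.wavelength,
        secondary_source=secondary_source,
    )


def resolution_chain(
    train: IlluminationTrain, eye: EyeGeometry, det: DetectionConfig
) -> ResolutionReport:
    """Full chain: projection → scleral diffusion → NA_i → NA_eff → Δx, DOF."""
    incident = project_source_to_sclera(train, eye)
    diffused = scleral_broadening(incident, eye)
    na_i = illumination_na(diffused, eye)
    src = SecondarySource(
        incident_diameter=incident, diffused_diameter=diffused, na_illumination=na_i
    )
    na_eff = effective_na(na_i, det)
    return resolution_dof(na_eff, det, eye, secondary_source=src)


def etendue_bound(led_diameter_mm: float, led_half_angle_rad: float,
                  target_half_angle_rad: float) -> float:
    """Informative only: étendue-conserving lower bound on the spot diameter.

    For a Lambertian LED chip, conservation of A·Ω in 2D optics bounds the
    demagnified spot by d·sin(u)/sin(u'), the reason the prototype stops at a
    1:1 LED projection instead of demagnifying further.  Diagnostic; not used
    by any resolution calculation.
    """
    if min(led_diameter_mm, led_half_angle_rad, target_half_angle_rad) <= 0:
        raise ValueError("all arguments must be positive")
    return led_diameter_mm * math.sin(led_half_angle_rad) / math.sin(target_half_angle_rad)
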