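"""Analytic defocus-contrast model for extended incoherent sources.

A sub-resolution scatterer in a transmission microscope appears bright on one
side of focus and dark on the other: the diffracted wave picks up the Gouy
phase of the focused detection mode, so the interference term with the
transmitted wave changes sign through focus.  In the Gaussian-beam picture
the on-axis interference term of a scatterer defocused by z is

    m(z) = A · (z/z_R) / (1 + (z/z_R)^2),

the imaginary part of the complex defocus factor 1/(1 - i z/z_R): an
antisymmetric dark/bright profile whose extrema sit at z = ±z_R, i.e. are
separated by the depth of field (z_R = DOF/2), with a built-in Lorentzian
axial envelope.

An illumination angle theta tilts the whole dark/bright structure: at
defocus z the pattern is sheared laterally by z·tan(theta), so the on-axis
camera pixel sees the single-angle profile attenuated by the lateral beam
envelope evaluated at that shear.  Summing the tilted profiles over the
angular extent of the (spatially incoherent) secondary source reproduces the
condenser-aperture behaviour: a wider source lowers the peak-to-trough
contrast and shortens the axial range over which the scatterer is visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DefocusModelParams:
    """Parameters of the Gaussian-beam defocus model.

    ``z_rayleigh`` (µm) defaults to half the detection-limited depth of
    field, DOF/2 with NA_eff = NA_d/2 (the point-source limit of the
    effective aperture), i.e. z_R = 2·n·lambda/NA_d^2.
    """

    na_detection: float
    wavelength: float = 0.85  # µm
    amplitude: float = 1.0
    n_medium: float = 1.4
    z_rayleigh: float | None = None

    def __post_init__(self) -> None:
        if self.na_detection <= 0 or self.wavelength <= 0 or self.amplitude <= 0:
            raise ValueError("model parameters must be positive")
        if self.z_rayleigh is not None and self.z_rayleigh <= 0:
            raise ValueError("z_rayleigh must be positive")

    @property
    def z_r(self) -> float:
        if self.z_rayleigh is not None:
            return self.z_rayleigh
        na_eff = self.na_detection / 2.0
        return self.n_medium * self.wavelength / na_eff**2 / 2.0

    @property
    def dof(self) -> float:
        """Extrema separation of the point-source profile, µm."""
        return 2.0 * self.z_r

    @property
    def waist(self) -> float:
        """Lateral beam waist, µm (Rayleigh radius / 2 of the detection PSF)."""
        return 0.61 * self.wavelength / self.na_detection / 2.0

    def beam_radius(self, z: float | np.ndarray) -> float | np.ndarray:
        return self.waist * np.sqrt(1.0 + (np.asarray(z) / self.z_r) ** 2)


@dataclass(frozen=True)
class SourceDistribution:
    """Angular content of the secondary scleral source.

    A uniform disc of ``diameter`` mm seen from ``eye_length`` mm away in a
    medium of index ``n_medium``; discretized into ``n_samples`` tilt angles
    weighted by the disc chord (the exact 1D marginal of a uniform disc).
    """

    diameter: float  # mm
    eye_length: float = 23.0  # mm
    n_samples: int = 65
    n_medium: float = 1.4

    def __post_init__(self) -> None:
        if self.diameter < 0:
            raise ValueError("diameter must be >= 0")
        if self.n_samples < 1:
            raise ValueError("need at least one angular sample")

    def samples(self) -> tuple[np.ndarray, np.ndarray]:
        """(angles [rad], weights summing to 1)."""
        r = self.diameter / 2.0
        if r == 0 or self.n_samples == 1:
            return np.zeros(1), np.ones(1)
        x = np.linspace(-r, r, self.n_samples)
        w = np.sqrt(np.maximum(r**2 - x**2, 0.0))
        if w.sum() == 0:
            w = np.ones_like(x)
        theta = np.arctan(x / self.eye_length)
        return theta, w / w.sum()

    @property
    def na_illumination(self) -> float:
        return self.n_medium * math.sin(math.atan((self.diameter / 2) / self.eye_length))


@dataclass(frozen=True)
class AxialProfile:
    """On-axis intensity offset vs defocus."""

    z: np.ndarray  # µm
    intensity: np.ndarray
    background: float = 0.0

    def __post_init__(self) -> None:
        if len(self.z) != len(self.intensity):
            raise ValueError("z and intensity must have equal length")


def single_angle_profile(
    z: float | np.ndarray, theta: float, params: DefocusModelParams
) -> np.ndarray:
    """Interference modulation at the on-axis pixel for one tilt angle.

    Gouy-phase Lorentzian-derivative profile sheared by z·tan(theta) and
    attenuated by the Gaussian lateral envelope at that shear.
    """
    z = np.asarray(z, dtype=float)
    zr = params.z_r
    gouy = (z / zr) / (1.0 + (z / zr) ** 2)
    # lateral shear of the tilted pattern, µm (z in µm, tan(theta) dimensionless)
    shear = z * math.tan(theta)
    w = params.beam_radius(z)
    envelope = np.exp(-0.5 * (shear / w) ** 2)
    return params.amplitude * gouy * envelope


def incoherent_sum_profile(
    z: np.ndarray, source: SourceDistribution, params: DefocusModelParams
) -> AxialProfile:
    """Weighted sum of tilted single-angle profiles over the source disc."""
    z = np.asarray(z, dtype=float)
    theta, w = source.samples()
    total = np.zeros_like(z)
    for t, wi in zip(theta, w):
        total += wi * single_angle_profile(z, t, params)
    return AxialProfile(z=z, intensity=total)


def axial_contrast(profile: AxialProfile) -> float:
    """Peak-to-trough contrast: max - min of the axial profile."""
    if len(profile.intensity) == 0:
        raise ValueError("empty profile")
    return float(np.max(profile.intensity) - np.min(profile.intensity))


def axial_fwhm(profile: AxialProfile) -> float:
    """FWHM of |intensity - background| — the axial visibility range, µm."""
    dev = np.abs(profile.intensity - profile.background)
    half = dev.max() / 2.0
    above = dev >= half
    if not above.any():
        return 0.0
    idx = np.where(above)[0]
    return float(profile.z[idx[-1]] - profile.z[idx[0]])


def normalize_profiles(
    profiles: dict, reference_key
) -> dict:
    """Affine-map all profiles so the reference spans exactly [0, 1].

    Mirrors the bench normalization in which every axial stack is scaled by
    the min/max of the most contrasted (smallest-source) condition.
    """
    if reference_key not in profiles:
        raise KeyError(f"reference {reference_key!r} not among profiles")
    ref = profiles[reference_key]
    lo, hi = float(np.min(ref.intensity)), float(np.max(ref.intensity))
    if hi == lo:
        raise ValueError("degenerate reference profile (max == min)")
    out = {}
    for key, p in profiles.items():
        out[key] = AxialProfile(
            z=p.z,
            intensity=(p.intensity - lo) / (hi - lo),
            background=(p.background - lo) / (hi - lo),
        )
    return out


def contrast_sweep(
    diameters_mm,
    params: DefocusModelParams,
    eye_length: float = 23.0,
    z: np.ndarray | None = None,
    n_samples: int = 65,
) -> list[dict]:
    """Contrast and axial FWHM vs equivalent source diameter.

    Returns one row per diameter with keys ``diameter_mm``, ``contrast``,
    ``axial_fwhm_um``, mirroring the measured contrast-vs-spot-size curve.
    """
    if z is None:
        z = np.linspace(-6 * params.z_r, 6 * params.z_r, 601)
    rows = []
    for d in diameters_mm:
        src = SourceDistribution(diameter=d, eye_length=eye_length, n_samples=n_samples)
        prof = incoherent_sum_profile(z, src, params)
        rows.append(
            {
                "diameter_mm": float(d),
                "contrast": axial_contrast(prof),
                "axial_fwhm_um": axial_fwhm(prof),
            }
        )
    return rows
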