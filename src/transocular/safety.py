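"""Ocular light-safety budget for pulsed NIR retroillumination.

Implements the Group-1 style checks used to clear the instrument for human
imaging: time-averaged weighted retinal irradiance, pulsed retinal radiant
exposure against its spot-size/time/pulse-count limit, and corneal
irradiance/exposure against fixed limits.  Two conventions are deliberately
idiosyncratic and kept because the budget is defined with them:

* spot "area" enters as ``(diameter in cm)**2`` — NOT the circular area
  pi·(d/2)^2.  A circular-area variant exists behind a flag for comparison
  but the budget numbers are defined with the square convention.
* the corneal pulsed-exposure limit is modelled as ``1.8·t^(1/4) J/cm^2``,
  the unique power law through both tabulated anchor points (1.8 J/cm^2 at
  1 s, ≈3.8 J/cm^2 at 20 s).  It is a reconstruction of the standard's
  table, not a quotation from it.

The spectral weighting coefficient R defaults to 0.63 (thermal hazard
weighting near 800 nm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum


class WrongPlaneError(ValueError):
    """Beam specified at the wrong plane for the requested check."""


@dataclass(frozen=True)
class PulseSchedule:
    """On/off pulse train: ``pulse_duration`` s of light, ``off_interval`` s dark."""

    pulse_duration: float
    off_interval: float
    assessment_time: float = 20.0

    def __post_init__(self) -> None:
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be > 0")
        if self.off_interval < 0:
            raise ValueError("off_interval must be >= 0")
        if self.assessment_time < self.period:
            raise ValueError("assessment_time must cover at least one pulse period")

    @property
    def period(self) -> float:
        return self.pulse_duration + self.off_interval

    @property
    def duty(self) -> float:
        return self.pulse_duration / self.period

    def n_pulses(self, t: float | None = None) -> int:
        """Number of pulses inside an assessment window of ``t`` seconds."""
        t = self.assessment_time if t is None else t
        n = math.floor(t / self.period)
        if n < 1:
            raise ValueError("assessment window shorter than one pulse period")
        return n


class Plane(Enum):
    RETINA = "retina"
    CORNEA = "cornea"


@dataclass(frozen=True)
class BeamAtPlane:
    """Beam description at the retina (power + spot) or cornea (irradiance).

    ``power`` is the per-pulse incident power in mW spread over a retinal
    spot of ``spot_diameter`` mm; ``irradiance`` is the measured corneal
    irradiance in mW/mm^2.
    """

    plane: Plane
    power: float | None = None
    spot_diameter: float | None = None
    irradiance: float | None = None

    def __post_init__(self) -> None:
        if self.plane is Plane.RETINA:
            if self.power is None or self.spot_diameter is None:
                raise ValueError("retina beam needs power and spot_diameter")
            if self.power < 0 or self.spot_diameter <= 0:
                raise ValueError("retina beam magnitudes must be positive")
        else:
            if self.irradiance is None or self.irradiance < 0:
                raise ValueError("cornea beam needs a non-negative irradiance")


@dataclass(frozen=True)
class SpectralWeighting:
    """Spectral hazard weighting coefficient R(lambda)."""

    r_coefficient: float = 0.63

    def __post_init__(self) -> None:
        if not 0 < self.r_coefficient <= 1:
            raise ValueError("r_coefficient must be in (0, 1]")


@dataclass(frozen=True)
class SafetyCheck:
    """One computed quantity against its permissible limit."""

    name: str
    value: float
    limit: float
    units: str
    weighted: bool | None = None

    @property
    def margin(self) -> float:
        return math.inf if self.value == 0 else self.limit / self.value

    @property
    def passed(self) -> bool:
        return self.value <= self.limit


@dataclass
class SafetyAssessment:
    """Collection of checks for one illumination mode."""

    mode: str
    checks: list[SafetyCheck] = field(default_factory=list)

    @property
    def all_pass(self) -> bool:
        return all(c.passed for c in self.checks)

    def check(self, name: str) -> SafetyCheck:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)

    def as_rows(self) -> list[dict]:
        return [
            {
                "check": c.name,
                "value": c.value,
                "limit": c.limit,
                "units": c.units,
                "margin": c.margin,
                "pass": c.passed,
            }
            for c in self.checks
        ]


def effective_area(spot_diameter: float, circular: bool = False) -> float:
    """Spot area in cm^2 under the budget's square convention.

    ``(d_cm)^2`` by default; ``circular=True`` gives pi·(d/2)^2 for
    comparison only.
    """
    if spot_diameter <= 0:
        raise ValueError("spot_diameter must be > 0")
    d_cm = spot_diameter / 10.0
    return math.pi * (d_cm / 2.0) ** 2 if circular else d_cm**2


def retinal_irradiance_time_avg(
    beam: BeamAtPlane,
    sched: PulseSchedule,
    w: SpectralWeighting = SpectralWeighting(),
    weighted: bool = True,
    circular: bool = False,
) -> float:
    """Time-averaged retinal irradiance, mW/cm^2 (× R when ``weighted``)."""
    if beam.plane is not Plane.RETINA:
        raise WrongPlaneError("retinal check requires a retina-plane beam")
    value = beam.power * sched.duty / effective_area(beam.spot_diameter, circular)
    return value * w.r_coefficient if weighted else value


def retinal_radiant_exposure(
    beam: BeamAtPlane,
    sched: PulseSchedule,
    w: SpectralWeighting = SpectralWeighting(),
    t: float = 20.0,
    circular: bool = False,
) -> float:
    """Weighted retinal radiant exposure over ``t`` seconds, J/cm^2."""
    if beam.plane is not Plane.RETINA:
        raise WrongPlaneError("retinal check requires a retina-plane beam")
    if t <= 0:
        raise ValueError("t must be > 0")
    mj = (
        beam.power
        / effective_area(beam.spot_diameter, circular)
        * t
        * sched.duty
        * w.r_coefficient
    )
    return mj / 1000.0


def retinal_exposure_limit_pulsed(spot_diameter: float, t: float, n_pulses: int) -> float:
    """Permissible pulsed retinal exposure ``(10/d)·t^(3/4)·N^(-1/4)``, J/cm^2."""
    if spot_diameter <= 0:
        raise ValueError("spot_diameter must be > 0")
    if t <= 0:
        raise ValueError("t must be > 0")
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    return (10.0 / spot_diameter) * t**0.75 * n_pulses**-0.25


def retinal_irradiance_limit_cw(spot_diameter: float) -> float:
    """Permissible time-averaged retinal irradiance ``1.2/d W/cm^2``, in mW/cm^2."""
    if spot_diameter <= 0:
        raise ValueError("spot_diameter must be > 0")
    return 1.2 / spot_diameter * 1000.0


CORNEAL_IRRADIANCE_LIMIT = 100.0  # mW/cm^2, fixed


def corneal_irradiance_time_avg(beam: BeamAtPlane, sched: PulseSchedule) -> float:
    """Time-averaged corneal irradiance, mW/cm^2 (input is mW/mm^2)."""
    if beam.plane is not Plane.CORNEA:
        raise WrongPlaneError("corneal check requires a cornea-plane beam")
    return beam.irradiance * 100.0 * sched.duty


def corneal_radiant_exposure(beam: BeamAtPlane, t: float, duty: float) -> float:
    """Corneal radiant exposure over ``t`` seconds at the given duty, J/cm^2."""
    if beam.plane is not Plane.CORNEA:
        raise WrongPlaneError("corneal check requires a cornea-plane beam")
    if t <= 0:
        raise ValueError("t must be > 0")
    return beam.irradiance * 100.0 * t * duty / 1000.0


def corneal_exposure_limit(t: float) -> float:
    """Permissible corneal exposure, ``1.8·t^(1/4) J/cm^2`` (reconstructed law)."""
    if t <= 0:
        raise ValueError("t must be > 0")
    return 1.8 * t**0.25


@dataclass(frozen=True)
class IlluminationMode:
    """Complete description of one clinical illumination mode."""

    name: str
    schedule: PulseSchedule
    retinal_beam: BeamAtPlane
    corneal_beam: BeamAtPlane
    # window for the "short time scale" single-exposure check: the light-on
    # time of one pulse, treated as duty 1 with a single pulse
    short_time_s: float | None = None


def standard_mode(spot_diameter: float = 1.7) -> IlluminationMode:
    """10 ms pulses at 10% duty, 100 mW, 5 mW/mm^2 at the cornea."""
    return IlluminationMode(
        name="standard",
        schedule=PulseSchedule(pulse_duration=0.01, off_interval=0.09),
        retinal_beam=BeamAtPlane(Plane.RETINA, power=100.0, spot_diameter=spot_diameter),
        corneal_beam=BeamAtPlane(Plane.CORNEA, irradiance=5.0),
    )


def alternative_mode(spot_diameter: float = 1.7) -> IlluminationMode:
    """1 s exposure every 20 s; short-time check on the single 1 s pulse."""
    return IlluminationMode(
        name="alternative",
        schedule=PulseSchedule(pulse_duration=1.0, off_interval=19.0),
        retinal_beam=BeamAtPlane(Plane.RETINA, power=100.0, spot_diameter=spot_diameter),
        corneal_beam=BeamAtPlane(Plane.CORNEA, irradiance=5.0),
        short_time_s=1.0,
    )


MODE_PRESETS = {"standard": standard_mode, "alternative": alternative_mode}


def assess_mode(
    mode: IlluminationMode,
    w: SpectralWeighting = SpectralWeighting(),
    t_max: float = 20.0,
    sweep_points: int = 40,
) -> SafetyAssessment:
    """Evaluate the full budget for one mode, both planes, adult or child spot.

    Beyond the headline numbers at ``t_max``, the pulsed-exposure checks are
    swept over assessment windows t in (0, t_max] (one extra check per plane
    recording the worst margin over the sweep).
    """
    sched = mode.schedule
    ret, cor = mode.retinal_beam, mode.corneal_beam
    a = SafetyAssessment(mode=mode.name)

    a.checks.append(
        SafetyCheck(
            "retinal_irradiance_weighted",
            retinal_irradiance_time_avg(ret, sched, w, weighted=True),
            retinal_irradiance_limit_cw(ret.spot_diameter),
            "mW/cm^2",
            weighted=True,
        )
    )
    a.checks.append(
        SafetyCheck(
            "retinal_irradiance_unweighted",
            retinal_irradiance_time_avg(ret, sched, w, weighted=False),
            retinal_irradiance_limit_cw(ret.spot_diameter),
            "mW/cm^2",
            weighted=False,
        )
    )
    a.checks.append(
        SafetyCheck(
            "retinal_exposure_pulsed",
            retinal_radiant_exposure(ret, sched, w, t=t_max),
            retinal_exposure_limit_pulsed(ret.spot_diameter, t_max, sched.n_pulses(t_max)),
            "J/cm^2",
            weighted=True,
        )
    )
    a.checks.append(
        SafetyCheck(
            "corneal_irradiance",
            corneal_irradiance_time_avg(cor, sched),
            CORNEAL_IRRADIANCE_LIMIT,
            "mW/cm^2",
        )
    )
    a.checks.append(
        SafetyCheck(
            "corneal_exposure",
            corneal_radiant_exposure(cor, t_max, sched.duty),
            corneal_exposure_limit(t_max),
            "J/cm^2",
        )
    )

    if mode.short_time_s is not None:
        # single-exposure window: duty 1 within the pulse, one pulse
        ts = mode.short_time_s
        one = PulseSchedule(pulse_duration=ts, off_interval=0.0, assessment_time=ts)
        a.checks.append(
            SafetyCheck(
                "retinal_exposure_short",
                retinal_radiant_exposure(ret, one, w, t=ts),
                retinal_exposure_limit_pulsed(ret.spot_diameter, ts, 1),
                "J/cm^2",
                weighted=True,
            )
        )
        a.checks.append(
            SafetyCheck(
                "corneal_exposure_short",
                corneal_radiant_exposure(cor, ts, 1.0),
                corneal_exposure_limit(ts),
                "J/cm^2",
            )
        )

    # sweep every assessment window up to t_max: record the worst margin
    worst_ret = worst_cor = math.inf
    t_ret = t_cor = t_max
    for k in range(1, sweep_points + 1):
        t = t_max * k / sweep_points
        if t >= sched.period:
            v = retinal_radiant_exposure(ret, sched, w, t=t)
            lim = retinal_exposure_limit_pulsed(ret.spot_diameter, t, sched.n_pulses(t))
            if v > 0 and lim / v < worst_ret:
                worst_ret, t_ret = lim / v, t
        vc = corneal_radiant_exposure(cor, t, sched.duty)
        limc = corneal_exposure_limit(t)
        if vc > 0 and limc / vc < worst_cor:
            worst_cor, t_cor = limc / vc, t
    a.checks.append(
        SafetyCheck(
            "retinal_exposure_sweep_worst",
            retinal_radiant_exposure(ret, sched, w, t=t_ret),
            retinal_exposure_limit_pulsed(ret.spot_diameter, t_ret, sched.n_pulses(t_ret)),
            "J/cm^2",
            weighted=True,
        )
    )
    a.checks.append(
        SafetyCheck(
            "corneal_exposure_sweep_worst",
            corneal_radiant_exposure(cor, t_cor, sched.duty),
            corneal_exposure_limit(t_cor),
            "J/cm^2",
        )
    )
    return a
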