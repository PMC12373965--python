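"""Time-domain 2D scalar-wave simulation of 4F transmission imaging.

The bench geometry is reduced to its optical skeleton: a plane-wave source
passes through a random particle assembly (the diffuser that makes the
illumination quasi-incoherent), illuminates a wavelength-scale scatterer
near the front focal plane of lens 1, and is relayed by the two-lens 4F
system onto a camera line.  The simulation solves the scalar wave equation

    u_tt = c(x, y)^2 * (u_xx + u_yy),        c = c0 / n(x, y)

with an explicit leapfrog update on a uniform grid, absorbing sponge layers
at the domain edges, and a soft line source.  Units: the vacuum wavelength
is the length unit (lambda = 1) and the vacuum speed of light the velocity
unit, so one optical period is one time unit.

Quasi-incoherence is obtained by averaging camera intensity over
re-randomized diffuser assemblies; the diffuser's distance from the sample
sets the angular subtense of the diffuse light at the scatterer and thus the
equivalent source size, exactly as moving the assembly does on the bench.

Everything here is a qualitative physics testbed: the phenomena of interest
(defocus contrast and its sign inversion, transmitted/diffracted wave
separation in the back focal plane, contrast-vs-source-size trade-off) are
scale-invariant, so the domain is tens of wavelengths rather than a 23 mm
eye.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


class UnstableGrid(ValueError):
    """Grid/time-step combination violates the CFL stability criterion."""


@dataclass(frozen=True)
class Grid2D:
    """Uniform simulation grid in wavelength units.

    ``courant`` is the CFL number c0·dt/dx; the 2D limit for the 5-point
    leapfrog stencil is 1/sqrt(2).
    """

    extent_x: float = 90.0
    extent_y: float = 24.0
    spatial_step: float = 0.05
    courant: float = 0.5
    boundary_width: float = 3.0

    def __post_init__(self) -> None:
        if self.spatial_step <= 0 or self.extent_x <= 0 or self.extent_y <= 0:
            raise ValueError("grid dimensions must be positive")
        if not 0 < self.courant <= 1 / math.sqrt(2) + 1e-12:
            raise UnstableGrid(
                f"courant={self.courant} exceeds the 2D stability limit 1/sqrt(2)"
            )
        if self.boundary_cells < 10:
            raise ValueError("absorbing layer must be at least 10 cells wide")

    @property
    def nx(self) -> int:
        return int(round(self.extent_x / self.spatial_step))

    @property
    def ny(self) -> int:
        return int(round(self.extent_y / self.spatial_step))

    @property
    def dt(self) -> float:
        return self.courant * self.spatial_step

    @property
    def boundary_cells(self) -> int:
        return int(round(self.boundary_width / self.spatial_step))

    @property
    def steps_per_period(self) -> int:
        return max(int(round(1.0 / self.dt)), 1)

    def x_to_col(self, x: float) -> int:
        return int(round(x / self.spatial_step))

    def y_to_row(self, y: float) -> int:
        return int(round((y + self.extent_y / 2) / self.spatial_step))


class RefractiveMap:
    """Refractive-index field with geometric builders.

    Builders are deterministic: random structure (the diffuser) takes an
    explicit ``numpy.random.Generator``.
    """

    def __init__(self, grid: Grid2D, background: float = 1.0):
        if background < 1:
            raise ValueError("refractive index must be >= 1 everywhere")
        self.grid = grid
        self.n = np.full((grid.ny, grid.nx), float(background))
        # extra absorption (opaque stops, lens mounts); added to the sponge
        self.absorption = np.zeros((grid.ny, grid.nx))

    def add_aperture_stop(self, x: float, open_radius: float,
                          thickness: float = 3.0, strength: float = 0.35,
                          edge_width: float = 1.0) -> None:
        """Absorbing screen with a clear opening of ``open_radius``.

        The absorption ramps smoothly both along the axis (cos^2 bump of
        ``thickness``) and across the opening edge (``edge_width``), so the
        screen absorbs obliquely incident light without the impedance
        discontinuity of a hard absorber, which would reflect.
        """
        g = self.grid
        y = (np.arange(g.ny) * g.spatial_step) - g.extent_y / 2
        xs = np.arange(g.nx) * g.spatial_step
        gy = np.clip((np.abs(y) - open_radius) / edge_width, 0.0, 1.0)
        gy = np.sin(0.5 * math.pi * gy) ** 2
        u = np.clip((xs - x) / (thickness / 2), -1.0, 1.0)
        gx = np.cos(0.5 * math.pi * u) ** 2
        gx[np.abs(xs - x) > thickness / 2] = 0.0
        self.absorption = np.maximum(
            self.absorption, strength * gy[:, None] * gx[None, :]
        )

    def _disc(self, x: float, y: float, diameter: float, index: float) -> None:
        g = self.grid
        r = diameter / 2.0
        j0, i0 = x / g.spatial_step, (y + g.extent_y / 2) / g.spatial_step
        rr = max(r / g.spatial_step, 0.5)
        jlo, jhi = int(j0 - rr - 1), int(j0 + rr + 2)
        ilo, ihi = int(i0 - rr - 1), int(i0 + rr + 2)
        jlo, jhi = max(jlo, 0), min(jhi, g.nx)
        ilo, ihi = max(ilo, 0), min(ihi, g.ny)
        if jlo >= jhi or ilo >= ihi:
            return
        jj, ii = np.meshgrid(np.arange(jlo, jhi), np.arange(ilo, ihi))
        inside = (jj - j0) ** 2 + (ii - i0) ** 2 <= rr**2
        self.n[ilo:ihi, jlo:jhi][inside] = index

    def add_scatterer(self, x: float, y: float = 0.0, diameter: float = 1.0,
                      index: float = 2.5) -> None:
        """Wavelength-scale test scatterer of elevated index."""
        self._disc(x, y, diameter, index)

    def add_lens(self, x: float, focal_length: float, aperture_radius: float,
                 index: float = 1.5, style: str = "graded",
                 slab_halfwidth: float = 6.0) -> None:
        """Lens with the quadratic optical path of focal length ``f``.

        ``style="graded"`` (default) writes a smooth index slab
        n(x, y) = 1 + A(y)·cos^2(pi (x - x0) / (2 W)) whose integrated
        optical path matches the ideal quadratic lens profile.  The
        gradual index transition suppresses the Fresnel reflections and
        thick-glass aberrations of a literal lens while keeping the index
        near the glass value; its symmetry pins the principal planes to the
        slab centre so the 4F conjugate planes land where designed.

        ``style="glass"`` builds the literal biconvex n = 1.5 lens with a
        parabolic thickness profile T(y) = T0·(1 - (y/R)^2),
        T0 = R^2/(2f(n-1)).
        """
        g = self.grid
        if style == "glass":
            t0 = aperture_radius**2 / (2.0 * focal_length * (index - 1.0))
            y = (np.arange(g.ny) * g.spatial_step) - g.extent_y / 2
            half_t = 0.5 * t0 * np.maximum(1.0 - (y / aperture_radius) ** 2, 0.0)
            xs = np.arange(g.nx) * g.spatial_step
            inside = np.abs(xs[None, :] - x) <= half_t[:, None]
            self.n[inside] = index
            return
        if style != "graded":
            raise ValueError("style must be 'graded' or 'glass'")
        w = slab_halfwidth
        y = (np.arange(g.ny) * g.spatial_step) - g.extent_y / 2
        # optical path difference of an ideal lens, zero at the aperture edge
        opd = np.maximum(aperture_radius**2 - y**2, 0.0) / (2.0 * focal_length)
        amp = opd / w  # integral of cos^2 over [-w, w] is w
        xs = np.arange(g.nx) * g.spatial_step
        u = (xs[None, :] - x) / w
        profile = np.where(np.abs(u) <= 1.0, np.cos(0.5 * math.pi * u) ** 2, 0.0)
        self.n += amp[:, None] * profile

    def add_diffuser(
        self,
        x: float,
        rng: np.random.Generator,
        width: float = 10.0,
        thickness: float = 3.0,
        particle_density: float = 4.0,
        particle_diameter: float = 0.25,
        index: float = 1.5,
    ) -> None:
        """Random assembly of sub-wavelength particles (phase randomizer).

        ``width`` is the transverse extent (sets the effective source size
        together with the distance to the sample), ``particle_density`` is
        particles per lambda^2.
        """
        n_part = int(round(particle_density * width * thickness))
        xs = rng.uniform(x - thickness / 2, x + thickness / 2, n_part)
        ys = rng.uniform(-width / 2, width / 2, n_part)
        for px, py in zip(xs, ys):
            self._disc(px, py, particle_diameter, index)


def _sponge(grid: Grid2D, strength: float = 0.35) -> np.ndarray:
    """Damping coefficient sigma·dt, quadratic ramp inside the boundary."""
    ny, nx, w = grid.ny, grid.nx, grid.boundary_cells
    dx_edge = np.minimum(np.arange(nx), nx - 1 - np.arange(nx))
    dy_edge = np.minimum(np.arange(ny), ny - 1 - np.arange(ny))
    dist = np.minimum(dy_edge[:, None], dx_edge[None, :])
    ramp = np.clip((w - dist) / w, 0.0, 1.0)
    return strength * ramp**2


@njit(cache=True)
def _leapfrog(u0, u1, csq, damp, src_col, src2d, n_steps,
              accum_start, probe_cols, probe_acc, record_every, snapshots):
    ny, nx = u0.shape
    n_snap = 0
    for t in range(n_steps):
        for i in range(1, ny - 1):
            for j in range(1, nx - 1):
                lap = (
                    u1[i - 1, j] + u1[i + 1, j] + u1[i, j - 1] + u1[i, j + 1]
                    - 4.0 * u1[i, j]
                )
                u0[i, j] = (
                    2.0 * u1[i, j]
                    - (1.0 - damp[i, j]) * u0[i, j]
                    + csq[i, j] * lap
                ) / (1.0 + damp[i, j])
        for i in range(ny):
            u0[i, src_col] += src2d[t, i]
        tmp = u0
        u0 = u1
        u1 = tmp
        if t >= accum_start:
            for p in range(probe_cols.shape[0]):
                col = probe_cols[p]
                for i in range(ny):
                    probe_acc[p, i] += u1[i, col] * u1[i, col]
        if record_every > 0 and t % record_every == 0 and n_snap < snapshots.shape[0]:
            for i in range(ny):
                for j in range(nx):
                    snapshots[n_snap, i, j] = u1[i, j]
            n_snap += 1
    return n_snap


@dataclass
class PropagationResult:
    """Time-averaged probe intensities and optional field snapshots."""

    probe_intensity: dict  # name -> 1D array over y
    snapshots: np.ndarray | None = None
    grid: Grid2D | None = None


def propagate(
    refmap: RefractiveMap,
    n_periods: float,
    source_x: float,
    source_halfwidth: float | None = None,
    probes: dict | None = None,
    average_periods: float = 2.0,
    record_every: int = 0,
    max_snapshots: int = 0,
    ramp_periods: float = 3.0,
    phase_rng: np.random.Generator | None = None,
    coherence_periods: float = 4.0,
    phase_correlation: float = 1.5,
    source_envelope: np.ndarray | None = None,
) -> PropagationResult:
    """Run the leapfrog solver with a soft line source.

    ``probes`` maps names to x positions whose columns accumulate
    time-averaged intensity over the final ``average_periods`` optical
    periods.  A super-Gaussian transverse envelope of half-width
    ``source_halfwidth`` confines the beam.

    With ``phase_rng`` set, the source wavefront carries a transverse random
    phase screen (correlation length ``phase_correlation`` wavelengths) that
    decorrelates every ``coherence_periods`` optical periods — a
    quasi-monochromatic spatially incoherent source.  Time-averaging the
    camera intensity over many coherence times then averages over
    independent speckle realizations within a single run.
    """
    grid = refmap.grid
    dt = grid.dt
    n_steps = int(round(n_periods / dt))
    spp = grid.steps_per_period
    accum_start = max(n_steps - int(round(average_periods * spp)), 0)

    csq = (grid.courant / refmap.n) ** 2
    damp = _sponge(grid) + refmap.absorption

    y = (np.arange(grid.ny) * grid.spatial_step) - grid.extent_y / 2
    if source_envelope is not None:
        src_env = np.asarray(source_envelope, dtype=float)
        if src_env.shape != (grid.ny,):
            raise ValueError("source_envelope must have length grid.ny")
    else:
        hw = source_halfwidth if source_halfwidth is not None else (
            grid.extent_y / 2 - grid.boundary_width - 1.0
        )
        hw = max(hw, 2.0 * grid.spatial_step)
        src_env = np.exp(-((y / hw) ** 8))

    t = np.arange(n_steps) * dt
    ramp = np.clip(t / ramp_periods, 0.0, 1.0) ** 2
    carrier = 2.0 * math.pi * t
    if phase_rng is None:
        src2d = (np.sin(carrier) * ramp * 2.0 * dt)[:, None] * src_env[None, :]
    else:
        n_screens = int(math.ceil(n_periods / coherence_periods)) + 2
        sigma_cells = phase_correlation / grid.spatial_step
        screens = phase_rng.uniform(0, 2 * math.pi, (n_screens, grid.ny))
        # smooth across y by FFT Gaussian filtering, then rescale to a
        # strong (several-radian) phase excursion
        k = np.fft.rfftfreq(grid.ny)
        gauss = np.exp(-0.5 * (2 * math.pi * k * sigma_cells) ** 2)
        screens = np.fft.irfft(np.fft.rfft(screens, axis=1) * gauss[None, :],
                               n=grid.ny, axis=1)
        screens *= (2.0 * math.pi / max(screens.std(), 1e-12))
        # linear interpolation between screens over time
        pos = t / coherence_periods
        i0 = np.minimum(pos.astype(int), n_screens - 2)
        frac = pos - i0
        phase = (1 - frac)[:, None] * screens[i0] + frac[:, None] * screens[i0 + 1]
        src2d = np.sin(carrier[:, None] + phase) * (ramp * 2.0 * dt)[:, None] \
            * src_env[None, :]

    probes = probes or {}
    names = list(probes)
    probe_cols = np.array([grid.x_to_col(probes[k]) for k in names], dtype=np.int64)
    if len(names) == 0:
        probe_cols = np.zeros(0, dtype=np.int64)
    probe_acc = np.zeros((len(names), grid.ny))

    snaps = np.zeros(
        (max_snapshots, grid.ny, grid.nx) if record_every > 0 else (0, 1, 1)
    )
    u0 = np.zeros((grid.ny, grid.nx))
    u1 = np.zeros((grid.ny, grid.nx))
    n_snap = _leapfrog(
        u0, u1, csq, damp, grid.x_to_col(source_x), np.ascontiguousarray(src2d),
        n_steps, accum_start, probe_cols, probe_acc, record_every, snaps,
    )
    n_acc = max(n_steps - accum_start, 1)
    out = {k: probe_acc[i] / n_acc for i, k in enumerate(names)}
    return PropagationResult(
        probe_intensity=out,
        snapshots=snaps[:n_snap] if record_every > 0 else None,
        grid=grid,
    )


@dataclass(frozen=True)
class FourFSystem:
    """Layout of the simulated 4F bench in wavelength units.

    The sample plane sits one focal length before lens 1, the camera one
    focal length after lens 2; ``scatterer_offset`` defocuses the scatterer
    along the axis (+ toward the lens).  ``diffuser_distance`` (sample to
    assembly centre) controls the angular subtense of the quasi-incoherent
    illumination: the equivalent incoherent source is the illuminated
    diffuser band of ``diffuser_width``, so the half-angle at the scatterer
    is atan(width / 2 / distance).
    """

    focal_length: float = 14.0
    aperture_radius: float = 9.0
    scatterer_diameter: float = 1.0
    scatterer_index: float = 1.15
    scatterer_offset: float = 0.0
    include_scatterer: bool = True
    include_diffuser: bool = True
    diffuser_distance: float = 12.0
    diffuser_width: float = 10.0
    diffuser_thickness: float = 4.0
    particle_density: float = 5.0
    particle_diameter: float = 0.35
    spatial_step: float = 0.1
    margin: float = 5.0
    beam_halfwidth: float | None = None  # default: well inside the aperture
    focus_offset: float = 0.0  # calibrated camera-conjugate plane, lambda

    def __post_init__(self) -> None:
        if self.focal_length <= 0 or self.aperture_radius <= 0:
            raise ValueError("focal length and aperture must be positive")
        if self.include_diffuser and (
            self.diffuser_distance < self.diffuser_thickness / 2 + 2.0
        ):
            raise ValueError("diffuser assembly overlaps the sample plane")

    # --- axial layout -----------------------------------------------------
    @property
    def lens_slab_halfwidth(self) -> float:
        return 6.0

    @property
    def lens_radius(self) -> float:
        """Physical lens semi-aperture; oversized so the Fourier-plane stop,
        not the glass edge, truncates the light."""
        return self.aperture_radius + 3.0

    @property
    def slab_delta(self) -> float:
        """Axial focus correction per focal gap for the graded-index lens.

        The lens slab's elevated on-axis index shortens the *reduced*
        distance (integral of dx/n) of every focal gap it straddles; each
        gap is stretched by delta = W·(1 - 1/sqrt(1 + a)) with
        a = R^2/(2 f W) the on-axis index elevation, so that reduced
        distances — which set the paraxial conjugates — equal f.
        """
        w = self.lens_slab_halfwidth
        a = self.lens_radius**2 / (2.0 * self.focal_length * w)
        return w * (1.0 - 1.0 / math.sqrt(1.0 + a))

    @property
    def source_x(self) -> float:
        return self.margin

    @property
    def sample_x(self) -> float:
        extra = (
            self.diffuser_distance + self.diffuser_thickness
            if self.include_diffuser
            else 4.0
        )
        return self.margin + 2.0 + extra

    @property
    def lens1_x(self) -> float:
        return self.sample_x + self.focal_length + self.slab_delta

    @property
    def bfp_x(self) -> float:
        return self.lens1_x + self.focal_length + self.slab_delta

    @property
    def lens2_x(self) -> float:
        return self.bfp_x + self.focal_length + self.slab_delta

    @property
    def camera_x(self) -> float:
        return self.lens2_x + self.focal_length + self.slab_delta

    @property
    def equivalent_source_size(self) -> float:
        """Dimensionless source-size measure: width / distance (0 = point)."""
        if not self.include_diffuser:
            return 0.0
        return self.diffuser_width / self.diffuser_distance

    @property
    def dof_estimate(self) -> float:
        """Geometric DOF scale of the relay, lambda units: 1/NA^2 with the
        lens marginal-ray NA."""
        na = math.sin(math.atan(self.aperture_radius / self.focal_length))
        return 1.0 / na**2

    def grid(self) -> Grid2D:
        return Grid2D(
            extent_x=self.camera_x + self.margin + 3.0,
            extent_y=2 * (self.lens_radius + 4.0),
            spatial_step=self.spatial_step,
        )

    def build_map(self, rng: np.random.Generator | None = None) -> RefractiveMap:
        grid = self.grid()
        m = RefractiveMap(grid)
        if self.include_diffuser:
            if rng is None:
                raise ValueError("diffuser requires an rng for particle placement")
            m.add_diffuser(
                self.sample_x - self.diffuser_distance,
                rng,
                width=self.diffuser_width,
                thickness=self.diffuser_thickness,
                particle_density=self.particle_density,
                particle_diameter=self.particle_diameter,
            )
        if self.include_scatterer:
            m.add_scatterer(
                self.sample_x + self.scatterer_offset,
                0.0,
                diameter=self.scatterer_diameter,
                index=self.scatterer_index,
            )
        # oversized lenses; the system NA is set by a clean stop in the
        # Fourier plane, where angle maps to height (y = f·tan(theta))
        m.add_lens(self.lens1_x, self.focal_length, self.lens_radius)
        m.add_lens(self.lens2_x, self.focal_length, self.lens_radius)
        m.add_aperture_stop(self.bfp_x, self.aperture_radius)
        return m


@dataclass
class SimResult:
    """Realization-averaged camera and back-focal-plane line intensities."""

    camera_intensity: np.ndarray
    bfp_intensity: np.ndarray
    y: np.ndarray
    n_realizations: int
    system: FourFSystem


@dataclass
class AxialScan:
    """On-axis feature contrast versus scatterer defocus."""

    z: np.ndarray
    contrast: np.ndarray
    background: float = 0.0


def _run_once(system: FourFSystem, rng: np.random.Generator | None,
              probes: dict, average_periods: float = 2.0,
              phase_rng: np.random.Generator | None = None) -> dict:
    refmap = system.build_map(rng)
    grid = refmap.grid
    # transit plus settling, then the averaging window
    n_periods = grid.extent_x * 1.35 + average_periods
    hw = system.beam_halfwidth if system.beam_halfwidth is not None else 6.0
    res = propagate(
        refmap,
        n_periods=n_periods,
        source_x=system.source_x,
        source_halfwidth=hw,
        probes=probes,
        average_periods=average_periods,
        phase_rng=phase_rng,
    )
    return res.probe_intensity


def simulate_camera_image(
    system: FourFSystem, n_realizations: int = 4, seed: int = 0,
    average_periods: float = 40.0,
) -> SimResult:
    """Camera line image averaged over quasi-incoherent illumination.

    Each realization re-randomizes the diffuser assembly and drives the
    source with an independently evolving random phase screen; the camera
    intensity is additionally time-averaged over ``average_periods`` optical
    periods (about ten coherence times), so the effective number of
    independent speckle patterns is much larger than ``n_realizations``.
    Coherent systems (no diffuser) skip the phase screen and use a short
    average.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    grid = system.grid()
    cam = np.zeros(grid.ny)
    bfp = np.zeros(grid.ny)
    root = np.random.default_rng(seed)
    for _ in range(n_realizations):
        if system.include_diffuser:
            rng = np.random.default_rng(root.integers(0, 2**31))
            phase_rng = np.random.default_rng(root.integers(0, 2**31))
            avg = average_periods
        else:
            rng, phase_rng, avg = None, None, 2.0
        out = _run_once(
            system, rng, {"camera": system.camera_x, "bfp": system.bfp_x},
            average_periods=avg, phase_rng=phase_rng,
        )
        cam += out["camera"]
        bfp += out["bfp"]
    y = (np.arange(grid.ny) * grid.spatial_step) - grid.extent_y / 2
    return SimResult(cam / n_realizations, bfp / n_realizations, y,
                     n_realizations, system)


def camera_uniformity(result: SimResult, halfwidth: float = 3.0) -> float:
    """Relative std of the camera intensity over the central region."""
    sel = np.abs(result.y) <= halfwidth
    region = result.camera_intensity[sel]
    return float(region.std() / region.mean())


def feature_contrast(result: SimResult, reference: SimResult | None = None,
                     window: float = 0.75,
                     background_halfwidth: float = 3.5) -> float:
    """(I_feature - I_background)/I_background at the conjugate pixel.

    The scatterer sits on axis, so its conjugate is the central camera
    pixel; the feature intensity is averaged over ±``window``.  With a
    matched no-scatterer ``reference`` (same seed, so the same diffuser
    realizations) the background is the reference intensity at the same
    pixels, which cancels residual speckle and the illumination envelope;
    otherwise the median of the surrounding region is used.
    """
    y = result.y
    sel_feat = np.abs(y) <= window
    feat = result.camera_intensity[sel_feat].mean()
    if reference is not None:
        bg = float(reference.camera_intensity[sel_feat].mean())
    else:
        sel = (np.abs(y) <= background_halfwidth) & (np.abs(y) > 2 * window)
        bg = float(np.median(result.camera_intensity[sel]))
    return float((feat - bg) / bg)


def back_focal_plane_analysis(
    system: FourFSystem, core_radius: float | None = None
) -> dict:
    """Energy fraction outside the focused transmitted-wave core at the BFP.

    Runs the coherent (single-realization, no diffuser) system with and
    without the scatterer.  The transmitted wave focuses into a tight core;
    light diffracted by the scatterer crosses the BFP collimated, i.e. well
    outside the core.  Returns both outside-core fractions.
    """
    base = replace(system, include_diffuser=False)
    with_sc = replace(base, include_scatterer=True)
    without = replace(base, include_scatterer=False)
    grid = base.grid()
    y = (np.arange(grid.ny) * grid.spatial_step) - grid.extent_y / 2

    i_without = _run_once(without, None, {"bfp": without.bfp_x})["bfp"]
    i_with = _run_once(with_sc, None, {"bfp": with_sc.bfp_x})["bfp"]

    if core_radius is None:
        # a few diffraction-limited spots: the focused core of an aperture of
        # half-width a at distance f has first zero at f/(2a)
        core_radius = 3.0 * base.focal_length / (2.0 * base.aperture_radius)
    inside = np.abs(y) <= core_radius
    frac = lambda ii: float(ii[~inside].sum() / ii.sum())
    # angular spread of the scattered light alone: rms height of the
    # difference intensity (clipped at zero) inside the stop opening
    diff = np.clip(i_with - i_without, 0.0, None)
    sel = np.abs(y) <= base.aperture_radius
    w = diff[sel]
    rms = float(np.sqrt(np.sum(w * y[sel] ** 2) / w.sum())) if w.sum() > 0 else 0.0
    return {
        "core_radius": float(core_radius),
        "outside_fraction_no_scatterer": frac(i_without),
        "outside_fraction_with_scatterer": frac(i_with),
        "scattered_rms_radius": rms,
    }


def axial_contrast_scan(
    system: FourFSystem,
    z_offsets,
    n_realizations: int = 8,
    seed: int = 0,
) -> AxialScan:
    """Feature contrast at the conjugate pixel for each scatterer defocus."""
    z_offsets = np.asarray(list(z_offsets), dtype=float)
    if len(z_offsets) < 1:
        raise ValueError("need at least one z offset")
    reference = simulate_camera_image(
        replace(system, include_scatterer=False),
        n_realizations=n_realizations, seed=seed,
    )
    contrasts = []
    for z in z_offsets:
        sys_z = replace(system, scatterer_offset=float(z) + system.focus_offset)
        res = simulate_camera_image(sys_z, n_realizations=n_realizations, seed=seed)
        contrasts.append(feature_contrast(res, reference))
    return AxialScan(z=z_offsets, contrast=np.asarray(contrasts))


def calibrate_focus(system: FourFSystem, z_range: float = 8.0,
                    n_points: int = 11, n_realizations: int = 2,
                    seed: int = 0) -> FourFSystem:
    """Locate the camera-conjugate plane and store it as ``focus_offset``.

    Scans the system as configured (with its own illumination) through
    defocus and takes the zero crossing of the feature contrast between the
    bright and dark extrema by linear interpolation — the numerical
    analogue of focusing the bench before a measurement.  The returned
    system has ``focus_offset`` set so that scan coordinates are relative
    to the contrast-inversion plane.
    """
    base = replace(system, focus_offset=0.0)
    if not base.include_diffuser:
        n_realizations = 1
    zs = np.linspace(-z_range, z_range, n_points)
    ref = simulate_camera_image(
        replace(base, include_scatterer=False),
        n_realizations=n_realizations, seed=seed,
    )
    c = np.array([
        feature_contrast(
            simulate_camera_image(
                replace(base, scatterer_offset=float(z)),
                n_realizations=n_realizations, seed=seed,
            ),
            ref,
        )
        for z in zs
    ])
    # zero crossing of the main bright->dark transition (between the global
    # extrema), linearly interpolated; noise-level sign flips far from the
    # transition are ignored
    i_hi, i_lo = int(np.argmax(c)), int(np.argmin(c))
    a, b = sorted((i_hi, i_lo))
    z0 = float(zs[a:b + 1][np.argmin(np.abs(c[a:b + 1]))])
    for i in range(a, b):
        if c[i] == 0 or c[i] * c[i + 1] < 0:
            z0 = float(zs[i] - c[i] * (zs[i + 1] - zs[i]) / (c[i + 1] - c[i]))
            break
    return replace(system, focus_offset=z0)


def scan_extent(scan: AxialScan) -> float:
    """FWHM of |contrast| over the scanned range (axial visibility extent).

    The half-maximum crossings are located by linear interpolation between
    scan points, so the extent is not quantized to the scan grid.
    """
    z = np.asarray(scan.z, dtype=float)
    dev = np.abs(scan.contrast - scan.background)
    half = dev.max() / 2.0
    above = np.where(dev >= half)[0]
    if len(above) == 0:
        return 0.0
    i0, i1 = int(above[0]), int(above[-1])
    z_lo = z[i0]
    if i0 > 0 and dev[i0] != dev[i0 - 1]:
        f = (half - dev[i0 - 1]) / (dev[i0] - dev[i0 - 1])
        z_lo = z[i0 - 1] + f * (z[i0] - z[i0 - 1])
    z_hi = z[i1]
    if i1 < len(z) - 1 and dev[i1] != dev[i1 + 1]:
        f = (dev[i1] - half) / (dev[i1] - dev[i1 + 1])
        z_hi = z[i1] + f * (z[i1 + 1] - z[i1])
    return float(z_hi - z_lo)


def source_size_sweep(
    equivalent_sizes,
    system: FourFSystem,
    z_offsets=None,
    n_realizations: int = 8,
    seed: int = 0,
) -> list[dict]:
    """Contrast and axial extent versus equivalent source size.

    ``equivalent_sizes`` are width/distance ratios realized by moving the
    diffuser assembly (larger ratio = closer assembly = larger incoherent
    source).  Each entry runs an axial contrast scan and reports the
    peak-to-trough contrast and the FWHM visibility extent.
    """
    sizes = list(equivalent_sizes)
    if z_offsets is None:
        d = system.dof_estimate
        z_offsets = np.linspace(-1.6 * d, 1.6 * d, 9)
    rows = []
    for s in sizes:
        if s <= 0:
            raise ValueError("equivalent source size must be positive")
        sys_s = replace(system, diffuser_distance=system.diffuser_width / s)
        scan = axial_contrast_scan(
            sys_s, z_offsets, n_realizations=n_realizations, seed=seed
        )
        rows.append(
            {
                "equivalent_size": float(s),
                "contrast": float(scan.contrast.max() - scan.contrast.min()),
                "axial_extent": scan_extent(scan),
                "scan": scan,
            }
        )
    return rows
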