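"""Seeded phantom generators with ground truth.

No anterior-eye image data ships with the instrument, so every quantitative
behaviour of the processing and measurement chain is validated on synthetic
phantoms that carry their own ground truth: endothelial-style cell mosaics
with both interference-contrast signs in one field (the cornea curves
through focus), curvilinear sub-basal nerve layers at a prescribed length
density, defocused scatterer stacks rendered through the shared defocus
model, and the camera artifacts the pipeline is built to remove
(fixed-pattern noise, Bayer-segment gain mismatch, per-frame noise).

The phantoms emulate counting statistics, contrast signs and artifact
structure — not the full texture of in vivo frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .contrast import DefocusModelParams, SourceDistribution, incoherent_sum_profile


@dataclass
class PhantomSpec:
    """Geometry, content and artifact parameters of one phantom.

    Field of view in mm, pixel pitch in µm.  ``cell_density`` in cells/mm^2,
    ``nerve_density`` in mm/mm^2.  Artifact amplitudes are in the same
    arbitrary intensity units as the rendered image (background level 1).
    """

    fov_mm: tuple = (0.5, 0.5)
    pixel_pitch: float = 1.0
    cell_density: float = 3200.0
    cell_diameter_um: float = 20.0
    nerve_density: float = 22.0
    nerve_width_um: float = 2.5
    modulation: float = 0.35
    defocus_amplitude_um: float = 25.0
    fixed_pattern_rms: float = 0.0
    bayer_amplitude: float = 0.0
    noise_std: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.fov_mm) <= 0 or self.pixel_pitch <= 0:
            raise ValueError("geometry must be positive")
        if self.cell_density < 0 or self.nerve_density < 0:
            raise ValueError("densities must be >= 0")

    @property
    def shape(self) -> tuple:
        h = int(round(self.fov_mm[0] * 1000.0 / self.pixel_pitch))
        w = int(round(self.fov_mm[1] * 1000.0 / self.pixel_pitch))
        return h, w

    @property
    def area_mm2(self) -> float:
        h, w = self.shape
        return h * w * (self.pixel_pitch * 1e-3) ** 2


@dataclass
class GroundTruth:
    """Everything needed to score the metrics without touching pixels."""

    cell_centers: np.ndarray | None = None  # (n, 2) row, col px
    cell_z_um: np.ndarray | None = None
    cell_signs: np.ndarray | None = None  # +1 bright, -1 dark
    bright_mask: np.ndarray | None = None
    cell_density: float | None = None
    cell_diameter_um: float | None = None
    nerve_polylines: list = field(default_factory=list)  # (n,2) µm arrays
    nerve_density: float | None = None
    scatterer_xyz: np.ndarray | None = None
    fixed_pattern: np.ndarray | None = None
    bayer_pattern: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def _defocus_sign_field(shape, defocus_amplitude_um: float, rng) -> np.ndarray:
    """Smooth curvature-like z-offset map (µm) with both signs present.

    A tilted paraboloid: the corneal surface bows through the focal plane so
    one part of the field sits above focus and the rest below.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy = h * rng.uniform(0.3, 0.7)
    cx = w * rng.uniform(0.3, 0.7)
    r2 = ((yy - cy) / (0.6 * h)) ** 2 + ((xx - cx) / (0.6 * w)) ** 2
    f = r2 - np.median(r2)
    # sigmoidal saturation: most of the field sits clearly above or below
    # focus, with a narrow invisible transition band at the crossing
    z = defocus_amplitude_um * np.tanh(4.0 * f / np.std(f))
    return z


def _gouy(z_um: np.ndarray, z_r_um: float) -> np.ndarray:
    zn = z_um / z_r_um
    return zn / (1.0 + zn**2)


def gen_endothelial_mosaic(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Space-filling cell mosaic with signed interference contrast.

    Cell centres come from a jittered hexagonal point process at the target
    density; the mosaic is the nearest-centre partition.  Each cell is
    rendered with a modulation whose sign and strength follow the Gouy-phase
    defocus law at the cell's z offset, taken from a smooth curvature-like
    field, so bright and dark cells coexist in one image.
    """
    if not 500.0 <= spec.cell_density <= 6000.0:
        raise ValueError("cell_density outside the supported 500-6000 cells/mm^2")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    pitch_mm = spec.pixel_pitch * 1e-3

    # hexagonal lattice with area per cell = 1/density
    a = math.sqrt(2.0 / (math.sqrt(3.0) * spec.cell_density)) / pitch_mm  # px
    rows = np.arange(0, h + a, a * math.sqrt(3) / 2)
    centers = []
    for k, ry in enumerate(rows):
        xs = np.arange((a / 2 if k % 2 else 0.0), w + a, a)
        for rx in xs:
            centers.append((ry, rx))
    centers = np.asarray(centers)
    centers += rng.normal(0.0, 0.10 * a, centers.shape)
    keep = (
        (centers[:, 0] >= 0) & (centers[:, 0] < h)
        & (centers[:, 1] >= 0) & (centers[:, 1] < w)
    )
    centers = centers[keep]

    zfield = _defocus_sign_field((h, w), spec.defocus_amplitude_um, rng)
    cz = zfield[
        np.clip(centers[:, 0].astype(int), 0, h - 1),
        np.clip(centers[:, 1].astype(int), 0, w - 1),
    ]
    z_r = spec.defocus_amplitude_um / 2.0
    amp = spec.modulation * _gouy(cz, z_r) / np.max(np.abs(_gouy(cz, z_r)))

    # nearest-centre partition; each cell renders as a peaked bump around its
    # own centre so neighbouring same-sign cells stay resolvable
    yy, xx = np.mgrid[0:h, 0:w]
    tree = cKDTree(centers)
    _, label = tree.query(np.column_stack([yy.ravel(), xx.ravel()]), k=1)
    label = label.reshape(h, w)
    r2_own = (yy - centers[label, 0]) ** 2 + (xx - centers[label, 1]) ** 2
    bump = np.exp(-r2_own / (2.0 * (0.25 * a) ** 2))

    image = 1.0 + amp[label] * bump
    gt = GroundTruth(
        cell_centers=centers,
        cell_z_um=cz,
        cell_signs=np.sign(amp).astype(int),
        bright_mask=(amp[label] > 0),
        cell_density=len(centers) / spec.area_mm2,
        cell_diameter_um=2.0 * math.sqrt(1.0 / (math.pi * spec.cell_density)) * 1000.0,
        extra={"z_field": zfield, "label": label},
    )
    return image, gt


def gen_nerve_layer(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Curvilinear nerve strokes at a prescribed length density.

    Smooth random walks of bounded curvature are added until the total
    length per area is within 2% of the target (the last stroke is
    truncated to land on it).  Nerves render dark on the bright
    transmission background, as sub-basal nerves typically do near focus.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    target_mm = spec.nerve_density * spec.area_mm2
    step_px = 2.0
    step_mm = step_px * spec.pixel_pitch * 1e-3

    mask = np.zeros((h, w))
    polylines = []
    total = 0.0
    guard = 0
    while total < target_mm * 0.999 and target_mm > 0 and guard < 10000:
        guard += 1
        y = rng.uniform(0.05 * h, 0.95 * h)
        x = rng.uniform(0.05 * w, 0.95 * w)
        theta = rng.uniform(0, 2 * math.pi)
        n_steps = int(rng.uniform(150, 400) / step_px)
        pts = [(y, x)]
        for _ in range(n_steps):
            theta += rng.normal(0.0, 0.12)
            y += step_px * math.sin(theta)
            x += step_px * math.cos(theta)
            if not (0 <= y < h and 0 <= x < w):
                break
            pts.append((y, x))
            total += step_mm
            if total >= target_mm:
                break
        if len(pts) >= 2:
            poly = np.asarray(pts) * spec.pixel_pitch  # µm
            polylines.append(poly)
            rr = np.asarray(pts)
            ir, ic = rr[:, 0].astype(int), rr[:, 1].astype(int)
            mask[ir, ic] = 1.0

    width_px = spec.nerve_width_um / spec.pixel_pitch
    profile = ndimage.gaussian_filter(mask, sigma=max(width_px / 2.0, 0.6))
    if profile.max() > 0:
        profile = profile / profile.max()
    image = 1.0 - spec.modulation * profile

    density = total / spec.area_mm2
    gt = GroundTruth(nerve_polylines=polylines, nerve_density=density)
    return image, gt


def gen_scatterer_stack(
    spec: PhantomSpec,
    z_offsets,
    source_diameter_mm: float = 2.4,
    n_scatterers: int = 12,
    params: DefocusModelParams | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Through-focus stack of point scatterers under the shared defocus law.

    Each scatterer at depth z0 appears in the slice focused at zf with the
    incoherent-sum modulation evaluated at (zf - z0) and a lateral Gaussian
    footprint that widens with defocus, reproducing the bright → invisible →
    dark transition; a smaller secondary source keeps scatterers visible
    over more slices.
    """
    if params is None:
        params = DefocusModelParams(na_detection=0.3)
    z_offsets = np.asarray(list(z_offsets), dtype=float)
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    src = SourceDistribution(diameter=source_diameter_mm)
    zspan = max(abs(z_offsets).max(), params.z_r)
    sy = rng.uniform(0.15 * h, 0.85 * h, n_scatterers)
    sx = rng.uniform(0.15 * w, 0.85 * w, n_scatterers)
    sz = rng.uniform(-0.6 * zspan, 0.6 * zspan, n_scatterers)

    frames = np.ones((len(z_offsets), h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    for k, zf in enumerate(z_offsets):
        dz = zf - sz  # µm, per scatterer
        mod = incoherent_sum_profile(dz, src, params).intensity
        for i in range(n_scatterers):
            sigma_px = max(params.beam_radius(dz[i]) / spec.pixel_pitch, 0.8)
            r2 = (yy - sy[i]) ** 2 + (xx - sx[i]) ** 2
            frames[k] += (
                spec.modulation * mod[i] * np.exp(-r2 / (2 * sigma_px**2))
            )
    gt = GroundTruth(
        scatterer_xyz=np.column_stack([sy, sx, sz]),
        extra={"z_offsets": z_offsets, "source_diameter_mm": source_diameter_mm},
    )
    return frames, gt


def add_camera_artifacts(
    frames: np.ndarray, spec: PhantomSpec, poisson: bool = False
) -> tuple[np.ndarray, GroundTruth]:
    """Add static fixed-pattern noise, Bayer-period modulation and noise.

    The fixed pattern (smooth component plus per-pixel component, scaled to
    ``fixed_pattern_rms``) is shared by all frames of a stack; the Bayer
    mismatch is a multiplicative period-2 gain map; per-frame noise is
    Gaussian of ``noise_std`` (or Poisson shot noise when requested).
    Returns the corrupted frames and the injected artifact fields.
    """
    rng = np.random.default_rng(spec.seed + 1)
    arr = np.asarray(frames, dtype=float)
    single = arr.ndim == 2
    stack = arr[None] if single else arr.copy()
    h, w = stack.shape[1:]

    fp = np.zeros((h, w))
    if spec.fixed_pattern_rms > 0:
        smooth = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=6.0)
        pixel = rng.normal(size=(h, w))
        fp = 0.6 * smooth / smooth.std() + 0.4 * pixel
        fp = fp / fp.std() * spec.fixed_pattern_rms
        fp -= fp.mean()

    bayer = np.ones((h, w))
    if spec.bayer_amplitude > 0:
        gains = 1.0 + spec.bayer_amplitude * np.array([1.0, -0.5, 0.5, -1.0])
        cell = gains.reshape(2, 2)
        bayer = np.tile(cell, (h // 2 + 1, w // 2 + 1))[:h, :w]

    out = (stack + fp[None]) * bayer[None]
    if poisson:
        scale = 1000.0
        out = rng.poisson(np.clip(out, 0, None) * scale) / scale
    elif spec.noise_std > 0:
        out = out + rng.normal(0.0, spec.noise_std, out.shape)

    gt = GroundTruth(fixed_pattern=fp, bayer_pattern=bayer)
    return (out[0] if single else out), gt


def gen_moving_stack(
    image: np.ndarray, n_frames: int, max_shift_px: int = 20, seed: int = 0
) -> np.ndarray:
    """Stack of circularly shifted copies emulating inter-frame eye motion."""
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        dy, dx = rng.integers(-max_shift_px, max_shift_px + 1, 2)
        frames.append(np.roll(image, (int(dy), int(dx)), axis=(0, 1)))
    return np.stack(frames)
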