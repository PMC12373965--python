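"""Morphometric metrics: cell density, nerve length density, diameters, SNR.

Clinical readouts of the anterior segment reduce to a handful of numbers:
endothelial/epithelial cell density (cells/mm^2, the decompensation-risk
biomarker), sub-basal nerve fibre length density (mm of nerve per mm^2, the
dry-eye/neuropathy biomarker), characteristic cell diameter per layer, and
the image SNR.  Because interference contrast renders cells bright on one
side of focus and dark on the other — both signs in one image when the
cornea curves through focus — counting is restricted to a single contrast
sign within the region where that sign dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.morphology import skeletonize


@dataclass
class CellDetections:
    """Detected cell centres with the contrast sign they were counted on."""

    centers: np.ndarray  # (n, 2) row, col in px
    sign: str  # "bright" | "dark"
    area_mm2: float
    pixel_pitch: float  # µm

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        if self.area_mm2 <= 0:
            raise ValueError("analysis area must be > 0")

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class NerveTrace:
    """Nerve paths as polylines (µm coordinates) or a skeleton mask."""

    polylines: list = field(default_factory=list)  # list of (n,2) µm arrays
    skeleton: np.ndarray | None = None
    pixel_pitch: float = 1.0  # µm
    area_mm2: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0 or self.area_mm2 <= 0:
            raise ValueError("pixel pitch and area must be > 0")


def detect_cells(
    image: np.ndarray,
    sign: str = "bright",
    expected_diameter_um: float = 20.0,
    pixel_pitch: float | None = None,
    mask: np.ndarray | None = None,
    area_mm2: float | None = None,
    threshold_rel: float = 0.3,
) -> CellDetections:
    """Local-extremum cell detection at the expected cell scale.

    The (band-passed) image is smoothed at ~1/4 of the expected diameter and
    local maxima of the selected contrast sign are kept, with a minimum
    separation of half the expected diameter.  Detection is invariant to
    global affine intensity changes: the threshold is relative to the robust
    deviation range of the (sign-selected) image.
    """
    if pixel_pitch is None or pixel_pitch <= 0:
        raise ValueError("pixel_pitch (µm) is required")
    if sign not in ("bright", "dark"):
        raise ValueError("sign must be 'bright' or 'dark'")
    img = np.asarray(image, dtype=float)
    work = img - np.median(img)
    if sign == "dark":
        work = -work
    diam_px = expected_diameter_um / pixel_pitch
    work = ndimage.gaussian_filter(work, sigma=max(diam_px / 8.0, 0.5))
    scale = np.percentile(np.abs(work), 99.5)
    if scale <= 0:
        centers = np.empty((0, 2))
    else:
        min_dist = max(int(round(0.4 * diam_px)), 1)
        centers = peak_local_max(
            work,
            min_distance=min_dist,
            threshold_abs=threshold_rel * scale,
            exclude_border=False,
            labels=None if mask is None else mask.astype(int),
        ).astype(float)
    if area_mm2 is None:
        npix = img.size if mask is None else int(np.count_nonzero(mask))
        area_mm2 = npix * (pixel_pitch * 1e-3) ** 2
    return CellDetections(centers=centers, sign=sign, area_mm2=area_mm2,
                          pixel_pitch=pixel_pitch)


def cell_density(d: CellDetections) -> float:
    """Cells per mm^2: count / analysis area."""
    return len(d) / d.area_mm2


def nerve_length_density(trace: NerveTrace) -> float:
    """Total nerve length per area, mm/mm^2.

    Polylines are summed directly; a skeleton mask is measured with the
    8-connectivity estimator (orthogonal steps count the pitch, diagonal
    steps sqrt(2)·pitch).
    """
    length_mm = 0.0
    for poly in trace.polylines:
        p = np.asarray(poly, dtype=float)
        if len(p) >= 2:
            length_mm += float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1))) * 1e-3
    if trace.skeleton is not None:
        length_mm += skeleton_length_mm(trace.skeleton, trace.pixel_pitch)
    return length_mm / trace.area_mm2


def skeleton_length_mm(skeleton: np.ndarray, pixel_pitch: float) -> float:
    """Length of a binary skeleton, mm, counting orthogonal and diagonal links.

    Uses Kulpa's corrected link weights (0.948 orthogonal, 1.340 diagonal),
    which remove the ~5% over-estimation of the naive (1, sqrt(2)) chain
    estimator for lines of random orientation.
    """
    sk = np.asarray(skeleton, bool)
    # count each link once: right, down, down-right, down-left neighbours
    ortho = np.count_nonzero(sk[:, :-1] & sk[:, 1:]) + np.count_nonzero(
        sk[:-1, :] & sk[1:, :]
    )
    diag = np.count_nonzero(sk[:-1, :-1] & sk[1:, 1:]) + np.count_nonzero(
        sk[:-1, 1:] & sk[1:, :-1]
    )
    return (0.948 * ortho + 1.340 * diag) * pixel_pitch * 1e-3


def trace_nerves(
    image: np.ndarray,
    pixel_pitch: float,
    threshold_rel: float = 0.25,
    sign: str = "dark",
    min_object_px: int = 20,
) -> NerveTrace:
    """Segment and skeletonize curvilinear nerve structures.

    Thresholds the sign-selected deviation image at ``threshold_rel`` of its
    99.5th percentile, removes specks below ``min_object_px`` and
    skeletonizes.  Replaces manual/NN segmentation for phantom work.
    """
    img = np.asarray(image, dtype=float)
    work = img - np.median(img)
    if sign == "dark":
        work = -work
    work = ndimage.gaussian_filter(work, sigma=0.8)
    scale = np.percentile(work[work > 0], 99.5) if (work > 0).any() else 0.0
    if scale <= 0:
        sk = np.zeros(img.shape, bool)
    else:
        binary = work > threshold_rel * scale
        lab, n = ndimage.label(binary)
        sizes = ndimage.sum_labels(binary, lab, index=np.arange(1, n + 1))
        keep = np.isin(lab, np.where(sizes >= min_object_px)[0] + 1)
        sk = skeletonize(keep)
    area = img.size * (pixel_pitch * 1e-3) ** 2
    return NerveTrace(polylines=[], skeleton=sk, pixel_pitch=pixel_pitch, area_mm2=area)


def mean_cell_diameter(diameters_um) -> float:
    """Arithmetic mean of manually measured cell diameters, µm."""
    d = np.asarray(list(diameters_um), dtype=float)
    if d.size == 0:
        raise ValueError("need at least one diameter")
    return float(d.mean())


def snr_db(
    image: np.ndarray,
    signal_roi: tuple[slice, slice],
    noise_roi: tuple[slice, slice],
    power: bool = False,
) -> float:
    """SNR in dB: mean of the signal ROI over the std of the noise ROI.

    Amplitude convention 20·log10 by default; ``power=True`` uses 10·log10.
    """
    img = np.asarray(image, dtype=float)
    sig = img[signal_roi]
    noise = img[noise_roi]
    ns = float(noise.std())
    if ns == 0:
        raise ValueError("noise ROI has zero standard deviation")
    factor = 10.0 if power else 20.0
    return factor * float(np.log10(np.abs(sig.mean()) / ns))
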