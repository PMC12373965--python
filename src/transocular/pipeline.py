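"""Raw-frame processing chain for the two prototype cameras.

The colour rolling-shutter camera needs a minimal 3x3 Gaussian blur to even
out the Bayer-segment gain mismatch; the front-illuminated mono camera needs
its static fixed-pattern noise subtracted (temporal mean over a stack of
*moving* eye images); both then get a large-kernel (121x121) high-pass to
strip the bright uniform transmission background, and frames may be averaged
for SNR.  A software rolling buffer stands in for a hardware trigger: only
the frame whose exposure caught the LED pulse (maximal mean intensity) is
kept.  Two co-registered cameras at different defocus capture the two
interference phases; subtracting them doubles in-focus phase contrast and
cancels the defocus-symmetric background (tomographic mode).

All operations take/return float64 arrays or :class:`ImageStack` and use
reflect padding at the borders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation


class CameraTag(Enum):
    MONO_GLOBAL = "mono_global"
    COLOR_ROLLING = "color_rolling"


@dataclass
class Frame:
    """Single camera frame with physical pixel pitch in µm."""

    data: np.ndarray
    pixel_pitch: float = 1.0
    camera: CameraTag = CameraTag.MONO_GLOBAL
    index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("frame data must be 2D")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")


@dataclass
class ImageStack:
    """Ordered stack of equally shaped frames."""

    frames: np.ndarray  # (n, h, w)
    pixel_pitch: float = 1.0
    camera: CameraTag = CameraTag.MONO_GLOBAL
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or len(self.frames) < 1:
            raise ValueError("stack must be (n >= 1, h, w)")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")

    def __len__(self) -> int:
        return len(self.frames)


def bayer_smooth(frame: np.ndarray, camera: CameraTag = CameraTag.COLOR_ROLLING,
                 sigma: float = 0.8) -> np.ndarray:
    """Minimal 3x3 Gaussian blur removing the Bayer-period gain checkerboard.

    On a mono frame this is a no-op (with a warning): there is no mosaic to
    uniformize.
    """
    frame = np.asarray(frame, dtype=float)
    if camera is not CameraTag.COLOR_ROLLING:
        warnings.warn("bayer_smooth called on a mono frame; returning input unchanged")
        return frame.copy()
    return ndimage.gaussian_filter(frame, sigma=sigma, radius=1, mode="reflect")


def remove_fixed_pattern(stack: ImageStack) -> ImageStack:
    """Subtract the per-pixel temporal mean from every frame.

    With inter-frame motion of the eye, the temporal mean holds the static
    sensor pattern (plus a motion-blurred scene average); subtracting it
    cancels the fixed-pattern noise exactly while moving content survives up
    to a DC shift.
    """
    if len(stack) < 2:
        raise ValueError("fixed-pattern removal needs a stack of moving frames (>= 2)")
    frames = np.asarray(stack.frames, dtype=float)
    out = frames - frames.mean(axis=0, keepdims=True)
    return ImageStack(out, stack.pixel_pitch, stack.camera, dict(stack.metadata))


def highpass(frame: np.ndarray, kernel_size: int = 121, gaussian: bool = False) -> np.ndarray:
    """Subtract the large-kernel local mean, suppressing the bright background.

    Boxcar mean of ``kernel_size`` (odd) by default; ``gaussian=True`` uses a
    Gaussian of matching support instead.
    """
    if kernel_size < 3 or kernel_size % 2 == 0:
        raise ValueError("kernel_size must be odd and >= 3")
    frame = np.asarray(frame, dtype=float)
    if gaussian:
        lowpass = ndimage.gaussian_filter(
            frame, sigma=kernel_size / 6.0, radius=kernel_size // 2, mode="reflect"
        )
    else:
        lowpass = ndimage.uniform_filter(frame, size=kernel_size, mode="reflect")
    return frame - lowpass


def register_translation(reference: np.ndarray, moving: np.ndarray) -> tuple[float, float]:
    """Translation (dy, dx) aligning ``moving`` onto ``reference`` (px)."""
    shift, _, _ = phase_cross_correlation(
        np.asarray(reference, float), np.asarray(moving, float), upsample_factor=10
    )
    return float(shift[0]), float(shift[1])


def average_frames(stack: ImageStack, n: int | None = None, register: bool = False) -> np.ndarray:
    """Pixel-wise mean of the first ``n`` frames (optionally aligned first).

    Averaging n frames of matched content reduces additive white noise by
    ~sqrt(n).
    """
    n = len(stack) if n is None else n
    if n < 1 or n > len(stack):
        raise ValueError(f"n must be in [1, {len(stack)}]")
    frames = np.asarray(stack.frames[:n], dtype=float)
    if register and n > 1:
        ref = frames[0]
        aligned = [ref]
        for f in frames[1:]:
            dy, dx = register_translation(ref, f)
            aligned.append(ndimage.shift(f, (dy, dx), mode="reflect", order=1))
        frames = np.stack(aligned)
    return frames.mean(axis=0)


def select_pulse_frame(buffer: ImageStack) -> np.ndarray:
    """Frame of maximal mean intensity — the one that caught the LED pulse.

    Ties go to the earliest frame.
    """
    if len(buffer) == 0:
        raise ValueError("empty rolling buffer")
    means = np.asarray(buffer.frames, dtype=float).mean(axis=(1, 2))
    return np.asarray(buffer.frames[int(np.argmax(means))], dtype=float).copy()


def two_phase_subtract(frame_a: np.ndarray, frame_b: np.ndarray,
                       gain_match: bool = True) -> np.ndarray:
    """Difference of two co-registered frames at opposite defocus.

    In-focus phase structures flip sign between the two planes and are
    reinforced; defocus-symmetric background cancels.  ``gain_match`` scales
    frame_b by the ratio of medians before subtracting.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if gain_match:
        mb = np.median(b)
        if mb != 0:
            b = b * (np.median(a) / mb)
    return a - b


def process_stack(
    stack: ImageStack,
    highpass_kernel: int = 121,
    average: int | None = None,
    gaussian_highpass: bool = False,
) -> ImageStack | np.ndarray:
    """Camera-appropriate chain: Bayer blur / fixed-pattern → high-pass → average.

    Colour rolling-shutter frames get the 3x3 Bayer blur; mono global-shutter
    stacks get temporal-mean fixed-pattern subtraction.  Both then receive
    the large-kernel high-pass per frame.  With ``average`` set, returns the
    averaged 2D frame; otherwise the processed stack.
    """
    if stack.camera is CameraTag.COLOR_ROLLING:
        frames = np.stack([bayer_smooth(f, stack.camera) for f in stack.frames])
        work = ImageStack(frames, stack.pixel_pitch, stack.camera, dict(stack.metadata))
    else:
        work = remove_fixed_pattern(stack) if len(stack) >= 2 else ImageStack(
            np.asarray(stack.frames, float), stack.pixel_pitch, stack.camera,
            dict(stack.metadata),
        )
    frames = np.stack([highpass(f, highpass_kernel, gaussian_highpass) for f in work.frames])
    out = ImageStack(frames, stack.pixel_pitch, stack.camera, dict(stack.metadata))
    if average is not None:
        return average_frames(out, average)
    return out
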