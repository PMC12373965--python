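"""Image stack readers/writers and sidecar metadata.

TIFF (single- or multi-page, via tifffile) and numbered PNG sequences are
supported losslessly for 8/16-bit integer and float data; 10-bit camera data
travels in its 16-bit container untouched.  Physical metadata (pixel pitch,
camera tag, seed, arbitrary parameters) that the raster formats cannot carry
reliably goes into a YAML sidecar next to the image file.
"""

from __future__ import annotations

import glob
import os

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .pipeline import CameraTag, ImageStack


class FormatError(ValueError):
    """Unreadable, inconsistent or unsupported image input."""


def _sidecar_path(path: str) -> str:
    return os.path.splitext(path)[0] + ".meta.yaml"


def write_stack(stack: ImageStack, path: str, **extra_metadata) -> None:
    """Write a stack as multi-page TIFF (or single-page for one frame).

    Pixel pitch and camera tag are recorded in a ``<name>.meta.yaml``
    sidecar along with any extra metadata.
    """
    frames = np.asarray(stack.frames)
    tifffile.imwrite(path, frames if len(frames) > 1 else frames[0],
                     photometric="minisblack")
    meta = {
        "pixel_pitch_um": float(stack.pixel_pitch),
        "camera": stack.camera.value,
        **stack.metadata,
        **extra_metadata,
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_stack(path: str) -> ImageStack:
    """Read TIFF (single/multi-page) or a numbered PNG pattern into a stack.

    ``path`` may be a TIFF file, a single PNG, or a glob pattern matching a
    numbered PNG sequence.  Pages of differing shape raise
    :class:`FormatError`.
    """
    meta = {}
    sidecar = _sidecar_path(path if "*" not in path else path.replace("*", "0"))
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}

    if "*" in path or path.lower().endswith(".png"):
        files = sorted(glob.glob(path)) if "*" in path else [path]
        if not files:
            raise FormatError(f"no files match {path!r}")
        frames = [np.asarray(iio.imread(f)) for f in files]
    else:
        try:
            with tifffile.TiffFile(path) as tf:
                frames = [p.asarray() for p in tf.pages]
        except Exception as exc:
            raise FormatError(f"cannot read {path!r}: {exc}") from exc

    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FormatError(f"mixed page shapes in {path!r}: {sorted(shapes)}")
    arr = np.stack(frames)
    if arr.ndim == 4:  # (1, n, h, w) from a 3D first page
        arr = arr.reshape(-1, *arr.shape[-2:])
    if arr.ndim != 3:
        raise FormatError(f"unsupported dimensionality {arr.ndim} in {path!r}")
    return ImageStack(
        frames=arr,
        pixel_pitch=float(meta.get("pixel_pitch_um", 1.0)),
        camera=CameraTag(meta.get("camera", "mono_global")),
        metadata={k: v for k, v in meta.items() if k not in ("pixel_pitch_um", "camera")},
    )


def write_table(rows: list[dict], path: str, sep: str = "\t") -> None:
    """Write a list of flat dicts as a delimited text table."""
    if not rows:
        raise ValueError("no rows to write")
    cols = list(rows[0])
    with open(path, "w") as fh:
        fh.write(sep.join(cols) + "\n")
        for r in rows:
            fh.write(sep.join(str(r[c]) for c in cols) + "\n")
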