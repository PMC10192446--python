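"""TIFF stack I/O with voxel calibration.

Stacks are stored as multi-page grayscale TIFF, page order = z order, with
ImageJ-style axis metadata so calibration (XY pixel size, z spacing, bit
depth) survives a round trip bit-exactly.  Microscope-vendor containers are
out of scope: stacks exported as plain TIFF are the interchange format.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError
from .segmentation import ImageStack, LabeledMask


def write_stack(stack: ImageStack, path) -> None:
    """Write a calibrated stack as a multi-page grayscale ImageJ TIFF."""
    tifffile.imwrite(
        str(path),
        stack.voxels,
        imagej=True,
        resolution=(1.0 / stack.pixel_size, 1.0 / stack.pixel_size),
        metadata={
            "spacing": float(stack.z_spacing),
            "unit": "um",
            "axes": "ZYX",
            "pixel_size_um": float(stack.pixel_size),
            "bit_depth": int(stack.bit_depth),
        },
    )


def read_stack(path) -> ImageStack:
    """Read a multi-page grayscale TIFF written by :func:`write_stack`.

    Plain grayscale TIFFs from other sources are accepted too; calibration
    then falls back to 1 um pixels / 20 um spacing.  RGB pages or pages of
    differing shape raise :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(str(path)) as tf:
            shapes = {p.shape for p in tf.pages}
            if any(len(s) != 2 for s in shapes):
                raise FormatError(f"{path}: pages are not single-channel grayscale")
            if len(shapes) != 1:
                raise FormatError(f"{path}: page sizes differ across pages")
            data = tf.asarray()
            meta = tf.imagej_metadata or {}
    except FormatError:
        raise
    except Exception as exc:  # corrupt container
        raise FormatError(f"{path}: cannot be read as TIFF ({exc})") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 2D/3D grayscale image")
    if data.dtype == np.uint8:
        bit_depth = 8
    elif data.dtype == np.uint16:
        bit_depth = 16
    else:
        raise FormatError(f"{path}: unsupported dtype {data.dtype}")
    return ImageStack(
        voxels=data,
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
        z_spacing=float(meta.get("spacing", 20.0)),
        bit_depth=int(meta.get("bit_depth", bit_depth)),
    )


def write_mask(mask: LabeledMask, path, binary: bool = False) -> None:
    """Write a labelled mask: 16-bit label image, or 8-bit 0/255 if binary."""
    if binary:
        data = np.where(mask.labels > 0, 255, 0).astype(np.uint8)
    else:
        if mask.labels.max() > 65535:
            raise FormatError("too many labels for a 16-bit label image")
        data = mask.labels.astype(np.uint16)
    tifffile.imwrite(str(path), data, metadata={"provenance": mask.provenance})


def read_mask(path, provenance: str = "projection") -> LabeledMask:
    data = tifffile.imread(str(path))
    if data.ndim != 2:
        raise FormatError(f"{path}: expected a single-page mask")
    labels = data.astype(np.int32)
    n = int(len(np.unique(labels[labels > 0])))
    return LabeledMask(labels=labels, n_objects=n, provenance=provenance)
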