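"""Calibrated 2D image container and TIFF I/O.

Images follow the standard lateral-view mounting convention for zebrafish
embryos: anterior to the left, dorsal to the top.  All physical quantities
are in micrometres; ``px_size_um`` converts between pixel and physical
coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import ConfigError


@dataclass
class PixelImage:
    """A single-channel image with micrometre calibration.

    Parameters
    ----------
    data
        2D float array of non-negative intensities (arbitrary fluorescence
        units).
    px_size_um
        Pixel size in micrometres per pixel (isotropic).
    anterior_left
        Orientation convention flag: anterior at left, dorsal at top.  The
        flag is mandatory so that angle signs are interpretable; all
        analysis code assumes it is True.
    """

    data: np.ndarray
    px_size_um: float
    anterior_left: bool = True

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigError(f"PixelImage expects a 2D array, got ndim={self.data.ndim}")
        if self.px_size_um <= 0:
            raise ConfigError(f"px_size_um must be positive, got {self.px_size_um}")
        if np.nanmin(self.data) < 0:
            raise ConfigError("PixelImage intensities must be non-negative")

    @property
    def shape(self):
        return self.data.shape

    def um_to_px(self, um: float) -> float:
        return um / self.px_size_um

    def px_to_um(self, px: float) -> float:
        return px * self.px_size_um


def save_tiff(path, image: PixelImage | np.ndarray, px_size_um: float | None = None,
              frame_interval_s: float | None = None) -> None:
    """Write an image or stack as TIFF with micrometre pixel-size metadata."""
    if isinstance(image, PixelImage):
        data, px = image.data, image.px_size_um
    else:
        data, px = np.asarray(image), px_size_um
    if px is None:
        raise ConfigError("px_size_um required when saving a bare array")
    meta = {"px_size_um": px, "unit": "um"}
    if frame_interval_s is not None:
        meta["frame_interval_s"] = frame_interval_s
    tifffile.imwrite(
        path,
        np.asarray(data, dtype=np.float32),
        resolution=(1.0 / px, 1.0 / px),
        description=json.dumps(meta),
    )


def load_tiff(path):
    """Load a TIFF written by :func:`save_tiff`.

    Returns
    -------
    (data, metadata) where metadata holds ``px_size_um`` and, for stacks,
    ``frame_interval_s``.
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError):
        meta = {}
    if "px_size_um" not in meta:
        raise ConfigError(f"TIFF {path} lacks px_size_um calibration metadata")
    return np.asarray(data, dtype=float), meta


def load_pixel_image(path) -> PixelImage:
    data, meta = load_tiff(path)
    return PixelImage(data=data, px_size_um=float(meta["px_size_um"]))
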