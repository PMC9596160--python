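"""Dorsoventral ROI grids for branch-density profiling.

Branch density along the dorsoventral axis is measured by counting
thresholded objects inside a stack of horizontal bands ("ROIs") placed at
regularly spaced intervals from dorsal (top) to ventral (bottom).  The
band height follows the assay convention of 3 µm; the number of bands
defaults to eight.  Spacing and anchoring are configuration values and are
recorded alongside any output computed from a grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError


@dataclass(frozen=True)
class ROIGrid:
    """A ladder of horizontal bands, ordered dorsal (index 0) to ventral.

    Parameters
    ----------
    n_rois
        Number of bands (default 8).
    roi_height_um
        Height of each band in µm (default 3).
    spacing_um
        Edge-to-edge vertical gap between consecutive bands in µm.
    top_anchor_um
        y (µm, measured downward from the image top) of the top edge of the
        first band — conventionally aligned with the bottom of the central
        axon fascicle.
    x_extent_um
        Optional (x0, x1) horizontal extent in µm; None means full width.
    """

    n_rois: int = 8
    roi_height_um: float = 3.0
    spacing_um: float = 5.0
    top_anchor_um: float = 0.0
    x_extent_um: tuple | None = None

    def __post_init__(self):
        if self.n_rois < 1:
            raise ConfigError("n_rois must be >= 1")
        if self.roi_height_um <= 0:
            raise ConfigError("roi_height_um must be positive")
        if self.spacing_um < 0:
            raise ConfigError("spacing_um must be non-negative (bands may not overlap)")

    def band_bounds_um(self) -> list[tuple[float, float]]:
        """(y_top, y_bottom) in µm for each band, dorsal to ventral."""
        pitch = self.roi_height_um + self.spacing_um
        return [
            (self.top_anchor_um + i * pitch, self.top_anchor_um + i * pitch + self.roi_height_um)
            for i in range(self.n_rois)
        ]

    def band_bounds_px(self, px_size_um: float) -> list[tuple[int, int]]:
        """Integer pixel row bounds [y0, y1) for each band."""
        out = []
        for y0, y1 in self.band_bounds_um():
            out.append((int(round(y0 / px_size_um)), int(round(y1 / px_size_um))))
        return out

    def x_bounds_px(self, px_size_um: float, width_px: int) -> tuple[int, int]:
        if self.x_extent_um is None:
            return 0, width_px
        x0, x1 = self.x_extent_um
        return int(round(x0 / px_size_um)), int(round(x1 / px_size_um))

    def validate_for_image(self, shape: tuple, px_size_um: float) -> None:
        h, w = shape
        for i, (y0, y1) in enumerate(self.band_bounds_px(px_size_um)):
            if y0 < 0 or y1 > h:
                raise ConfigError(
                    f"ROI {i + 1} spans rows [{y0}, {y1}) outside image height {h}"
                )
        x0, x1 = self.x_bounds_px(px_size_um, w)
        if x0 < 0 or x1 > w or x0 >= x1:
            raise ConfigError(f"ROI x-extent [{x0}, {x1}) outside image width {w}")

    @classmethod
    def standard_for_image(cls, shape: tuple, px_size_um: float,
                           n_rois: int = 8, roi_height_um: float = 3.0) -> "ROIGrid":
        """Evenly distribute ``n_rois`` bands over the central image height.

        A margin of roughly half a band pitch is kept at the top and
        bottom; spacing is derived from the available span.
        """
        h_um = shape[0] * px_size_um
        margin = 0.06 * h_um
        span = h_um - 2 * margin
        total_band = n_rois * roi_height_um
        if span <= total_band:
            raise ConfigError("image too short for the requested band count")
        spacing = (span - total_band) / (n_rois - 1) - 1e-9 if n_rois > 1 else 0.0
        return cls(
            n_rois=n_rois,
            roi_height_um=roi_height_um,
            spacing_um=spacing,
            top_anchor_um=margin,
        )
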