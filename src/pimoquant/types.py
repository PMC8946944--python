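"""Core raster containers shared by every pipeline stage.

All images are single-plane 2-D rasters with an isotropic micron-per-pixel
calibration. Masks remember how they were built (``provenance``) plus the
structured values behind that description (``meta``), so a run can be
re-executed bit-identically from its provenance record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = ["ChannelImage", "BinaryMask", "ThresholdPolicy", "um_to_px"]


def um_to_px(length_um: float, pixel_size_um: float) -> int:
    """Convert a physical length to a pixel radius/length.

    Always at least one pixel, so micron-calibrated morphology never
    degenerates to a no-op on coarse rasters.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    return max(1, round(length_um / pixel_size_um))


@dataclass
class ChannelImage:
    """One stained channel: a 2-D non-negative intensity raster.

    Parameters
    ----------
    pixels
        2-D float array of fluorescence intensities.
    pixel_size_um
        Isotropic calibration, microns per pixel.
    label
        Channel name, e.g. ``nuclear``, ``pimo``, ``ecadherin`` or a
        marker name such as ``glut3``.
    origin_px
        (row, col) offset of this raster inside its parent image; set by
        tiling so per-tile results can be mapped back.
    """

    pixels: np.ndarray
    pixel_size_um: float
    label: str = ""
    origin_px: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("ChannelImage requires a non-empty 2-D raster")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """A boolean raster sharing the calibration of its source channel."""

    pixels: np.ndarray
    pixel_size_um: float
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("BinaryMask requires a non-empty 2-D raster")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    def same_grid_as(self, other: "BinaryMask | ChannelImage") -> bool:
        return self.shape == other.shape and np.isclose(
            self.pixel_size_um, other.pixel_size_um
        )


@dataclass(frozen=True)
class ThresholdPolicy:
    """An explicit, recordable rule for choosing an intensity cutoff.

    The original analyses chose thresholds empirically per tumor; making
    the choice a value object keeps every run reproducible. ``fixed``
    returns ``value`` verbatim, ``otsu`` maximizes between-class variance,
    ``quantile`` returns the stated intensity quantile (``value`` in (0,1)).
    """

    method: Literal["fixed", "otsu", "quantile"]
    value: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("fixed", "otsu", "quantile"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.method == "fixed":
            if self.value is None or self.value < 0:
                raise ValueError("fixed policy requires value >= 0")
        if self.method == "quantile":
            if self.value is None or not (0 < self.value < 1):
                raise ValueError("quantile policy requires value in (0, 1)")

    @staticmethod
    def from_dict(d: dict) -> "ThresholdPolicy":
        return ThresholdPolicy(method=d["method"], value=d.get("value"))
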