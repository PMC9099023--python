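"""ROI densitometry of grayscale image planes.

Staining intensity is quantified as the mean gray value of a region of
interest (a drawn cell-body mask or a projection-field rectangle, e.g.
275 x 180 um in the dorsal protocerebrum) minus the mean of a nearby
background rectangle (20 x 20 um) placed outside the stained structures.
Per-brain values average the two hemispheres.  Rectangles are specified in
micrometres and converted to pixels half-open (floor of the start edge,
ceil of the end edge); sub-pixel edges are not interpolated.  Negative
background-corrected values are kept (clamping would bias group means) but
flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImagePlane",
    "RectangleROI",
    "MaskROI",
    "IntensityResult",
    "roi_mean",
    "corrected_intensity",
    "brain_intensity",
]


@dataclass
class ImagePlane:
    """A merged grayscale confocal plane with its pixel scale."""

    pixels: np.ndarray
    scale_um_per_px: float
    sample_id: str = ""
    hemisphere: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("image must be 2-D grayscale")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")
        if self.scale_um_per_px <= 0:
            raise ValueError("scale must be positive")


@dataclass(frozen=True)
class RectangleROI:
    """Axis-aligned rectangle in micrometres: origin (x, y) and size."""

    x_um: float
    y_um: float
    width_um: float
    height_um: float
    role: str = "projection_field"

    def to_slices(self, scale_um_per_px: float) -> tuple[slice, slice]:
        x0 = math.floor(self.x_um / scale_um_per_px)
        y0 = math.floor(self.y_um / scale_um_per_px)
        x1 = math.ceil((self.x_um + self.width_um) / scale_um_per_px)
        y1 = math.ceil((self.y_um + self.height_um) / scale_um_per_px)
        return slice(y0, y1), slice(x0, x1)


@dataclass
class MaskROI:
    """Free-form ROI as a boolean pixel mask (drawn cell-body outline or a
    simulator ground-truth mask)."""

    mask: np.ndarray
    role: str = "cell_body"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("empty ROI mask")


def _roi_pixels(image: ImagePlane, roi) -> np.ndarray:
    if isinstance(roi, RectangleROI):
        ys, xs = roi.to_slices(image.scale_um_per_px)
        h, w = image.pixels.shape
        if ys.start < 0 or xs.start < 0 or ys.stop > h or xs.stop > w:
            raise ValueError("ROI extends outside the image")
        return image.pixels[ys, xs].ravel()
    if isinstance(roi, MaskROI):
        if roi.mask.shape != image.pixels.shape:
            raise ValueError("mask shape does not match image")
        return image.pixels[roi.mask]
    raise TypeError(f"unsupported ROI type {type(roi).__name__}")


def roi_mean(image: ImagePlane, roi) -> float:
    """Arithmetic mean gray value of the pixels under the ROI."""
    return float(_roi_pixels(image, roi).mean())


def _overlap(image: ImagePlane, a, b) -> bool:
    def as_mask(roi):
        m = np.zeros(image.pixels.shape, dtype=bool)
        if isinstance(roi, RectangleROI):
            ys, xs = roi.to_slices(image.scale_um_per_px)
            m[ys, xs] = True
        else:
            m |= roi.mask
        return m

    return bool((as_mask(a) & as_mask(b)).any())


@dataclass
class IntensityResult:
    """Background-corrected ROI intensity of one hemisphere."""

    raw_mean: float
    background_mean: float
    sample_id: str = ""
    hemisphere: str = ""
    negative_flag: bool = False

    @property
    def corrected(self) -> float:
        return self.raw_mean - self.background_mean


def corrected_intensity(image: ImagePlane, signal_roi, background_roi) -> IntensityResult:
    """Mean(signal ROI) - mean(background ROI); the ROIs must be disjoint."""
    if _overlap(image, signal_roi, background_roi):
        raise ValueError("signal and background ROIs overlap")
    raw = roi_mean(image, signal_roi)
    bg = roi_mean(image, background_roi)
    return IntensityResult(
        raw_mean=raw,
        background_mean=bg,
        sample_id=image.sample_id,
        hemisphere=image.hemisphere,
        negative_flag=raw < bg,
    )


def brain_intensity(
    left: IntensityResult | None, right: IntensityResult | None
) -> tuple[float, bool]:
    """Per-brain staining intensity: mean of both hemispheres' corrected
    values.  With one hemisphere missing, returns the present one with the
    single-hemisphere flag set."""
    if left is None and right is None:
        raise ValueError("no hemisphere measurements")
    if left is None or right is None:
        present = left if left is not None else right
        return float(present.corrected), True
    return float((left.corrected + right.corrected) / 2.0), False
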