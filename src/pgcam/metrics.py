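"""Background-image subtraction and the pixel-value-ratio (PVR) contrast.

Two reference acquisitions serve as image-domain backgrounds for a target
run: the graphite-scatterer run (subtracted image "SIwG") and the no-target
run ("SIwoT").  Subtraction is pixel-by-pixel without exposure normalisation
(equal-exposure acquisitions); an optional scale accommodates unequal ones.

PVR is the mean pixel value inside the target region of interest divided by
the mean over all other pixels, computed after clipping negative pixels to
zero.  Pixels belong to the ROI when their centers fall inside it
(half-open on the high edges).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reconstruction import ImageGrid, PlaneImage
from .scenes import Scene

__all__ = ["ROI", "PVRResult", "subtract_images", "pvr", "target_roi"]


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangle on the image plane, mm."""

    x_lo: float
    x_hi: float
    y_lo: float
    y_hi: float

    def __post_init__(self) -> None:
        if self.x_lo >= self.x_hi or self.y_lo >= self.y_hi:
            raise ValueError("ROI must have positive extent")

    def mask(self, grid: ImageGrid) -> np.ndarray:
        """(ny, nx) boolean mask of pixel centers inside the ROI."""
        x = grid.x_centers
        y = grid.y_centers
        mx = (x >= self.x_lo) & (x < self.x_hi)
        my = (y >= self.y_lo) & (y < self.y_hi)
        m = np.outer(my, mx)
        if not m.any():
            raise ValueError("ROI does not intersect the image grid")
        return m


@dataclass
class PVRResult:
    pvr: float
    mean_in: float
    mean_out: float
    n_clipped: int
    undefined: bool  # mean_out == 0

    def as_dict(self) -> dict:
        return {
            "pvr": self.pvr,
            "mean_in": self.mean_in,
            "mean_out": self.mean_out,
            "n_clipped": self.n_clipped,
            "undefined": self.undefined,
        }


def subtract_images(
    target_img: PlaneImage, background_img: PlaneImage, scale: float = 1.0
) -> PlaneImage:
    """Pixel-by-pixel ``target - scale * background``; negatives preserved.

    Clipping of negative pixels happens only inside :func:`pvr`.
    """
    if target_img.grid != background_img.grid:
        raise ValueError("images must share an identical grid")
    return PlaneImage(
        grid=target_img.grid,
        values=target_img.values - scale * background_img.values,
        provenance="subtracted",
    )


def pvr(img: PlaneImage, roi: ROI) -> PVRResult:
    """Pixel-value ratio of ROI mean over outside mean, negatives clipped."""
    m = roi.mask(img.grid)
    v = img.values
    n_clipped = int((v < 0).sum())
    v = np.clip(v, 0.0, None)
    mean_in = float(v[m].mean())
    mean_out = float(v[~m].mean())
    if mean_out == 0.0:
        return PVRResult(np.nan, mean_in, mean_out, n_clipped, undefined=True)
    return PVRResult(mean_in / mean_out, mean_in, mean_out, n_clipped, undefined=False)


def target_roi(scene: Scene, grid: ImageGrid | None = None) -> ROI:
    """ROI covering the lateral footprint of the scene's PG target.

    A cylinder maps to the square of side 2r around its center; a box slab
    to its lateral half-sizes.  Raises ``KeyError`` when the scene has no
    ``PG_target`` component.
    """
    comp = scene.component("PG_target")
    sp = comp.spatial
    cx, cy = sp.center[0], sp.center[1]
    if sp.kind == "cylinder":
        hx = hy = sp.radius
    elif sp.kind == "box":
        hx, hy = sp.half_sizes[0], sp.half_sizes[1]
    elif sp.kind == "point":
        hx = hy = 5.0
    else:
        raise ValueError(f"cannot project spatial kind {sp.kind!r} to an ROI")
    return ROI(x_lo=cx - hx, x_hi=cx + hx, y_lo=cy - hy, y_hi=cy + hy)
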