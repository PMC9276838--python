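"""Level-set segmentation of ablation boundaries in grayscale slice scans.

Sectioned agar phantoms are scanned flat-bed and converted to grayscale;
the thermally denatured (opaque-white) region is brighter than the
surrounding agar.  A region-based level set (morphological Chan-Vese),
initialised from an automatic intensity threshold, recovers the ablation
boundary; the final contour is extracted at sub-pixel positions and
returned in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage import filters, measure, segmentation
from scipy import ndimage


class SegmentationError(RuntimeError):
    pass


@dataclass
class SliceScan:
    """2D grayscale section with isotropic pixel spacing (mm/px)."""

    image: np.ndarray
    pixel_spacing: float
    plane: str = "coronal"        # or "axial"

    def __post_init__(self):
        self.image = np.asarray(self.image, float)
        if self.image.ndim != 2:
            raise ValueError("slice scan must be a 2D grayscale image")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel spacing must be positive")


@dataclass
class TrueBoundary:
    """Closed boundary of a "true" ablation region.

    2D: ``contour`` is an (n, 2) closed polyline in mm (x, y image axes).
    Also records the enclosed area for convenience.
    """

    contour: np.ndarray
    area_mm2: float
    level_set: Optional[np.ndarray] = None


def segment_boundary(scan: SliceScan, *, n_iterations: int = 60,
                     smoothing: int = 2) -> TrueBoundary:
    """Segment the bright (denatured) region of a slice scan.

    Otsu thresholding provides the initial region; morphological Chan-Vese
    evolves it to the intensity-homogeneity optimum; the largest connected
    region's boundary is returned as a closed sub-pixel contour in mm.
    """
    img = scan.image
    if img.max() <= img.min():
        raise SegmentationError("image has no contrast; nothing to segment")
    thr = filters.threshold_otsu(img)
    init = img > thr
    if not init.any() or init.all():
        raise SegmentationError("no foreground region distinguishable")
    ls = segmentation.morphological_chan_vese(
        img, num_iter=n_iterations, init_level_set=init, smoothing=smoothing)
    if not ls.any():
        raise SegmentationError("level set collapsed; no region found")
    # keep the largest connected region, fill holes
    labels, n = ndimage.label(ls)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        ls = labels == (1 + int(np.argmax(sizes)))
    ls = ndimage.binary_fill_holes(ls)

    # sub-pixel contour: marching squares on a lightly smoothed indicator
    smooth = ndimage.gaussian_filter(ls.astype(float), 1.0)
    contours = measure.find_contours(smooth, 0.5)
    if not contours:
        raise SegmentationError("no closed contour found")
    contour = max(contours, key=len)           # (row, col) pixel coords
    xy = contour[:, ::-1] * scan.pixel_spacing  # -> (x, y) mm
    area = _polygon_area(xy)
    return TrueBoundary(contour=xy, area_mm2=area, level_set=ls)


def _polygon_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)
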