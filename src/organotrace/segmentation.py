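"""Classical organoid segmentation: smooth, threshold, clean, label.

A deterministic, dependency-light surrogate for the interactive
AI-assisted segmentation used with commercial microscopy suites.  The
downstream statistic of interest is the shift between widefield and
cleared morphometrics, so the same parameters must be applied to both
images of a pair; this module is deliberately parameter-for-parameter
reproducible.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .frames import DomainError, ImageFrame
from .filters import gaussian_smooth

logger = logging.getLogger(__name__)

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class SegmentationParams:
    presmooth_sigma: float = 4.0  # µm
    threshold_mode: str = "auto_otsu"  # or "manual"
    manual_threshold: float | None = None  # counts, used iff manual
    fill_holes: bool = True  # organoid lumens count toward area
    opening_radius: float = 6.0  # µm
    min_object_area: float = 5000.0  # µm²; rejects debris far below organoid size

    def __post_init__(self) -> None:
        if self.presmooth_sigma < 0:
            raise DomainError("presmooth_sigma must be >= 0")
        if self.min_object_area < 0:
            raise DomainError("min_object_area must be >= 0")
        if self.threshold_mode not in ("auto_otsu", "manual"):
            raise DomainError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "manual":
            if self.manual_threshold is None or not math.isfinite(self.manual_threshold):
                raise DomainError("manual threshold_mode requires a finite manual_threshold")


@dataclass
class LabelMap:
    """Integer-labelled segmentation (0 = background, 1..n_objects)."""

    label_grid: np.ndarray
    pixel_size: float
    n_objects: int

    def __post_init__(self) -> None:
        self.label_grid = np.asarray(self.label_grid, dtype=np.int32)
        if self.label_grid.ndim != 2:
            raise DomainError("label_grid must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_grid.shape  # type: ignore[return-value]


def segment(image: ImageFrame, params: SegmentationParams | None = None) -> LabelMap:
    """Smooth → threshold → fill holes → open → 8-connected label → area filter.

    A blank image (all pixels equal) under automatic thresholding yields
    an empty LabelMap with a logged warning rather than an exception.
    """
    params = params or SegmentationParams()
    data = image.as_float()
    if np.min(data) < 0:
        raise DomainError("input image must be non-negative")
    ps = image.pixel_size

    smoothed = gaussian_smooth(data, params.presmooth_sigma / ps) if params.presmooth_sigma > 0 else data

    if params.threshold_mode == "manual":
        threshold = float(params.manual_threshold)  # type: ignore[arg-type]
    else:
        if np.ptp(smoothed) == 0:
            logger.warning("blank image (all pixels equal); returning empty segmentation")
            return LabelMap(np.zeros(image.shape, dtype=np.int32), ps, 0)
        threshold = float(threshold_otsu(smoothed))

    mask = smoothed > threshold
    if params.fill_holes:
        mask = ndi.binary_fill_holes(mask)
    radius_px = int(round(params.opening_radius / ps))
    if radius_px >= 1:
        mask = ndi.binary_opening(mask, structure=disk(radius_px))

    labels, n_raw = ndi.label(mask, structure=_EIGHT_CONNECTED)
    if n_raw == 0:
        return LabelMap(np.zeros(image.shape, dtype=np.int32), ps, 0)

    counts = np.bincount(labels.ravel(), minlength=n_raw + 1)
    keep = np.flatnonzero(counts[1:] * ps * ps >= params.min_object_area) + 1
    mapping = np.zeros(n_raw + 1, dtype=np.int32)
    mapping[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return LabelMap(mapping[labels], ps, int(keep.size))


def object_mask(labels: LabelMap, object_id: int) -> np.ndarray:
    """Binary mask of exactly the pixels carrying ``object_id``."""
    if not 1 <= object_id <= labels.n_objects:
        raise LookupError(
            f"object id {object_id} outside the labelled range 1..{labels.n_objects}"
        )
    return labels.label_grid == object_id


def labelmap_from_masks(masks: list[np.ndarray], pixel_size: float) -> LabelMap:
    """Build a LabelMap from disjoint binary masks (e.g. generator truth)."""
    if not masks:
        raise DomainError("at least one mask is required")
    grid = np.zeros(masks[0].shape, dtype=np.int32)
    for i, mask in enumerate(masks, start=1):
        grid[np.asarray(mask, dtype=bool)] = i
    return LabelMap(grid, pixel_size, len(masks))
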