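"""Calibrated image containers and shared error types.

Coordinate convention used throughout the package: pixel indices are
0-based ``(row, col)``; physical coordinates are in micrometres with the
origin at the centre of the top-left pixel, ``x`` increasing with column
and ``y`` increasing with row.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class CalibrationError(ValueError):
    """Missing or inconsistent pixel-size calibration."""


class FormatError(ValueError):
    """Image layout or dtype the pipeline does not accept."""


class DomainError(ValueError):
    """Input outside the mathematical domain of an operation."""


@dataclass
class ImageFrame:
    """A single-channel 2D intensity image with a µm/pixel calibration.

    Parameters
    ----------
    data :
        2D array of intensities (any numeric dtype; stored as given).
    pixel_size :
        Physical side length of one pixel in micrometres.
    """

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise FormatError(
                f"expected a single-channel 2D image, got array of shape {self.data.shape}"
            )
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise CalibrationError(f"pixel_size must be a positive finite µm/px value, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def check_same_grid(self, other: "ImageFrame", what: str = "images") -> None:
        """Raise :class:`CalibrationError` unless shapes and pixel sizes match."""
        if self.shape != other.shape:
            raise CalibrationError(f"{what} have mismatched shapes {self.shape} vs {other.shape}")
        if not np.isclose(self.pixel_size, other.pixel_size, rtol=1e-9, atol=0.0):
            raise CalibrationError(
                f"{what} have mismatched pixel sizes {self.pixel_size} vs {other.pixel_size} µm/px"
            )

    def as_float(self) -> np.ndarray:
        """Intensity grid as float64 (copy only when a cast is needed)."""
        return np.asarray(self.data, dtype=np.float64)
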