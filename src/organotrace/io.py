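"""TIFF, CSV, and sidecar I/O with pixel-size calibration.

Images travel as single-channel TIFF (8/16-bit unsigned or 32/64-bit
float).  The pixel size in µm/px is embedded in the TIFF description as
JSON and mirrored in the resolution tags (pixels per micrometre,
resolution unit NONE); on read it is recovered from either, or taken
from an explicit argument.  Tables are plain CSV via pandas.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .frames import CalibrationError, FormatError, ImageFrame
from .morphometrics import PERIMETER_ESTIMATOR, MorphRecord
from .segmentation import LabelMap
from .tracing import CCWFVector

_ACCEPTED_DTYPES = ("uint8", "uint16", "float32", "float64")


def write_image(frame: ImageFrame, path: str | Path) -> None:
    """Write a frame losslessly at its current dtype with calibration."""
    data = frame.data
    if data.dtype.name not in _ACCEPTED_DTYPES:
        data = data.astype(np.float32)
    tifffile.imwrite(
        Path(path),
        data,
        resolution=(1.0 / frame.pixel_size, 1.0 / frame.pixel_size),
        resolutionunit="NONE",
        description=json.dumps({"pixel_size_um": frame.pixel_size}),
    )


def read_image(path: str | Path, pixel_size: float | None = None) -> ImageFrame:
    """Read a single-channel TIFF; errors on multi-channel/RGB layouts.

    The calibration comes from the explicit argument, the JSON
    description, or the resolution tags, in that order of preference.
    """
    with tifffile.TiffFile(Path(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise FormatError(
                f"expected a single-channel image, found shape {data.shape} "
                f"(multi-channel/RGB layout)"
            )
        if pixel_size is None:
            desc = page.tags.get("ImageDescription")
            if desc is not None:
                try:
                    meta = json.loads(desc.value)
                    pixel_size = float(meta["pixel_size_um"])
                except (ValueError, KeyError, TypeError):
                    pixel_size = None
            if pixel_size is None:
                xres = page.tags.get("XResolution")
                # (1, 1) is tifffile's uncalibrated default, not a real
                # 1 µm/px calibration; our writer stores the true value in
                # the JSON description above
                if xres is not None and xres.value != (1, 1):
                    num, den = xres.value
                    if num > 0:
                        pixel_size = den / num
    if pixel_size is None:
        raise CalibrationError(
            f"{path}: no pixel-size calibration found; pass pixel_size explicitly"
        )
    return ImageFrame(data, float(pixel_size))


def quantize_uint16(frame: ImageFrame, max_value: float | None = None) -> ImageFrame:
    """Scale a float frame to the full 16-bit range (for WF exports)."""
    data = frame.as_float()
    top = float(np.max(data)) if max_value is None else float(max_value)
    if top <= 0:
        top = 1.0
    scaled = np.clip(data / top * 65535.0, 0.0, 65535.0).astype(np.uint16)
    return ImageFrame(scaled, frame.pixel_size)


def write_labels(labels: LabelMap, path: str | Path) -> None:
    if labels.n_objects > 65535:
        raise FormatError("more than 65535 objects cannot be stored as uint16")
    write_image(ImageFrame(labels.label_grid.astype(np.uint16), labels.pixel_size), path)


def read_labels(path: str | Path, pixel_size: float | None = None) -> LabelMap:
    frame = read_image(path, pixel_size)
    grid = frame.data.astype(np.int32)
    return LabelMap(grid, frame.pixel_size, int(grid.max()))


# --- sidecar metadata (flat key=value text) --------------------------------


def write_sidecar(path: str | Path, entries: dict) -> None:
    lines = [f"{k} = {v}" for k, v in entries.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_sidecar(path: str | Path) -> dict[str, str]:
    entries: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, value = line.split("=", 1)
        entries[key.strip()] = value.strip()
    return entries


# --- tables ----------------------------------------------------------------


def morph_to_frame(records: list[MorphRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "object_id": [r.object_id for r in records],
            "source": [r.source for r in records],
            "area_um2": [r.area for r in records],
            "perimeter_um": [r.perimeter for r in records],
            "circularity": [r.circularity for r in records],
            "centroid_x_um": [r.centroid[0] for r in records],
            "centroid_y_um": [r.centroid[1] for r in records],
            "perimeter_estimator": [PERIMETER_ESTIMATOR] * len(records),
        }
    )


def vectors_to_frame(vectors: list[CCWFVector]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "wf_id": [v.wf_id for v in vectors],
            "cc_id": [v.cc_id for v in vectors],
            "iou": [v.iou for v in vectors],
            "d_area_um2": [v.d_area for v in vectors],
            "d_perimeter_um": [v.d_perimeter for v in vectors],
            "d_circularity": [v.d_circularity for v in vectors],
            "abs_d_area_um2": [v.abs_d_area for v in vectors],
            "abs_d_perimeter_um": [v.abs_d_perimeter for v in vectors],
            "abs_d_circularity": [v.abs_d_circularity for v in vectors],
            "std_magnitude": [v.standardized_magnitude for v in vectors],
            "condition": [v.condition for v in vectors],
        }
    )
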