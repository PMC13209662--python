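"""CC−WF shift vectors: the differential morphometric statistic.

An organoid is measured twice — on the widefield (WF) image and on its
computationally cleared (CC) counterpart.  For intact organoids, whose
signal is sharp and specific, clearing barely moves the segmented shape,
so the (Δarea, Δperimeter, Δcircularity) displacement stays near the
origin.  Injured organoids, whose diffuse signal is dominated by haze,
shift substantially.  The per-component absolute shift is the injury
score; a combined score robust-standardizes the three incommensurate
components (median / 1.4826·MAD) before taking the Euclidean norm.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .frames import CalibrationError, DomainError
from .morphometrics import MorphRecord
from .segmentation import LabelMap

logger = logging.getLogger(__name__)

COMPONENTS = ("area", "perimeter", "circularity")
MAD_SCALE = 1.4826  # MAD → sigma for a normal distribution


class ConsistencyError(ValueError):
    """A paired object id has no morphometric record."""


@dataclass
class ObjectPairing:
    """Greedy IoU matching between WF and CC label maps."""

    pairs: list[tuple[int, int, float]]  # (wf_id, cc_id, IoU)
    unmatched_wf: list[int]
    unmatched_cc: list[int]
    min_iou: float


@dataclass
class StandardizationStats:
    """Per-component location/scale used before combining shifts.

    Location is the cohort median of each absolute shift; scale is
    1.4826·MAD, falling back to the SD when the MAD is zero and to 1
    when both vanish.
    """

    location: np.ndarray  # (3,)
    scale: np.ndarray  # (3,)
    components: tuple[str, ...] = COMPONENTS
    method: str = "median/MAD"

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=np.float64)
        self.scale = np.asarray(self.scale, dtype=np.float64)
        if np.any(self.scale <= 0):
            raise DomainError("standardization scales must be positive")


@dataclass
class CCWFVector:
    """Per-object displacement from the WF point to the CC point."""

    wf_id: int
    cc_id: int
    d_area: float  # µm², CC − WF
    d_perimeter: float  # µm, CC − WF
    d_circularity: float
    abs_d_area: float = field(init=False)
    abs_d_perimeter: float = field(init=False)
    abs_d_circularity: float = field(init=False)
    standardized_magnitude: float | None = None
    condition: str | None = None
    iou: float | None = None

    def __post_init__(self) -> None:
        self.abs_d_area = abs(self.d_area)
        self.abs_d_perimeter = abs(self.d_perimeter)
        self.abs_d_circularity = abs(self.d_circularity)


def pair_objects(wf_labels: LabelMap, cc_labels: LabelMap, min_iou: float = 0.3) -> ObjectPairing:
    """Match WF objects to CC objects greedily by descending IoU.

    Ties are broken by smaller centroid distance, then smaller wf_id;
    candidate pairs below ``min_iou`` are rejected.  Unmatched objects
    on either side are listed (and logged) rather than silently dropped.
    """
    if wf_labels.shape != cc_labels.shape:
        raise CalibrationError(
            f"label maps have mismatched shapes {wf_labels.shape} vs {cc_labels.shape}"
        )
    if not np.isclose(wf_labels.pixel_size, cc_labels.pixel_size, rtol=1e-9, atol=0.0):
        raise CalibrationError("label maps have mismatched pixel sizes")

    nw, nc = wf_labels.n_objects, cc_labels.n_objects
    wf_grid = wf_labels.label_grid.astype(np.int64)
    cc_grid = cc_labels.label_grid.astype(np.int64)
    joint = wf_grid * (nc + 1) + cc_grid
    counts = np.bincount(joint.ravel(), minlength=(nw + 1) * (nc + 1))
    overlap = counts.reshape(nw + 1, nc + 1).astype(np.float64)
    wf_areas = overlap.sum(axis=1)
    cc_areas = overlap.sum(axis=0)

    wf_cent = ndi.center_of_mass(np.ones_like(wf_grid), wf_grid, range(1, nw + 1)) if nw else []
    cc_cent = ndi.center_of_mass(np.ones_like(cc_grid), cc_grid, range(1, nc + 1)) if nc else []

    candidates = []
    for i in range(1, nw + 1):
        for j in range(1, nc + 1):
            inter = overlap[i, j]
            if inter == 0:
                continue
            iou = inter / (wf_areas[i] + cc_areas[j] - inter)
            if iou >= min_iou:
                dy = wf_cent[i - 1][0] - cc_cent[j - 1][0]
                dx = wf_cent[i - 1][1] - cc_cent[j - 1][1]
                candidates.append((i, j, float(iou), float(np.hypot(dx, dy))))
    candidates.sort(key=lambda c: (-c[2], c[3], c[0], c[1]))

    used_wf: set[int] = set()
    used_cc: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for i, j, iou, _dist in candidates:
        if i in used_wf or j in used_cc:
            continue
        pairs.append((i, j, iou))
        used_wf.add(i)
        used_cc.add(j)

    unmatched_wf = [i for i in range(1, nw + 1) if i not in used_wf]
    unmatched_cc = [j for j in range(1, nc + 1) if j not in used_cc]
    if unmatched_wf or unmatched_cc:
        logger.info(
            "pairing left %d WF and %d CC objects unmatched (min_iou=%.2f)",
            len(unmatched_wf), len(unmatched_cc), min_iou,
        )
    return ObjectPairing(pairs, unmatched_wf, unmatched_cc, min_iou)


def fit_standardization(abs_shifts: np.ndarray) -> StandardizationStats:
    """Robust per-component location/scale from an (n, 3) absolute-shift matrix."""
    abs_shifts = np.asarray(abs_shifts, dtype=np.float64).reshape(-1, len(COMPONENTS))
    if abs_shifts.shape[0] == 0:
        raise DomainError("cannot fit standardization on an empty cohort")
    location = np.median(abs_shifts, axis=0)
    mad = np.median(np.abs(abs_shifts - location), axis=0) * MAD_SCALE
    sd = np.std(abs_shifts, axis=0)
    scale = np.where(mad > 0, mad, np.where(sd > 0, sd, 1.0))
    return StandardizationStats(location=location, scale=scale)


def ccwf_vectors(wf_records: list[MorphRecord], cc_records: list[MorphRecord],
                 pairing: ObjectPairing,
                 stats: StandardizationStats | None = None) -> list[CCWFVector]:
    """Component-wise CC − WF differences for every matched pair.

    When ``stats`` is omitted, standardization statistics are fitted on
    the cohort formed by the pairs themselves.
    """
    wf_by_id = {r.object_id: r for r in wf_records}
    cc_by_id = {r.object_id: r for r in cc_records}
    vectors: list[CCWFVector] = []
    for wf_id, cc_id, iou in pairing.pairs:
        if wf_id not in wf_by_id:
            raise ConsistencyError(f"no WF morphometric record for paired object {wf_id}")
        if cc_id not in cc_by_id:
            raise ConsistencyError(f"no CC morphometric record for paired object {cc_id}")
        w, c = wf_by_id[wf_id], cc_by_id[cc_id]
        vectors.append(
            CCWFVector(
                wf_id=wf_id,
                cc_id=cc_id,
                d_area=c.area - w.area,
                d_perimeter=c.perimeter - w.perimeter,
                d_circularity=c.circularity - w.circularity,
                iou=iou,
            )
        )
    if vectors:
        apply_standardization(vectors, stats)
    return vectors


def apply_standardization(vectors: list[CCWFVector],
                          stats: StandardizationStats | None = None) -> StandardizationStats:
    """Fill ``standardized_magnitude`` in place; returns the stats used."""
    if not vectors:
        raise DomainError("no vectors to standardize")
    abs_matrix = np.array(
        [[v.abs_d_area, v.abs_d_perimeter, v.abs_d_circularity] for v in vectors]
    )
    if stats is None:
        stats = fit_standardization(abs_matrix)
    z = (abs_matrix - stats.location) / stats.scale
    magnitudes = np.linalg.norm(z, axis=1)
    for v, m in zip(vectors, magnitudes):
        v.standardized_magnitude = float(m)
    return stats


def shift_scores(vectors: list[CCWFVector], component: str = "circularity"
                 ) -> list[tuple[tuple[int, int], float]]:
    """Injury score per pair: an absolute shift, or the combined magnitude."""
    if not vectors:
        raise DomainError("shift_scores requires at least one vector")
    if component == "combined":
        if any(v.standardized_magnitude is None for v in vectors):
            raise DomainError("combined scores require standardized magnitudes")
        return [((v.wf_id, v.cc_id), float(v.standardized_magnitude)) for v in vectors]
    attr = {
        "area": "abs_d_area",
        "perimeter": "abs_d_perimeter",
        "circularity": "abs_d_circularity",
    }.get(component)
    if attr is None:
        raise DomainError(f"unknown component {component!r}")
    return [((v.wf_id, v.cc_id), float(getattr(v, attr))) for v in vectors]
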