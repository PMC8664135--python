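"""Automatic hot-slice selection and 40-mm ROI generation.

The single analysis slice is the transaxial section holding the global
maximum voxel (the hottest cylinder).  Eight 40-mm circular ROIs are then
placed on it: the four hot and three cold inserts on their ring, located by
rotating away from the detected hottest-insert position by the predetermined
inter-insert angles of the phantom layout, plus one background ROI at the
phantom center.  Hot-insert ROIs are re-centered on their actual local
maximum; the 8-mm ROI may need a manual override when noise dominates, which
is tracked via the ``manually_placed`` flag (a manually placed ROI is fitted
about its geometric center downstream, not a local maximum).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import LocalizationError, PhantomVolume
from .simulate import PhantomGeometry

logger = logging.getLogger("petqa")

ROI_DIAMETER_MM = 40.0
BACKGROUND_LABEL = "background"

__all__ = [
    "ROISpec",
    "ROISample",
    "find_hot_slice",
    "phantom_center",
    "generate_rois",
    "recenter_roi",
    "override_roi",
    "extract_samples",
    "save_roi_set",
    "load_roi_set",
]


@dataclass
class ROISpec:
    """One circular 2D ROI: center in pixel coordinates plus its role label."""

    center: tuple  # (row, col), floats allowed
    label: str
    diameter_mm: float = ROI_DIAMETER_MM
    manually_placed: bool = False

    def radius_px(self, pixel_size_mm: float) -> float:
        return self.diameter_mm / 2.0 / pixel_size_mm


@dataclass
class ROISample:
    """Voxel values of one ROI with per-value pixel offsets from its center."""

    spec: ROISpec
    values: np.ndarray
    offsets: np.ndarray  # (n, 2) of (drow, dcol) in pixels
    pixel_size_mm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if len(self.values) != len(self.offsets):
            raise ValueError("values and offsets must align")

    @property
    def n(self) -> int:
        return len(self.values)


def find_hot_slice(vol: PhantomVolume) -> int:
    """Index of the slice containing the global maximum voxel.

    Ties break toward the lower slice index (first occurrence in C order).
    """
    flat = int(np.argmax(vol.voxels))
    return int(np.unravel_index(flat, vol.voxels.shape)[0])


def phantom_center(slice2d: np.ndarray, support_fraction: float = 0.25):
    """Centroid of the phantom support (threshold mask, holes filled).

    Cold inserts punch holes in the thresholded bath; filling them keeps the
    centroid from being biased toward the hot side of the ring.
    """
    mask = slice2d > support_fraction * float(slice2d.max())
    labeled, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labeled, index=range(1, n + 1))
        mask = labeled == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    rows, cols = np.nonzero(mask)
    return float(rows.mean()), float(cols.mean())


def generate_rois(
    slice2d: np.ndarray,
    geometry: PhantomGeometry,
    pixel_size_mm: float,
) -> list[ROISpec]:
    """Place the eight 40-mm ROIs on the hot slice.

    The global maximum is assumed to sit in the hottest (25-mm) cylinder; the
    remaining inserts follow from the configured ring order by rotating the
    detected anchor angle by the predetermined angular offsets.  The
    background ROI sits at the phantom centroid.
    """
    nrow, ncol = slice2d.shape
    mrow, mcol = np.unravel_index(int(np.argmax(slice2d)), slice2d.shape)
    if mrow in (0, nrow - 1) or mcol in (0, ncol - 1):
        raise LocalizationError("global maximum on the image border; phantom truncated?")

    crow, ccol = phantom_center(slice2d)
    anchor = math.atan2(-(mrow - crow), mcol - ccol)  # image rows point down

    inserts = geometry.inserts()
    anchor_deg = math.degrees(anchor)
    a0 = geometry.hot_angles_deg[0]  # configured angle of the hottest insert
    ring_px = geometry.insert_ring_radius_mm / pixel_size_mm

    rois = []
    for lab, _d, ang in inserts:
        theta = math.radians(anchor_deg + (ang - a0))
        row = crow - ring_px * math.sin(theta)
        col = ccol + ring_px * math.cos(theta)
        rois.append(ROISpec(center=(row, col), label=lab))
    rois.append(ROISpec(center=(crow, ccol), label=BACKGROUND_LABEL))

    r_roi = ROI_DIAMETER_MM / 2.0 / pixel_size_mm
    for roi in rois:
        r, c = roi.center
        if r - r_roi < -0.5 or c - r_roi < -0.5 or r + r_roi > nrow - 0.5 or c + r_roi > ncol - 0.5:
            raise LocalizationError(f"ROI {roi.label} falls outside the image")
    return rois


def _footprint(slice2d, center, radius_px):
    """Pixel coordinates strictly inside the circle (pixel-center rule)."""
    nrow, ncol = slice2d.shape
    r0 = max(0, int(math.floor(center[0] - radius_px)))
    r1 = min(nrow - 1, int(math.ceil(center[0] + radius_px)))
    c0 = max(0, int(math.floor(center[1] - radius_px)))
    c1 = min(ncol - 1, int(math.ceil(center[1] + radius_px)))
    rows = np.arange(r0, r1 + 1)
    cols = np.arange(c0, c1 + 1)
    dr = rows[:, None] - center[0]
    dc = cols[None, :] - center[1]
    inside = (dr * dr + dc * dc) < radius_px * radius_px
    rr, cc = np.nonzero(inside)
    return rows[rr], cols[cc]


def recenter_roi(
    slice2d: np.ndarray,
    roi: ROISpec,
    pixel_size_mm: float,
    search_radius_mm: float | None = None,
) -> ROISpec:
    """Move a hot-insert ROI center onto the maximum voxel within its
    footprint, capped at ``search_radius_mm`` (default: the ROI radius).

    Ties go to the lowest (row, col) in lexicographic order.  A maximum on
    the footprint rim is accepted but logged as a likely mislocalization.
    """
    radius_px = roi.radius_px(pixel_size_mm)
    rows, cols = _footprint(slice2d, roi.center, radius_px)
    if rows.size == 0:
        return roi
    values = slice2d[rows, cols]
    k = int(np.lexsort((cols, rows, -values))[0]) if rows.size > 1 else 0
    # lexsort orders by -value first, then row, then col -> lexicographic ties
    new = (float(rows[k]), float(cols[k]))

    cap_px = (
        radius_px if search_radius_mm is None else search_radius_mm / pixel_size_mm
    )
    dr, dc = new[0] - roi.center[0], new[1] - roi.center[1]
    dist = math.hypot(dr, dc)
    if dist > cap_px and dist > 0:
        scale = cap_px / dist
        new = (roi.center[0] + dr * scale, roi.center[1] + dc * scale)
    if dist >= radius_px - 1.0:
        logger.warning(
            "ROI %s recentered onto its rim (moved %.1f px); possible "
            "mislocalization", roi.label, dist,
        )
    return replace(roi, center=new)


def override_roi(
    roi: ROISpec,
    new_center: tuple,
    slice2d: np.ndarray | None = None,
) -> ROISpec:
    """Manually re-place an ROI.  Sets ``manually_placed`` even for an
    identity move, switching downstream fitting to the geometric center."""
    if slice2d is not None:
        nrow, ncol = slice2d.shape
        r, c = new_center
        if not (0 <= r < nrow and 0 <= c < ncol):
            raise LocalizationError("override center outside the image")
        if slice2d[int(round(r)), int(round(c))] <= 0.05 * float(slice2d.max()):
            logger.warning("override center for %s appears outside the phantom", roi.label)
    return replace(roi, center=tuple(float(x) for x in new_center), manually_placed=True)


def extract_samples(
    slice2d: np.ndarray,
    roi: ROISpec,
    pixel_size_mm: float,
) -> ROISample:
    """Tabulate all pixels whose centers fall strictly inside the ROI circle.

    The sample count depends only on the ROI diameter, pixel size and the
    sub-pixel center position — never on image content.
    """
    radius_px = roi.radius_px(pixel_size_mm)
    rows, cols = _footprint(slice2d, roi.center, radius_px)
    if rows.size == 0:
        raise LocalizationError(f"ROI {roi.label} contains no pixels")
    offsets = np.stack([rows - roi.center[0], cols - roi.center[1]], axis=1)
    return ROISample(
        spec=roi,
        values=slice2d[rows, cols],
        offsets=offsets,
        pixel_size_mm=pixel_size_mm,
    )


# ---------------------------------------------------------------------------
# JSON sidecar
# ---------------------------------------------------------------------------

def save_roi_set(rois, path) -> Path:
    records = [
        {
            "label": r.label,
            "center": [float(r.center[0]), float(r.center[1])],
            "diameter_mm": r.diameter_mm,
            "manually_placed": r.manually_placed,
        }
        for r in rois
    ]
    Path(path).write_text(json.dumps(records, indent=1))
    return Path(path)


def load_roi_set(path) -> list[ROISpec]:
    records = json.loads(Path(path).read_text())
    return [
        ROISpec(
            center=tuple(rec["center"]),
            label=rec["label"],
            diameter_mm=float(rec.get("diameter_mm", ROI_DIAMETER_MM)),
            manually_placed=bool(rec.get("manually_placed", False)),
        )
        for rec in records
    ]
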