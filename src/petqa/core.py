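"""Volume container, readers/writers, normalization and display conventions.

A reconstructed PET QA phantom scan is held as a :class:`PhantomVolume`: a 3D
grid of non-negative voxel counts ordered (slice, row, col) together with its
pixel geometry.  Two normalization conventions used throughout the pipeline
live here:

* count normalization — the whole 3D volume is scaled by a single factor so
  the global maximum voxel equals 100, which regularizes data across scanners
  while preserving relative noise characteristics (every voxel ratio is
  unchanged);
* display resampling — transaxial sections are summed into ~1-cm slabs and
  magnified so the phantom outline spans 200 of 256 pixels.  This 256/200
  representation is for report images only; all analysis metrics are computed
  on the native reconstructed grid.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

logger = logging.getLogger("petqa")

NORMALIZED_MAX = 100.0
DISPLAY_GRID = 256
DISPLAY_PHANTOM_DIAMETER_PX = 200
SLAB_THICKNESS_MM = 10.0

__all__ = [
    "PhantomVolume",
    "DisplayImage",
    "PETQAError",
    "LoadError",
    "GeometryError",
    "LocalizationError",
    "load_volume",
    "save_volume",
    "normalize_volume",
    "render_display",
    "save_png",
]


class PETQAError(Exception):
    """Base class for pipeline errors."""


class LoadError(PETQAError):
    """A volume could not be read (missing/heterogeneous slices, bad file)."""


class GeometryError(PETQAError):
    """Phantom geometry is inconsistent (overlapping or out-of-bath inserts)."""


class LocalizationError(PETQAError):
    """Automatic slice/ROI localization failed (e.g. truncated phantom)."""


@dataclass
class PhantomVolume:
    """A reconstructed 3D phantom scan.

    voxels are ordered (slice, row, col); array coordinates are 0-based and
    physical positions refer to pixel centers.
    """

    voxels: np.ndarray
    pixel_size_mm: float
    slice_thickness_mm: float
    normalized: bool = False
    scale_factor: float = 1.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D (slice, row, col) array")
        self.validate()

    def validate(self) -> None:
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("voxel values must be non-negative")
        if self.pixel_size_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("pixel_size_mm and slice_thickness_mm must be positive")
        if self.normalized and abs(float(self.voxels.max()) - NORMALIZED_MAX) > 1e-9:
            raise ValueError("normalized volume must have global max exactly 100")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def get_slice(self, index: int) -> np.ndarray:
        return self.voxels[index]


@dataclass
class DisplayImage:
    """A 256x256 rendered summed slab with the phantom spanning 200 px."""

    pixels: np.ndarray
    slab_thickness_mm: float
    phantom_diameter_px: int = DISPLAY_PHANTOM_DIAMETER_PX

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (DISPLAY_GRID, DISPLAY_GRID):
            raise ValueError("display image must be 256x256")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def save_volume(vol: PhantomVolume, path, metadata: dict | None = None) -> Path:
    """Write the single-file array-container format (.npz + JSON metadata).

    ``metadata`` may carry ground-truth geometry for simulated volumes; it is
    round-tripped verbatim.
    """
    path = Path(path)
    meta = {
        "pixel_size_mm": vol.pixel_size_mm,
        "slice_thickness_mm": vol.slice_thickness_mm,
        "normalized": vol.normalized,
        "scale_factor": vol.scale_factor,
        "source_id": vol.source_id,
    }
    if metadata:
        meta["extra"] = metadata
    np.savez(path, voxels=vol.voxels, meta=np.array(json.dumps(meta)))
    # np.savez appends .npz if missing
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_volume(path, fmt: str | None = None) -> PhantomVolume:
    """Load a volume from a DICOM series directory or an array container file.

    ``fmt`` is ``"dicom-series"`` or ``"array-container"``; inferred from the
    path when omitted (directory -> DICOM series, file -> array container).
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such path: {path}")
    if fmt is None:
        fmt = "dicom-series" if path.is_dir() else "array-container"
    if fmt == "array-container":
        return _load_container(path)
    if fmt == "dicom-series":
        return _load_dicom_series(path)
    raise ValueError(f"unknown format {fmt!r}")


def load_container_metadata(path) -> dict:
    """Return the extra metadata record stored in an array container (or {})."""
    with np.load(Path(path), allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta"]))
    return meta.get("extra", {})


def _load_container(path: Path) -> PhantomVolume:
    try:
        with np.load(path, allow_pickle=False) as npz:
            voxels = npz["voxels"]
            meta = json.loads(str(npz["meta"]))
    except Exception as exc:  # noqa: BLE001 - report the offending file
        raise LoadError(f"cannot read array container {path}: {exc}") from exc
    return PhantomVolume(
        voxels=voxels,
        pixel_size_mm=float(meta["pixel_size_mm"]),
        slice_thickness_mm=float(meta["slice_thickness_mm"]),
        normalized=bool(meta.get("normalized", False)),
        scale_factor=float(meta.get("scale_factor", 1.0)),
        source_id=str(meta.get("source_id", path.stem)),
    )


def _load_dicom_series(path: Path) -> PhantomVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".dcm", ".ima"})
    if not files:
        files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise LoadError(f"no DICOM files found in {path}")

    datasets = []
    for f in files:
        try:
            datasets.append((f, pydicom.dcmread(f)))
        except Exception as exc:  # noqa: BLE001
            raise LoadError(f"cannot read DICOM file {f}: {exc}") from exc

    frame_refs = {str(getattr(ds, "FrameOfReferenceUID", "")) for _, ds in datasets}
    if len(frame_refs) > 1:
        raise LoadError(f"mixed frames of reference in series {path}")

    def instance_number(item):
        _, ds = item
        return int(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=instance_number)
    numbers = [instance_number(item) for item in datasets]
    for prev, cur, (f, _) in zip(numbers, numbers[1:], datasets[1:]):
        if cur != prev + 1:
            raise LoadError(
                f"missing or duplicate instance number before {f.name} "
                f"(got {cur} after {prev})"
            )

    slabs = []
    pixel_spacing = None
    slice_thickness = None
    for f, ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        if np.any(arr < 0):
            logger.warning("negative stored values in %s clamped to 0", f.name)
            arr = np.clip(arr, 0.0, None)
        if pixel_spacing is None:
            spacing = getattr(ds, "PixelSpacing", None)
            if spacing is None:
                raise LoadError(f"{f.name} has no PixelSpacing")
            if abs(float(spacing[0]) - float(spacing[1])) > 1e-6:
                raise LoadError(f"{f.name} has anisotropic in-plane pixels")
            pixel_spacing = float(spacing[0])
            slice_thickness = float(getattr(ds, "SliceThickness", pixel_spacing))
        slabs.append(arr)

    shapes = {a.shape for a in slabs}
    if len(shapes) > 1:
        raise LoadError(f"heterogeneous matrix sizes in series {path}: {shapes}")

    return PhantomVolume(
        voxels=np.stack(slabs, axis=0),
        pixel_size_mm=pixel_spacing,
        slice_thickness_mm=slice_thickness,
        source_id=path.name,
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_volume(vol: PhantomVolume) -> PhantomVolume:
    """Scale all voxels by one factor so the global maximum equals 100.

    Idempotent; preserves all pairwise voxel ratios.  Raises on an all-zero
    volume.
    """
    vmax = float(vol.voxels.max())
    if vmax <= 0:
        raise ValueError("empty volume")
    factor = NORMALIZED_MAX / vmax
    out = replace(
        vol,
        voxels=vol.voxels * factor,
        normalized=True,
        scale_factor=vol.scale_factor * factor,
    )
    # guard against floating rounding of the max itself
    out.voxels[np.unravel_index(np.argmax(out.voxels), out.voxels.shape)] = NORMALIZED_MAX
    return out


# ---------------------------------------------------------------------------
# display rendering
# ---------------------------------------------------------------------------

def render_display(vol: PhantomVolume) -> list[DisplayImage]:
    """Sum slices into ~1-cm slabs and magnify to the 256/200 display grid.

    Display-only: uses bilinear interpolation and never alters the analysis
    volume.  Slab count is ceil(n_slices * slice_thickness / 10 mm).
    """
    t = vol.slice_thickness_mm
    n = vol.n_slices
    n_slabs = max(1, math.ceil(n * t / SLAB_THICKNESS_MM))
    labels = np.minimum((np.arange(n) * t / SLAB_THICKNESS_MM).astype(int), n_slabs - 1)
    images = []
    for slab in range(n_slabs):
        members = np.nonzero(labels == slab)[0]
        if members.size == 0:
            summed = np.zeros(vol.voxels.shape[1:])
        else:
            summed = vol.voxels[members].sum(axis=0)
        images.append(
            DisplayImage(
                pixels=_magnify_to_display(summed),
                slab_thickness_mm=members.size * t,
            )
        )
    return images


def _magnify_to_display(image: np.ndarray) -> np.ndarray:
    vmax = float(image.max())
    if vmax <= 0:
        return np.zeros((DISPLAY_GRID, DISPLAY_GRID))
    mask = image >= 0.5 * vmax
    area = int(mask.sum())
    if area == 0:
        return np.zeros((DISPLAY_GRID, DISPLAY_GRID))
    rows, cols = np.nonzero(mask)
    crow, ccol = rows.mean(), cols.mean()
    radius_px = math.sqrt(area / math.pi)
    scale = DISPLAY_PHANTOM_DIAMETER_PX / (2.0 * radius_px)
    out = np.arange(DISPLAY_GRID) - (DISPLAY_GRID - 1) / 2.0
    rr = crow + out[:, None] / scale + np.zeros((1, DISPLAY_GRID))
    cc = ccol + out[None, :] / scale + np.zeros((DISPLAY_GRID, 1))
    return ndimage.map_coordinates(image, [rr, cc], order=1, mode="constant", cval=0.0)


def save_png(image, path) -> Path:
    """Write a display image (or any 2D array) as an 8-bit grayscale PNG."""
    from PIL import Image

    arr = image.pixels if isinstance(image, DisplayImage) else np.asarray(image, float)
    vmax = arr.max()
    scaled = np.zeros_like(arr) if vmax <= 0 else arr / vmax * 255.0
    Image.fromarray(scaled.astype(np.uint8), mode="L").save(path)
    return Path(path)
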