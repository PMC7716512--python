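"""Pixel-level layout extraction: regions, indices and per-region geometry.

A tissue layout is a raster in which cell-wall pixels, cell-interior pixels
and (optionally) excluded-tissue pixels are distinguished by value.  Cells
and the surrounding medium are found as connected components of the non-wall
pixels and indexed with the convention used throughout the package:

* index 1 — the external environment (interior components touching the
  image border, merged into one region),
* index 2 — tissue excluded from the simulated layout (all excluded
  components, merged),
* indices 3 .. N+2 — the N cells, in raster-scan order of each component's
  first pixel.

All geometry is reported in a y-up pixel coordinate frame: ``x = column``,
``y = height - 1 - row``, so "top" means larger ``y`` and angles are
measured counter-clockwise from the x-axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "PixelClass",
    "PixelGrid",
    "Region",
    "Ellipse",
    "CellRecord",
    "ClassificationError",
    "NoCellsError",
    "DEFAULT_CLASS_MAP",
    "EXTERIOR_ID",
    "EXCLUDED_ID",
    "FIRST_CELL_ID",
    "load_layout_image",
    "grid_from_array",
    "find_regions",
    "region_centroid",
    "region_area",
    "region_perimeter",
    "bounding_rectangle",
    "characteristic_ellipse",
    "make_cell_record",
    "extract_cells",
]

EXTERIOR_ID = 1
EXCLUDED_ID = 2
FIRST_CELL_ID = 3


class PixelClass(IntEnum):
    WALL = 0
    INTERIOR = 1
    EXCLUDED = 2


#: Default value -> class mapping for grayscale layout drawings.
DEFAULT_CLASS_MAP: dict[int, PixelClass] = {
    0: PixelClass.WALL,
    255: PixelClass.INTERIOR,
    128: PixelClass.EXCLUDED,
}


class ClassificationError(ValueError):
    """A raster value has no entry in the class map."""


class NoCellsError(ValueError):
    """The layout contains no interior cell component."""


@dataclass(frozen=True)
class PixelGrid:
    """Classified layout raster.

    ``classes`` holds one :class:`PixelClass` value per pixel;
    ``pixel_size`` is the physical edge length of a pixel in µm.
    """

    classes: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.classes.ndim != 2 or self.classes.size == 0:
            raise ValueError("pixel grid must be a non-empty 2D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def height(self) -> int:
        return int(self.classes.shape[0])

    @property
    def width(self) -> int:
        return int(self.classes.shape[1])


@dataclass(frozen=True)
class Region:
    """A set of same-class pixels with an index.

    Pixel coordinates are stored as parallel ``rows``/``cols`` arrays sorted
    in raster-scan order.  ``height`` is the height of the parent image and
    is carried so y-up geometry can be computed from the region alone.
    """

    id: int
    rows: np.ndarray
    cols: np.ndarray
    height: int

    def __post_init__(self) -> None:
        if len(self.rows) == 0:
            raise ValueError("region must contain at least one pixel")

    @property
    def n_pixels(self) -> int:
        return int(len(self.rows))

    @property
    def x(self) -> np.ndarray:
        """Pixel x coordinates (columns)."""
        return self.cols.astype(float)

    @property
    def y(self) -> np.ndarray:
        """Pixel y coordinates, y-up."""
        return (self.height - 1 - self.rows).astype(float)


@dataclass(frozen=True)
class Ellipse:
    """Characteristic ellipse of a pixel region.

    The ellipse with the same normalized second central moments as the
    region; ``angle_deg`` is the angle between its major axis and the
    x-axis, in (-90, 90], counter-clockwise positive (y-up frame).
    """

    major_axis_length: float
    minor_axis_length: float
    angle_deg: float

    def __post_init__(self) -> None:
        if not (self.major_axis_length >= self.minor_axis_length > 0):
            raise ValueError("require major >= minor > 0")


@dataclass
class CellRecord:
    """One indexed region with its geometric features.

    ``area``/``perimeter`` are physical (µm², µm); ``centroid``,
    ``bounding_rect`` and the ellipse axes are in pixels (y-up frame).
    """

    id: int
    region: Region
    area: float
    perimeter: float
    centroid: tuple[float, float]
    bounding_rect: tuple[float, float, float, float]
    ellipse: Ellipse
    cell_type: str = "default"


def _classify(values: np.ndarray, class_map: dict) -> np.ndarray:
    """Map raw raster values to PixelClass codes, rejecting unknown values."""
    out = np.full(values.shape, -1, dtype=np.int8)
    for value, cls in class_map.items():
        out[values == value] = int(cls)
    if (out < 0).any():
        bad = np.unique(values[out < 0])
        raise ClassificationError(
            f"pixel value(s) {bad.tolist()} not present in the class map"
        )
    return out


def load_layout_image(
    path: str | Path,
    pixel_size: float = 1.0,
    class_map: dict[int, PixelClass] | None = None,
) -> PixelGrid:
    """Load a PNG/TIFF layout drawing and classify its pixels.

    RGB images are accepted when all three channels agree (a grayscale
    drawing saved as RGB); otherwise the class map must be keyed by
    ``(r, g, b)`` tuples matched exactly.
    """
    if class_map is None:
        class_map = DEFAULT_CLASS_MAP
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (OSError, FileNotFoundError) as exc:
        raise OSError(f"cannot read layout image {path!r}: {exc}") from exc

    if arr.ndim == 3:
        arr = arr[..., :3]
        tuple_keys = any(isinstance(k, tuple) for k in class_map)
        if tuple_keys:
            codes = np.full(arr.shape[:2], -1, dtype=np.int8)
            for value, cls in class_map.items():
                mask = np.all(arr == np.asarray(value, dtype=arr.dtype), axis=-1)
                codes[mask] = int(cls)
            if (codes < 0).any():
                r, c = np.argwhere(codes < 0)[0]
                raise ClassificationError(
                    f"pixel value {tuple(arr[r, c].tolist())} not present in the class map"
                )
            return PixelGrid(codes, pixel_size)
        if not np.all(arr[..., 0:1] == arr):
            raise ClassificationError(
                "RGB image with unequal channels requires an (r, g, b)-keyed class map"
            )
        arr = arr[..., 0]
    return PixelGrid(_classify(arr, class_map), pixel_size)


def grid_from_array(
    values: np.ndarray,
    pixel_size: float = 1.0,
    class_map: dict[int, PixelClass] | None = None,
) -> PixelGrid:
    """Classify an in-memory raster (same contract as :func:`load_layout_image`)."""
    if class_map is None:
        class_map = DEFAULT_CLASS_MAP
    return PixelGrid(_classify(np.asarray(values), class_map), pixel_size)


def _label_components(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    if connectivity == 4:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    elif connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    else:
        raise ValueError("connectivity must be 4 or 8")
    return ndimage.label(mask, structure=structure)


def _region_from_mask_label(labels: np.ndarray, which: np.ndarray, rid: int, height: int) -> Region:
    rows, cols = np.nonzero(np.isin(labels, which))
    return Region(id=rid, rows=rows, cols=cols, height=height)


def find_regions(
    grid: PixelGrid, connectivity: int = 4
) -> tuple[list[Region], np.ndarray]:
    """Partition non-wall pixels into indexed regions.

    Returns the region list and a label raster of the same shape as the
    grid (0 on wall pixels, region id elsewhere).  Interior components
    touching the image border become the exterior (id 1, merged); excluded
    components become id 2 (merged); the remaining N interior components are
    the cells, ids 3..N+2 in raster-scan order of each component's first
    pixel.
    """
    cls = grid.classes
    h = grid.height
    interior = cls == int(PixelClass.INTERIOR)
    excluded = cls == int(PixelClass.EXCLUDED)

    lab_int, n_int = _label_components(interior, connectivity)
    border_labels = np.unique(
        np.concatenate(
            [lab_int[0, :], lab_int[-1, :], lab_int[:, 0], lab_int[:, -1]]
        )
    )
    border_labels = border_labels[border_labels > 0]

    cell_labels = [k for k in range(1, n_int + 1) if k not in set(border_labels.tolist())]
    # raster-scan order of each component's first pixel
    flat = lab_int.ravel()
    first_pixel = {}
    for k in cell_labels:
        first_pixel[k] = int(np.flatnonzero(flat == k)[0])
    cell_labels.sort(key=lambda k: first_pixel[k])

    if not cell_labels:
        raise NoCellsError("no cells found: every interior component touches the border")

    regions: list[Region] = []
    labels_out = np.zeros(cls.shape, dtype=np.int32)

    if len(border_labels) > 0:
        ext = _region_from_mask_label(lab_int, border_labels, EXTERIOR_ID, h)
        regions.append(ext)
        labels_out[ext.rows, ext.cols] = EXTERIOR_ID
    if excluded.any():
        rows, cols = np.nonzero(excluded)
        regions.append(Region(id=EXCLUDED_ID, rows=rows, cols=cols, height=h))
        labels_out[rows, cols] = EXCLUDED_ID

    for i, k in enumerate(cell_labels):
        rows, cols = np.nonzero(lab_int == k)
        rid = FIRST_CELL_ID + i
        regions.append(Region(id=rid, rows=rows, cols=cols, height=h))
        labels_out[rows, cols] = rid
    return regions, labels_out


def region_centroid(region: Region) -> tuple[float, float]:
    """Arithmetic mean of pixel coordinates, in the y-up frame."""
    return float(region.x.mean()), float(region.y.mean())


def region_area(region: Region, pixel_size: float = 1.0) -> float:
    """Pixel count scaled to µm²."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    return region.n_pixels * pixel_size**2


def region_perimeter(region: Region, pixel_size: float = 1.0) -> float:
    """Crack-length perimeter: unit pixel edges between region and non-region."""
    rmin, rmax = int(region.rows.min()), int(region.rows.max())
    cmin, cmax = int(region.cols.min()), int(region.cols.max())
    mask = np.zeros((rmax - rmin + 3, cmax - cmin + 3), dtype=bool)
    mask[region.rows - rmin + 1, region.cols - cmin + 1] = True
    edges = 0
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        edges += int(np.count_nonzero(mask & ~np.roll(mask, (dr, dc), axis=(0, 1))))
    return edges * pixel_size


def bounding_rectangle(region: Region) -> tuple[float, float, float, float]:
    """Smallest axis-aligned rectangle over pixel centers: (x_min, x_max, y_min, y_max)."""
    x, y = region.x, region.y
    return float(x.min()), float(x.max()), float(y.min()), float(y.max())


def characteristic_ellipse(region: Region) -> Ellipse:
    """Ellipse with the region's normalized second central moments.

    Each pixel contributes a 1/12 moment of its own unit square, so single
    pixels and one-pixel-wide lines yield non-degenerate ellipses.  Axis
    lengths are ``4 * sqrt(eigenvalue)``; the angle is half the argument of
    the moment tensor's off-diagonal rotation, folded into (-90, 90].
    """
    x, y = region.x, region.y
    dx = x - x.mean()
    dy = y - y.mean()
    n = region.n_pixels
    mu20 = float((dx * dx).sum()) / n + 1.0 / 12.0
    mu02 = float((dy * dy).sum()) / n + 1.0 / 12.0
    mu11 = float((dx * dy).sum()) / n
    common = 0.5 * (mu20 + mu02)
    delta = math.hypot(0.5 * (mu20 - mu02), mu11)
    lam_max = common + delta
    lam_min = max(common - delta, 0.0)
    angle = 0.5 * math.degrees(math.atan2(2.0 * mu11, mu20 - mu02))
    return Ellipse(
        major_axis_length=4.0 * math.sqrt(lam_max),
        minor_axis_length=4.0 * math.sqrt(lam_min),
        angle_deg=angle,
    )


def make_cell_record(region: Region, pixel_size: float = 1.0, cell_type: str = "default") -> CellRecord:
    """Compute all geometric features for one region."""
    return CellRecord(
        id=region.id,
        region=region,
        area=region_area(region, pixel_size),
        perimeter=region_perimeter(region, pixel_size),
        centroid=region_centroid(region),
        bounding_rect=bounding_rectangle(region),
        ellipse=characteristic_ellipse(region),
        cell_type=cell_type,
    )


def extract_cells(
    grid: PixelGrid, connectivity: int = 4
) -> tuple[dict[int, CellRecord], np.ndarray]:
    """Find regions and compute features; returns (records by id, label raster)."""
    regions, labels = find_regions(grid, connectivity)
    records = {r.id: make_cell_record(r, grid.pixel_size) for r in regions}
    return records, labels
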