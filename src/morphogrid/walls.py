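"""Wall-segment extraction and the indexed structural model.

The wall-pixel network of a tissue drawing is one big connected lattice, so
walls are not recovered as plain connected components.  Instead every wall
pixel is assigned the ordered pair ``{i, j}`` of the two distinct regions
nearest to it (Euclidean nearest-label propagation); the pixels sharing a
pair form the wall segment between cells i and j.  Segment length is the
extent of the pixels projected on the segment's characteristic-ellipse
major axis; width is area / length, clamped to one pixel.

The tissue is then summarized as a :class:`StructuralModel`: per-cell
feature records plus symmetric (N+2)-dimensional adjacency / length / width
matrices and an antisymmetric orientation-code matrix, indexed by the 1-based
region ids (matrix row/column ``k`` holds region id ``k + 1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .layout import (
    CellRecord,
    Ellipse,
    PixelClass,
    PixelGrid,
    Region,
    bounding_rectangle,
    characteristic_ellipse,
    extract_cells,
    region_centroid,
)

__all__ = [
    "WallRecord",
    "StructuralModel",
    "ConsistencyError",
    "assign_wall_pixels",
    "extract_wall_segments",
    "wall_length",
    "wall_width",
    "build_structural_model",
    "extract_structural_model",
]


class ConsistencyError(ValueError):
    """Inconsistent ids or duplicate wall pairs while assembling a model."""


@dataclass
class WallRecord:
    """One wall segment between an ordered cell pair (i < j).

    ``length``/``width`` are physical (µm); geometry fields are in pixels,
    y-up.  ``orientation_code`` is the side of cell i on which the wall
    lies (0 undetermined, 1 top, 2 bottom, 3 right, 4 left), filled in by
    the orientation module.
    """

    pair: tuple[int, int]
    region: Region
    length: float
    width: float
    centroid: tuple[float, float]
    bounding_rect: tuple[float, float, float, float]
    ellipse: Ellipse
    orientation_code: int = 0
    n_components: int = 1

    def __post_init__(self) -> None:
        i, j = self.pair
        if i >= j:
            raise ValueError("wall pair must be stored as (i, j) with i < j")


def assign_wall_pixels(
    grid: PixelGrid, labels: np.ndarray
) -> dict[tuple[int, int], tuple[int, int]]:
    """Assign each wall pixel the pair of the two nearest distinct regions.

    Distances are Euclidean from the wall pixel to the nearest pixel of
    each region.  When three or more region ids tie at the minimal
    distance the lexicographically smallest pair wins.  Pixels in an image
    with a single region are left unassigned (absent from the result).

    Returns a mapping ``(row, col) -> (i, j)`` with ``i < j``.
    """
    wall_rows, wall_cols = np.nonzero(grid.classes == int(PixelClass.WALL))
    if len(wall_rows) == 0:
        return {}
    reg_rows, reg_cols = np.nonzero(labels > 0)
    reg_ids = labels[reg_rows, reg_cols]
    if len(np.unique(reg_ids)) < 2:
        return {}

    pts = np.column_stack([reg_rows, reg_cols]).astype(float)
    tree = cKDTree(pts)
    wall_pts = np.column_stack([wall_rows, wall_cols]).astype(float)

    n_pts = len(pts)
    k0 = min(24, n_pts)
    dists, idxs = tree.query(wall_pts, k=k0)
    if k0 == 1:
        dists = dists[:, None]
        idxs = idxs[:, None]

    assignment: dict[tuple[int, int], tuple[int, int]] = {}
    eps = 1e-9
    for p in range(len(wall_pts)):
        d, li = dists[p], reg_ids[idxs[p]]
        pair = _nearest_pair(d, li)
        k = k0
        while pair is None and k < n_pts:
            k = min(k * 4, n_pts)
            d, ix = tree.query(wall_pts[p], k=k)
            li = reg_ids[np.atleast_1d(ix)]
            d = np.atleast_1d(d)
            pair = _nearest_pair(d, li, exhausted=(k == n_pts))
        if pair is None and k >= n_pts:
            pair = _nearest_pair(d, li, exhausted=True)
        if pair is not None:
            assignment[(int(wall_rows[p]), int(wall_cols[p]))] = pair
    return assignment


def _nearest_pair(d: np.ndarray, labels: np.ndarray, exhausted: bool = False):
    """Pick the two nearest distinct labels from a distance-sorted candidate list.

    Returns None when the fetched neighborhood cannot prove the choice
    (the second-distinct distance may still be beaten or tied by unfetched
    points) and ``exhausted`` is False.
    """
    eps = 1e-9
    d1 = d[0]
    tied1 = np.unique(labels[d <= d1 + eps])
    if len(tied1) >= 2:
        # all ties at d1 are fetched only if some strictly-farther point exists
        if exhausted or d[-1] > d1 + eps:
            a, b = sorted(tied1.tolist())[:2]
            return (int(a), int(b))
        return None
    a = int(tied1[0])
    other = labels != a
    if not other.any():
        return None if not exhausted else None
    d2 = d[other].min()
    if exhausted or d[-1] > d2 + eps:
        tied2 = np.unique(labels[other & (d <= d2 + eps)])
        b = int(tied2.min())
        return (min(a, b), max(a, b))
    return None


def _component_length(rows: np.ndarray, cols: np.ndarray, height: int) -> float:
    """Extent of one 8-connected wall component along its major axis, in px."""
    reg = Region(id=0, rows=rows, cols=cols, height=height)
    ell = characteristic_ellipse(reg)
    theta = math.radians(ell.angle_deg)
    proj = reg.x * math.cos(theta) + reg.y * math.sin(theta)
    return float(proj.max() - proj.min()) + 1.0


def _split_components(region: Region) -> list[tuple[np.ndarray, np.ndarray]]:
    rmin, cmin = int(region.rows.min()), int(region.cols.min())
    mask = np.zeros(
        (int(region.rows.max()) - rmin + 1, int(region.cols.max()) - cmin + 1), dtype=bool
    )
    mask[region.rows - rmin, region.cols - cmin] = True
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    out = []
    for k in range(1, n + 1):
        rr, cc = np.nonzero(lab == k)
        out.append((rr + rmin, cc + cmin))
    return out


def wall_length(record: WallRecord, pixel_size: float = 1.0) -> float:
    """Major-axis projection extent, summed over 8-connected components, in µm."""
    total = sum(
        _component_length(rr, cc, record.region.height)
        for rr, cc in _split_components(record.region)
    )
    return total * pixel_size


def wall_width(record: WallRecord, pixel_size: float = 1.0) -> float:
    """Mean width area/length, clamped to one pixel, in µm."""
    length_px = record.length / pixel_size
    return max(record.region.n_pixels * pixel_size**2 / (length_px * pixel_size), pixel_size)


def extract_wall_segments(
    assignment: dict[tuple[int, int], tuple[int, int]],
    height: int,
    pixel_size: float = 1.0,
) -> list[WallRecord]:
    """Group assigned wall pixels by pair and measure each segment.

    Disjoint components with the same pair (two cells touching twice) are
    merged into one record whose length sums the component lengths and
    whose other features are computed on the pixel union.
    """
    by_pair: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for px, pair in assignment.items():
        by_pair.setdefault(pair, []).append(px)

    records: list[WallRecord] = []
    for pair in sorted(by_pair):
        pixels = sorted(by_pair[pair])
        rows = np.array([p[0] for p in pixels])
        cols = np.array([p[1] for p in pixels])
        region = Region(id=0, rows=rows, cols=cols, height=height)
        comps = _split_components(region)
        length = sum(_component_length(rr, cc, height) for rr, cc in comps) * pixel_size
        rec = WallRecord(
            pair=pair,
            region=region,
            length=length,
            width=1.0,  # placeholder, fixed below
            centroid=region_centroid(region),
            bounding_rect=bounding_rectangle(region),
            ellipse=characteristic_ellipse(region),
            n_components=len(comps),
        )
        rec.width = wall_width(rec, pixel_size)
        records.append(rec)
    return records


@dataclass
class StructuralModel:
    """Indexed cells + walls with the (N+2)-dimensional structural matrices.

    Matrix row/column ``k`` corresponds to region id ``k + 1`` (ids run
    1..N+2).  Length/width matrices are symmetric with zeros exactly where
    adjacency is false; the orientation matrix stores ``code(i, j)`` at
    ``[i-1, j-1]`` and the opposite code at ``[j-1, i-1]``.
    """

    n_cells: int
    cells: dict[int, CellRecord]
    walls: dict[tuple[int, int], WallRecord]
    adjacency: np.ndarray
    length_matrix: np.ndarray
    width_matrix: np.ndarray
    orientation_matrix: np.ndarray
    pixel_size: float = 1.0
    labels: np.ndarray | None = None

    @property
    def dim(self) -> int:
        return self.n_cells + 2

    @property
    def cell_ids(self) -> list[int]:
        """Ids of true cells (>= 3), ascending."""
        return sorted(i for i in self.cells if i >= 3)

    def neighbors(self, i: int) -> list[int]:
        return [int(j) + 1 for j in np.nonzero(self.adjacency[i - 1])[0]]

    def is_adjacent(self, i: int, j: int) -> bool:
        return bool(self.adjacency[i - 1, j - 1])

    def wall_between(self, i: int, j: int) -> WallRecord | None:
        return self.walls.get((min(i, j), max(i, j)))

    def orientation(self, i: int, j: int) -> int:
        return int(self.orientation_matrix[i - 1, j - 1])

    def set_orientation(self, i: int, j: int, code: int) -> None:
        from .orientation import opposite  # local import avoids a cycle

        self.orientation_matrix[i - 1, j - 1] = code
        self.orientation_matrix[j - 1, i - 1] = opposite(code)
        rec = self.wall_between(i, j)
        if rec is not None:
            rec.orientation_code = code if (i, j) == rec.pair else opposite(code)


def build_structural_model(
    cells: dict[int, CellRecord],
    walls: list[WallRecord],
    pixel_size: float = 1.0,
    labels: np.ndarray | None = None,
) -> StructuralModel:
    """Assemble the indexed matrices from cell and wall records."""
    n_cells = sum(1 for i in cells if i >= 3)
    dim = n_cells + 2
    expected = set(range(3, n_cells + 3))
    actual = {i for i in cells if i >= 3}
    if actual != expected:
        raise ConsistencyError(f"cell ids {sorted(actual)} are not 3..{n_cells + 2}")

    adjacency = np.zeros((dim, dim), dtype=bool)
    length = np.zeros((dim, dim))
    width = np.zeros((dim, dim))
    orientation = np.zeros((dim, dim), dtype=np.int8)
    wall_map: dict[tuple[int, int], WallRecord] = {}
    for rec in walls:
        i, j = rec.pair
        if (i, j) in wall_map:
            raise ConsistencyError(f"duplicate wall pair {(i, j)}")
        if i not in cells or j not in cells:
            raise ConsistencyError(f"wall pair {(i, j)} references unknown region id")
        wall_map[(i, j)] = rec
        adjacency[i - 1, j - 1] = adjacency[j - 1, i - 1] = True
        length[i - 1, j - 1] = length[j - 1, i - 1] = rec.length
        width[i - 1, j - 1] = width[j - 1, i - 1] = rec.width
    return StructuralModel(
        n_cells=n_cells,
        cells=dict(cells),
        walls=wall_map,
        adjacency=adjacency,
        length_matrix=length,
        width_matrix=width,
        orientation_matrix=orientation,
        pixel_size=pixel_size,
        labels=labels,
    )


def extract_structural_model(grid: PixelGrid, connectivity: int = 4) -> StructuralModel:
    """Full extraction pipeline: regions -> features -> walls -> matrices."""
    cells, labels = extract_cells(grid, connectivity)
    assignment = assign_wall_pixels(grid, labels)
    walls = extract_wall_segments(assignment, grid.height, grid.pixel_size)
    return build_structural_model(cells, walls, grid.pixel_size, labels)
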