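"""Synthetic labeled tissue layouts with exhaustive ground truth.

These generators draw clean layout rasters (wall pixels 0, interior 255)
the way a hand-drawn tissue scheme would look, together with the complete
ground truth the extraction pipeline is supposed to recover: cell count,
the id of the cell at each grid position, the neighbor pairs, the true
orientation code of every internal wall, and per-cell type labels.

* :func:`make_grid_layout` — rows x cols rectangular cells;
* :func:`make_jittered_layout` — same topology, wall junctions displaced
  by a seeded uniform offset and walls re-rasterized as straight segments
  (the perturbation a slightly irregular tissue would show, without
  changing adjacency);
* :func:`make_roottip_layout` — a root-tip-like layout: cell files typed
  by column (epidermis/cortex/vascular) and a bottom cap of columella rows;
* :func:`demo_polar_transport_spec` — a minimal reflected-flow polar
  transport model on the root-tip layout: a morphogen is pumped rootward
  through the vascular files, laterally through the columella cap and
  shootward through the outer files, which self-organizes an interior
  concentration maximum from uniform initial data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from . import orientation as ori
from .assembly import Boundary, ModelSpec, Substance
from .kinetics import ReactionTerm, TransportParams
from .layout import FIRST_CELL_ID, PixelClass, grid_from_array

__all__ = [
    "GroundTruth",
    "LayoutSizeError",
    "TopologyError",
    "make_grid_layout",
    "make_jittered_layout",
    "make_roottip_layout",
    "demo_polar_transport_spec",
    "save_layout_png",
    "MAX_IMAGE_DIM",
]

MAX_IMAGE_DIM = 4096

WALL_VALUE = 0
INTERIOR_VALUE = 255


class LayoutSizeError(ValueError):
    """Requested parameters exceed the raster size cap."""


class TopologyError(RuntimeError):
    """Jitter collapsed the layout topology (cells merged or split)."""


@dataclass
class GroundTruth:
    """Everything the extraction pipeline should recover from a layout."""

    n_cells: int
    ids: dict[tuple[int, int], int]          # (grid row, grid col) -> cell id
    neighbor_pairs: set[tuple[int, int]]     # cell-cell pairs, i < j
    orientations: dict[tuple[int, int], int]  # directed (i, j) -> code
    cell_types: dict[int, str]
    params: dict = field(default_factory=dict)

    def type_map(self) -> dict[int, str]:
        return dict(self.cell_types)


def save_layout_png(image: np.ndarray, path) -> None:
    Image.fromarray(image).save(path, format="PNG")


def _check_dims(h: int, w: int) -> None:
    if h > MAX_IMAGE_DIM or w > MAX_IMAGE_DIM:
        raise LayoutSizeError(
            f"layout raster {h}x{w} exceeds the {MAX_IMAGE_DIM}px cap"
        )


def _raster_scan_cell_labels(image: np.ndarray) -> np.ndarray:
    """Label enclosed interior components in raster-scan order of first pixel.

    Same id convention as the extraction pipeline: border-connected
    interior is the exterior, enclosed components get 3, 4, ... in
    raster-scan order.  Used to attach ground-truth ids to grid positions.
    """
    from .layout import find_regions

    grid = grid_from_array(image)
    _, labels = find_regions(grid, connectivity=4)
    return labels


def _grid_truth(
    ids: dict[tuple[int, int], int],
    rows: int,
    cols: int,
    cell_types: dict[int, str],
    params: dict,
) -> GroundTruth:
    pairs: set[tuple[int, int]] = set()
    codes: dict[tuple[int, int], int] = {}

    def add(i: int, j: int, code_ij: int) -> None:
        pairs.add((min(i, j), max(i, j)))
        codes[(i, j)] = code_ij
        codes[(j, i)] = ori.opposite(code_ij)

    for r in range(rows):
        for c in range(cols):
            i = ids[(r, c)]
            if c + 1 < cols:
                add(i, ids[(r, c + 1)], ori.RIGHT)
            if r + 1 < rows:
                # larger grid row = lower on the page = smaller y
                add(i, ids[(r + 1, c)], ori.BOTTOM)
    return GroundTruth(
        n_cells=rows * cols,
        ids=dict(ids),
        neighbor_pairs=pairs,
        orientations=codes,
        cell_types=cell_types,
        params=params,
    )


def _nominal_centers(
    rows: int, cols: int, cell_px: int, wall_px: int, border_px: int
) -> dict[tuple[int, int], tuple[float, float]]:
    """(grid row, grid col) -> nominal (row, col) pixel center of the cell."""
    pitch = cell_px + wall_px
    out = {}
    for r in range(rows):
        for c in range(cols):
            rr = border_px + wall_px + r * pitch + (cell_px - 1) / 2.0
            cc = border_px + wall_px + c * pitch + (cell_px - 1) / 2.0
            out[(r, c)] = (rr, cc)
    return out


def make_grid_layout(
    rows: int,
    cols: int,
    cell_px: int = 20,
    wall_px: int = 2,
    border_px: int = 2,
) -> tuple[np.ndarray, GroundTruth]:
    """Rectangular grid of cells separated by walls, with exterior margin."""
    if rows < 1 or cols < 1 or cell_px < 3 or wall_px < 1 or border_px < 1:
        raise ValueError("require rows, cols >= 1, cell_px >= 3, wall_px, border_px >= 1")
    pitch = cell_px + wall_px
    h = 2 * border_px + rows * pitch + wall_px
    w = 2 * border_px + cols * pitch + wall_px
    _check_dims(h, w)
    img = np.full((h, w), WALL_VALUE, dtype=np.uint8)
    img[:border_px, :] = INTERIOR_VALUE
    img[-border_px:, :] = INTERIOR_VALUE
    img[:, :border_px] = INTERIOR_VALUE
    img[:, -border_px:] = INTERIOR_VALUE
    for r in range(rows):
        for c in range(cols):
            r0 = border_px + wall_px + r * pitch
            c0 = border_px + wall_px + c * pitch
            img[r0 : r0 + cell_px, c0 : c0 + cell_px] = INTERIOR_VALUE

    ids = {
        (r, c): FIRST_CELL_ID + r * cols + c for r in range(rows) for c in range(cols)
    }
    types = {i: "default" for i in ids.values()}
    params = dict(rows=rows, cols=cols, cell_px=cell_px, wall_px=wall_px,
                  border_px=border_px, jitter=0.0, seed=None)
    return img, _grid_truth(ids, rows, cols, types, params)


def _draw_segment(img: np.ndarray, p0, p1, radius: float) -> None:
    """Paint wall pixels within ``radius`` of the segment p0-p1 (row, col)."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    lo = np.floor(np.minimum(p0, p1) - radius).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + radius).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, img.shape)
    rr, cc = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), indexing="ij"
    )
    pts = np.stack([rr, cc], axis=-1).astype(float)
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0:
        t = np.zeros(pts.shape[:2])
    else:
        t = np.clip(((pts - p0) @ d) / denom, 0.0, 1.0)
    closest = p0 + t[..., None] * d
    dist = np.linalg.norm(pts - closest, axis=-1)
    sub = img[lo[0] : hi[0], lo[1] : hi[1]]
    sub[dist <= radius] = WALL_VALUE


def make_jittered_layout(
    rows: int,
    cols: int,
    cell_px: int = 20,
    wall_px: int = 2,
    jitter_frac: float = 0.1,
    seed: int = 0,
    border_px: int = 2,
) -> tuple[np.ndarray, GroundTruth]:
    """Grid layout with internal wall junctions displaced by a seeded offset.

    Junction points are moved by a uniform per-coordinate offset up to
    ``jitter_frac * cell_px`` and walls re-rasterized as straight segments,
    so the cell topology (adjacency and true orientations) is preserved.
    The same (parameters, seed) always yields a byte-identical image; the
    generator retries with a fresh substream if a jitter draw happens to
    merge or split cells, and raises :class:`TopologyError` if that keeps
    failing.
    """
    if not (0.0 <= jitter_frac <= 0.3):
        raise ValueError("jitter_frac must be in [0, 0.3]")
    if jitter_frac == 0.0:
        return make_grid_layout(rows, cols, cell_px, wall_px, border_px)
    pitch = cell_px + wall_px
    h = 2 * border_px + rows * pitch + wall_px
    w = 2 * border_px + cols * pitch + wall_px
    _check_dims(h, w)
    half = (wall_px - 1) / 2.0
    # nominal junction centers, (rows+1) x (cols+1)
    jr = border_px + np.arange(rows + 1) * pitch + half
    jc = border_px + np.arange(cols + 1) * pitch + half
    base = np.zeros((rows + 1, cols + 1, 2))
    base[..., 0] = jr[:, None]
    base[..., 1] = jc[None, :]

    rng = np.random.default_rng(seed)
    amp = jitter_frac * cell_px
    centers = _nominal_centers(rows, cols, cell_px, wall_px, border_px)
    for attempt in range(5):
        pts = base.copy()
        offs = rng.uniform(-amp, amp, size=(rows - 1 if rows > 1 else 0, cols - 1 if cols > 1 else 0, 2))
        if offs.size:
            pts[1:rows, 1:cols] += offs
        img = np.full((h, w), INTERIOR_VALUE, dtype=np.uint8)
        radius = wall_px / 2.0
        for r in range(rows + 1):
            for c in range(cols + 1):
                if c + 1 <= cols:
                    _draw_segment(img, pts[r, c], pts[r, c + 1], radius)
                if r + 1 <= rows:
                    _draw_segment(img, pts[r, c], pts[r + 1, c], radius)
        labels = _raster_scan_cell_labels(img)
        ids: dict[tuple[int, int], int] = {}
        ok = True
        for (r, c), (rr, cc) in centers.items():
            rid = int(labels[int(round(rr)), int(round(cc))])
            if rid < FIRST_CELL_ID:
                ok = False
                break
            ids[(r, c)] = rid
        if ok and len(set(ids.values())) == rows * cols and labels.max() == rows * cols + 2:
            types = {i: "default" for i in ids.values()}
            params = dict(rows=rows, cols=cols, cell_px=cell_px, wall_px=wall_px,
                          border_px=border_px, jitter=jitter_frac, seed=seed)
            return img, _grid_truth(ids, rows, cols, types, params)
    raise TopologyError(
        f"jitter {jitter_frac} kept breaking the cell topology for seed {seed}"
    )


def make_roottip_layout(
    columns_spec: list[str],
    rows: int,
    cap_rows: int,
    cell_px: int = 14,
    wall_px: int = 2,
    border_px: int = 2,
) -> tuple[np.ndarray, GroundTruth]:
    """Root-tip-like layout: column-typed cell files over a columella cap.

    ``columns_spec`` names the type of each column (e.g. epidermis |
    cortex | vascular, mirrored); the bottom ``cap_rows`` rows are typed
    ``"columella"`` regardless of column.  Total cells:
    ``(rows + cap_rows) * len(columns_spec)``.
    """
    if cap_rows < 1 or rows < 1 or not columns_spec:
        raise ValueError("require rows >= 1, cap_rows >= 1 and a non-empty column spec")
    cols = len(columns_spec)
    total_rows = rows + cap_rows
    img, truth = make_grid_layout(total_rows, cols, cell_px, wall_px, border_px)
    types: dict[int, str] = {}
    for (r, c), cid in truth.ids.items():
        types[cid] = "columella" if r >= rows else columns_spec[c]
    truth.cell_types = types
    truth.params.update(columns_spec=list(columns_spec), body_rows=rows, cap_rows=cap_rows)
    return img, truth


DEMO_TYPES = ("epidermis", "cortex", "vascular", "columella")


def demo_polar_transport_spec(
    truth: GroundTruth,
    synthesis: float = 0.1,
    decay: float = 0.01,
    permeability: float = 1.0,
    k_act: float = 0.5,
    carrier: float = 1.0,
    initial: float = 0.1,
) -> ModelSpec:
    """Reflected-flow polar transport demo on a root-tip layout.

    One mobile substance ("auxin") with uniform synthesis and turnover.
    Efflux carriers drive a convergent rootward stream — every cell file
    transports toward the tip, with carrier abundance graded from the
    epidermis (weakest) through the cortex to the vascular files
    (strongest) — and the columella cap reflects the stream shootward.
    Under closed boundaries this self-organizes a concentration maximum
    at the vascular tip, directly above the cap, from uniform initial
    data.  (A wiring in which the outer files pump shootward instead
    cannot place the maximum in the tissue interior when the boundary is
    closed: the shootward stream has active influx but no active efflux
    at the topmost cells, so mass accumulates there.)
    """
    present = set(truth.cell_types.values())
    missing = sorted(set(DEMO_TYPES) - present)
    if missing:
        raise ValueError(f"root-tip layout is missing cell types {missing}")
    terms = [
        ReactionTerm(kind="constant", params={"c0": synthesis}),
        ReactionTerm(kind="linear_decay", params={"k": decay}),
    ]
    return ModelSpec(
        substances=[Substance("auxin", mobile=True)],
        cell_types=sorted(present),
        equations={"*": {"auxin": list(terms)}},
        transport={
            "auxin": TransportParams(
                permeability=permeability,
                k_act=k_act,
                carriers={
                    "vascular": {"bottom": carrier},
                    "cortex": {"bottom": 0.5 * carrier},
                    "epidermis": {"bottom": 0.3 * carrier},
                    "columella": {"top": carrier},
                },
            )
        },
        boundary={1: Boundary()},
        initial={"*": {"auxin": initial}},
    )
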