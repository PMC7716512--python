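"""On-disk representation of a structural model.

A model directory holds:

* ``cells.csv`` — per-region features (one row per id, including the
  exterior and excluded regions when present);
* ``walls.csv`` — per-wall-segment features and orientation codes;
* ``adjacency.mtx``, ``length.mtx``, ``width.mtx``, ``orientation.mtx`` —
  sparse coordinate Matrix Market files of dimension (N+2) x (N+2), row k
  holding region id k+1;
* ``labels.tif`` — 16-bit label raster (0 on wall pixels, region id
  elsewhere), from which region pixel sets are reconstructed on load.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import sparse
from scipy.io import mmread, mmwrite

from .layout import CellRecord, Ellipse, Region, make_cell_record
from .orientation import Correction, CorrectionTable
from .walls import StructuralModel, WallRecord, build_structural_model

__all__ = [
    "write_model_dir",
    "read_model_dir",
    "read_corrections_csv",
    "write_state_csv",
    "read_state_csv",
]

_CELL_COLUMNS = [
    "id", "area", "perimeter", "centroid_x", "centroid_y",
    "bbox_xmin", "bbox_xmax", "bbox_ymin", "bbox_ymax",
    "ellipse_major", "ellipse_minor", "ellipse_angle_deg", "cell_type",
]

_WALL_COLUMNS = [
    "i", "j", "length", "width", "centroid_x", "centroid_y",
    "bbox_xmin", "bbox_xmax", "bbox_ymin", "bbox_ymax",
    "ellipse_angle_deg", "orientation_code",
]


def _cells_frame(model: StructuralModel) -> pd.DataFrame:
    rows = []
    for i in sorted(model.cells):
        c = model.cells[i]
        rows.append({
            "id": i,
            "area": c.area,
            "perimeter": c.perimeter,
            "centroid_x": c.centroid[0],
            "centroid_y": c.centroid[1],
            "bbox_xmin": c.bounding_rect[0],
            "bbox_xmax": c.bounding_rect[1],
            "bbox_ymin": c.bounding_rect[2],
            "bbox_ymax": c.bounding_rect[3],
            "ellipse_major": c.ellipse.major_axis_length,
            "ellipse_minor": c.ellipse.minor_axis_length,
            "ellipse_angle_deg": c.ellipse.angle_deg,
            "cell_type": c.cell_type,
        })
    return pd.DataFrame(rows, columns=_CELL_COLUMNS)


def _walls_frame(model: StructuralModel) -> pd.DataFrame:
    rows = []
    for (i, j) in sorted(model.walls):
        w = model.walls[(i, j)]
        rows.append({
            "i": i,
            "j": j,
            "length": w.length,
            "width": w.width,
            "centroid_x": w.centroid[0],
            "centroid_y": w.centroid[1],
            "bbox_xmin": w.bounding_rect[0],
            "bbox_xmax": w.bounding_rect[1],
            "bbox_ymin": w.bounding_rect[2],
            "bbox_ymax": w.bounding_rect[3],
            "ellipse_angle_deg": w.ellipse.angle_deg,
            "orientation_code": w.orientation_code,
        })
    return pd.DataFrame(rows, columns=_WALL_COLUMNS)


def write_model_dir(model: StructuralModel, out_dir: str | Path) -> Path:
    """Write the full structural model to a directory; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _cells_frame(model).to_csv(out / "cells.csv", index=False)
    _walls_frame(model).to_csv(out / "walls.csv", index=False)
    mmwrite(out / "adjacency.mtx", sparse.coo_matrix(model.adjacency.astype(np.int8)))
    mmwrite(out / "length.mtx", sparse.coo_matrix(model.length_matrix), precision=17)
    mmwrite(out / "width.mtx", sparse.coo_matrix(model.width_matrix), precision=17)
    mmwrite(out / "orientation.mtx", sparse.coo_matrix(model.orientation_matrix.astype(np.int32)))
    if model.labels is not None:
        tifffile.imwrite(out / "labels.tif", model.labels.astype(np.uint16))
    with open(out / "meta.txt", "w") as fh:
        fh.write(f"pixel_size={model.pixel_size!r}\nn_cells={model.n_cells}\n")
    return out


def _regions_from_labels(labels: np.ndarray) -> dict[int, Region]:
    h = labels.shape[0]
    out = {}
    for rid in np.unique(labels):
        if rid == 0:
            continue
        rows, cols = np.nonzero(labels == rid)
        out[int(rid)] = Region(id=int(rid), rows=rows, cols=cols, height=h)
    return out


def read_model_dir(in_dir: str | Path) -> StructuralModel:
    """Reconstruct a structural model from a model directory."""
    d = Path(in_dir)
    meta = {}
    for line in (d / "meta.txt").read_text().splitlines():
        k, v = line.split("=", 1)
        meta[k] = v
    pixel_size = float(meta["pixel_size"])

    labels = tifffile.imread(d / "labels.tif").astype(np.int32)
    regions = _regions_from_labels(labels)

    cells_df = pd.read_csv(d / "cells.csv")
    cells: dict[int, CellRecord] = {}
    for _, row in cells_df.iterrows():
        rid = int(row["id"])
        cells[rid] = CellRecord(
            id=rid,
            region=regions[rid],
            area=float(row["area"]),
            perimeter=float(row["perimeter"]),
            centroid=(float(row["centroid_x"]), float(row["centroid_y"])),
            bounding_rect=(
                float(row["bbox_xmin"]), float(row["bbox_xmax"]),
                float(row["bbox_ymin"]), float(row["bbox_ymax"]),
            ),
            ellipse=Ellipse(
                major_axis_length=float(row["ellipse_major"]),
                minor_axis_length=float(row["ellipse_minor"]),
                angle_deg=float(row["ellipse_angle_deg"]),
            ),
            cell_type=str(row["cell_type"]),
        )

    length = np.asarray(mmread(d / "length.mtx").todense())
    width = np.asarray(mmread(d / "width.mtx").todense())
    orient = np.asarray(mmread(d / "orientation.mtx").todense()).astype(np.int8)

    walls_df = pd.read_csv(d / "walls.csv")
    # wall pixel sets are not persisted; records carry geometry summaries
    # only (the matrices hold everything downstream modules need)
    walls = []
    for _, row in walls_df.iterrows():
        i, j = int(row["i"]), int(row["j"])
        placeholder = Region(
            id=0,
            rows=np.array([0]),
            cols=np.array([0]),
            height=labels.shape[0],
        )
        walls.append(WallRecord(
            pair=(i, j),
            region=placeholder,
            length=float(row["length"]),
            width=float(row["width"]),
            centroid=(float(row["centroid_x"]), float(row["centroid_y"])),
            bounding_rect=(
                float(row["bbox_xmin"]), float(row["bbox_xmax"]),
                float(row["bbox_ymin"]), float(row["bbox_ymax"]),
            ),
            ellipse=Ellipse(1.0, 1.0, float(row["ellipse_angle_deg"])),
            orientation_code=int(row["orientation_code"]),
        ))
    model = build_structural_model(cells, walls, pixel_size, labels)
    model.length_matrix = length
    model.width_matrix = width
    model.orientation_matrix = orient
    for rec in model.walls.values():
        rec.orientation_code = model.orientation(*rec.pair)
    return model


def read_corrections_csv(path: str | Path) -> CorrectionTable:
    """Read a manual correction table: columns i, j, code (1-4)."""
    df = pd.read_csv(path)
    entries = [
        Correction(i=int(r["i"]), j=int(r["j"]), code=int(r["code"]))
        for _, r in df.iterrows()
    ]
    return CorrectionTable(entries=entries)


def write_state_csv(path: str | Path, values: dict[str, dict[int, float]]) -> None:
    """Write per-cell concentrations: columns cell_id, substance, concentration."""
    rows = [
        {"cell_id": cid, "substance": name, "concentration": v}
        for name in sorted(values)
        for cid, v in sorted(values[name].items())
    ]
    pd.DataFrame(rows, columns=["cell_id", "substance", "concentration"]).to_csv(
        path, index=False
    )


def read_state_csv(path: str | Path) -> dict[str, dict[int, float]]:
    df = pd.read_csv(path)
    out: dict[str, dict[int, float]] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["substance"]), {})[int(r["cell_id"])] = float(
            r["concentration"]
        )
    return out
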