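"""Extract a structural model from a generated tissue layout.

Builds an 8x8 grid layout, finds cells and wall segments, and prints the
indexed features: cell areas/perimeters and the wall length matrix.  Cell
ids run 3..N+2 (1 = exterior, 2 = excluded tissue); the matrices are
(N+2)-dimensional with row/column k holding region id k+1.
"""

import numpy as np

import morphogrid as mg

img, truth = mg.make_grid_layout(rows=8, cols=8, cell_px=20, wall_px=2)
model = mg.extract_structural_model(mg.grid_from_array(img, pixel_size=1.0))

print(f"cells: {model.n_cells} (ids {model.cell_ids[0]}..{model.cell_ids[-1]})")
print(f"wall segments: {len(model.walls)} "
      f"({sum(1 for p in model.walls if p[0] >= 3)} between cells)")

c = model.cells[3]
print(f"cell 3: area {c.area:.0f} um^2, perimeter {c.perimeter:.0f} um, "
      f"centroid ({c.centroid[0]:.1f}, {c.centroid[1]:.1f}) px")

w = model.wall_between(3, 4)
print(f"wall (3,4): length {w.length:.1f} um, width {w.width:.1f} um")
print(f"neighbors of cell 12: {model.neighbors(12)}")
print("length matrix is symmetric:",
      bool(np.all(model.length_matrix == model.length_matrix.T)))
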