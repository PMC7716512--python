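# Methods

This note documents the models, estimators and numerical choices behind
`morphogrid`, and what the synthetic fixtures do and do not establish
about real imaging data.

## Coordinate and index conventions

All geometry uses a y-up pixel frame: `x = column`, `y = height − 1 − row`,
so "top" is larger y and angles are counter-clockwise from the x-axis.
Raster conventions give no intrinsic vertical direction; y-up was chosen
so that the top/bottom vocabulary of wall orientation matches how a
biologist reads a figure (shootward up, rootward down).

Regions are indexed 1 (external environment), 2 (excluded tissue) and
3..N+2 (cells, in raster-scan order of each component's first pixel —
an arbitrary but deterministic choice). Cell interiors are labeled with
4-connectivity and wall-pixel components with 8-connectivity: 4-connected
cells cannot leak diagonally through a one-pixel wall, while 8-connected
walls stay intact at corners. Interior components touching the image
border are all merged into region 1; all excluded components merge into
region 2. These two regions may therefore be disconnected pixel sets —
they act as boundary reservoirs, not as cells.

## Region geometry

* **Area** is pixel count × `pixel_size`²; **perimeter** is the
  crack-length (count of unit pixel edges between region and non-region),
  which is exact and parameter-free on pixel art. Both are reported in µm
  via the µm/px scale; `rescale_units` applies a further scale factor
  (areas ×f², lengths ×f) when a model is written in different units.
* The **characteristic ellipse** has the region's normalized second
  central moments: µ20 = Σdx²/n + 1/12, µ02 = Σdy²/n + 1/12,
  µ11 = Σdx·dy/n; axes are 4·√eigenvalue and the major-axis angle is
  ½·atan2(2µ11, µ20−µ02), folded into (−90°, 90°]. The +1/12 term is the
  second moment of a unit pixel about its own center; with it a single
  pixel gets the ellipse of a unit square (axes 4·√(1/12) ≈ 1.155) and a
  one-pixel-wide wall a nonzero minor axis, instead of degenerate zeros.
  The closed form is cross-checked in the tests against an independent
  eigendecomposition of the moment tensor.

## Wall segmentation and measurement

The wall network of a drawing is a single connected lattice, so segments
cannot be read off as connected components. Every wall pixel is instead
assigned the pair {i, j} of the two regions nearest to it by Euclidean
distance to region pixels (a KD-tree query); exact distance ties among
three or more regions — the generic situation at four-way junctions of a
perfect grid — resolve to the lexicographically smallest pair. Pixels
sharing a pair form the wall segment; when a pair's pixels fall into
several 8-connected components (two cells touching twice) they are merged
into one record whose length sums the component lengths, because the
structural matrices hold one scalar per pair.

Segment **length** is the extent of the pixels projected on the segment's
ellipse major axis, plus one pixel (so a single-pixel wall has length 1);
**width** is pixel area / length, clamped below at one pixel. Both are
exact on straight axis-aligned walls and stable on curved ones. On
jittered layouts the nearest-two rule can hand one or two junction pixels
to a diagonally-adjacent cell pair, creating a spurious wall record of a
few pixels; such records never disturb the orientation of true walls, and
the tests treat the true neighbor set as a subset (exact equality holds
on regular layouts).

## Wall orientation

`code(i, j)` names the side of cell i on which the wall lies (equivalently
the direction from i toward j): 1 top, 2 bottom, 3 right, 4 left. The
stored matrix satisfies `code(j, i) = opposite(code(i, j))`.

Direct rules, evaluated per wall:

1. **Extent** — if the wall's y-range lies strictly between the two
   centroids and the x-range does not, the pair is stacked vertically
   (code by centroid order); symmetrically for x. Both or neither → no
   verdict.
2. **Axis** — wall ellipse major-axis angle steeper than 45° means a
   vertical wall, so the code is right/left by centroid x-order;
   shallower than 45° gives top/bottom by y-order; exactly 45° abstains.
3. **Rectangle** — if the centroids fall on opposite sides of the wall's
   bounding rectangle, the code follows which side cell i occupies; if
   several side-pairs fire, the rule abstains.

A wall is resolved when at least one rule fires and all firing rules
agree. Requiring all three to fire would fail on ordinary curved walls
(the extent rule is the most fragile), so agreement-of-firing-rules is
the quorum. Remaining walls use common neighbors q of i and j, swept in
lexicographic pair order to a fixpoint: if (i, q) and (j, q) are both
vertical the wall (i, j) is horizontal (top/bottom by centroid order),
and symmetrically; if one flanking wall is vertical and the other
horizontal, the corner rule compares centroid order with the flanking
codes. The corner rule is implemented literally as stated for both
orderings of the pair; its left/right clause can fire together with the
top/bottom clause for obliquely offset cells, in which case the verdicts
conflict. Conflicting verdicts from different neighbors (or clauses)
leave the wall unresolved rather than voting — ambiguity is exactly what
the manual correction table is for, and silent majority voting could
hide segmentation errors. Resolution never overwrites an already-resolved
code, so the sweep is monotone and terminates.

Orientation is attempted for cell–exterior walls too (their centroids are
those of the merged exterior region, so corner walls often stay
unresolved); models with closed boundaries never need those codes.

## The ODE framework

State layout: substances outermost (spec order), cells innermost
ascending by id. For mobile substance A in cell i of type τ:

dA_i/dt = Σ terms(τ, A) + (1/V_i) Σ_j [ P·s_ij·(A_j − A_i)
          + k_act·s_ij·(c_ji·A_j − c_ij·A_i) ]

* V_i is the cell's cross-sectional area (µm²), the 2D volume proxy.
* s_ij is the wall contact **length** (µm); an optional switch multiplies
  it by the wall width, and optional per-side factors scale the passive
  permeability — the hooks for orientation-specific flow without fixing a
  formula.
* c_ij is the carrier amount of cell i on its (i, j) wall, resolved from
  a (cell type → wall side → amount) placement map. A placement value may
  also name an immobile substance, making the carrier a dynamic per-cell
  variable (uniform over the cell's walls). Compilation fails loudly if a
  carrier placement needs a wall side that the orientation stage left
  unresolved.
* Fluxes are computed as directed transfers T = s·(P + k_act·c_ij)·A_i
  subtracted at the donor (÷V_i) and added at the acceptor (÷V_j), which
  makes pairwise conservation exact to round-off: with all reactions off
  and boundaries closed, Σ V_i·A_i is constant (measured drift ~1e-16
  over t = 1000 on the 8×8 grid).
* Boundaries toward regions 1 and 2 default to closed (flux terms
  omitted); a fixed-concentration boundary treats the outside as a
  reservoir with constant concentration and no tracked derivative.
* Immobile substances keep only their reaction terms, so their dynamics
  are strictly cell-local.

Reaction terms: constant synthesis c0; linear turnover −k·x;
Michaelis–Menten Vmax·r/(Km+r); generalized Hill factors
(x/K)^h/(1+(x/K)^h) (activation) and 1/(1+(x/K)^h) (repression), scaled
by Vmax and composable as products over several regulators. Reaction
evaluation clips state values at zero because the stiff solver may
undershoot slightly; transport laws are linear and evaluated unclipped.

## Numerics

Integration uses `scipy.integrate.solve_ivp` with the BDF method
(implicit, variable order — the standard family for stiff
reaction–transport systems), defaults rtol 1e-6 and atol 1e-9; the method
is selectable. Steady states are detected by integrating over doubling
windows (1, 2, 4, ... time units, capped at t_max = 1e6) until
‖rhs(y)‖∞ < tol_rel·max(‖y‖∞, atol) with tol_rel = 1e-8; a residual test
is robust for stiff relaxation and avoids root-finding on the rhs. A
state-norm guard of 1e12 converts divergence into an explicit error.
Tightening rtol from 1e-6 to 1e-8 moves the demo steady state by less
than 1e-4 relative.

Rendering normalizes concentrations per render from the minimum to the
maximum over cells (a fixed range is available for comparing states);
walls are black, exterior/excluded neutral gray, and a degenerate range
maps every cell to the colormap midpoint.

## Synthetic layouts and what they show

The generators draw clean pixel layouts (walls 0, interior 255) with
exhaustive ground truth: `make_grid_layout` (rectangular cells),
`make_jittered_layout` (wall junctions displaced by a seeded uniform
offset up to `jitter_frac`·cell_px, walls re-rasterized as straight
segments so topology and true orientations are preserved; cell ids are
attached by locating each nominal cell center in the rasterized image,
since raster-scan id order itself can permute under jitter), and
`make_roottip_layout` (column-typed cell files over `cap_rows` bottom
rows of columella). All randomness flows through explicit seeds; equal
parameters and seed give byte-identical images.

These fixtures emulate tissue topology and moderate geometric
irregularity. They do not emulate curved organ outlines, variable wall
thickness, staining noise or segmentation artifacts — so passing tests
establish the correctness of the indexing, geometry, orientation logic
and ODE machinery on clean layouts, not robustness to imperfect
segmentations, where the manual correction path is expected to carry more
weight.

Fixture sizes used by the test-suite and the acceptance script (8×8
reference grid with 20 px cells, ten jittered 6×6 grids, a 5×10 root-tip
layout with 14 px cells) were chosen as the smallest layouts that exercise
every code path with comfortable margins.

## The polar-transport demo

The demo is deliberately minimal and is **not** a published auxin model:
one mobile substance with uniform constant synthesis (0.1 conc/time) and
linear turnover (0.01 /time), passive permeability P = 1 µm/time, carrier
rate k_act = 0.5, on the root-tip layout with closed boundaries and
uniform initial data (0.1). Efflux carriers drive a convergent rootward
stream — vascular files pump down with carrier 1.0, cortex 0.5, epidermis
0.3 — and the columella cap pumps up, reflecting the stream at the tip.
The steady state places the global maximum in the vascular cell directly
above the cap: an interior tip cell, with a ~3-fold contrast over the
layout.

The grading of carrier strength across files is what localizes the
maximum in the central file. A wiring in which the outer files pump
shootward instead (a naive reading of the reverse-fountain cartoon)
cannot produce an interior maximum under closed boundaries: the topmost
lateral cells then have carrier-mediated influx but no carrier-mediated
efflux, so mass necessarily accumulates at the shootward boundary —
published reverse-fountain models avoid this with a shootward source/sink
or a return path into the vasculature, both outside this demo's scope.
Likewise, pumping a cap cell both left and right cancels to pure lateral
mixing and orients nothing. The chosen wiring is the smallest closed
system whose steady state self-organizes the interior tip maximum from
uniform initial data.

## Known limitations

* Sub-pixel wall geometry and arc-length of strongly curved walls are out
  of scope; the length estimator chords each 8-connected component.
* The nearest-two-labels rule can fabricate few-pixel diagonal wall
  records at strongly jittered junctions (see above).
* Orientation is defined in the image frame only; tissues whose polarity
  follows a curved organ axis need their layouts drawn in a straightened
  frame first.
* Layout geometry is static: no growth, division or deformation.
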