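"""The wall-orientation rule cascade against generator ground truth."""

import numpy as np
import pytest

import morphogrid as mg
from morphogrid.layout import CellRecord, Ellipse, Region, grid_from_array
from morphogrid.orientation import (
    BOTTOM,
    LEFT,
    RIGHT,
    TOP,
    UNDETERMINED,
    Correction,
    CorrectionTable,
    CorrectionError,
    UnresolvedWallsError,
    direct_orientation,
    opposite,
    rule_axis,
    rule_extent,
    rule_rectangle,
)
from morphogrid.walls import WallRecord


def fake_cell(cid, centroid):
    reg = Region(id=cid, rows=np.array([0]), cols=np.array([0]), height=10)
    return CellRecord(
        id=cid, region=reg, area=1.0, perimeter=4.0, centroid=centroid,
        bounding_rect=(centroid[0], centroid[0], centroid[1], centroid[1]),
        ellipse=Ellipse(1.0, 1.0, 0.0),
    )


def fake_wall(pair, bounding_rect, angle_deg=0.0):
    reg = Region(id=0, rows=np.array([0]), cols=np.array([0]), height=10)
    return WallRecord(
        pair=pair, region=reg, length=1.0, width=1.0,
        centroid=((bounding_rect[0] + bounding_rect[1]) / 2,
                  (bounding_rect[2] + bounding_rect[3]) / 2),
        bounding_rect=bounding_rect,
        ellipse=Ellipse(2.0, 1.0, angle_deg),
    )


class TestOpposite:
    def test_involution_pairs(self):
        assert opposite(TOP) == BOTTOM and opposite(BOTTOM) == TOP
        assert opposite(RIGHT) == LEFT and opposite(LEFT) == RIGHT
        assert opposite(UNDETERMINED) == UNDETERMINED


class TestRuleExtent:
    def test_wall_between_stacked_cells(self):
        # j below i: wall y-extent strictly between the centroids
        wall = fake_wall((3, 4), (0, 9, 4.4, 4.6))
        assert rule_extent(wall, fake_cell(3, (5, 7)), fake_cell(4, (5, 2))) == BOTTOM
        assert rule_extent(wall, fake_cell(4, (5, 2)), fake_cell(3, (5, 7))) == TOP

    def test_extent_exceeding_centroids_fails(self):
        # wall y-extent spills past both centroids of a stacked pair
        wall = fake_wall((3, 4), (0, 9, 1, 8))
        assert rule_extent(wall, fake_cell(3, (5, 2)), fake_cell(4, (5, 7))) == UNDETERMINED

    def test_both_axes_between_is_ambiguous(self):
        wall = fake_wall((3, 4), (4.4, 4.6, 4.4, 4.6))
        assert rule_extent(wall, fake_cell(3, (2, 2)), fake_cell(4, (7, 7))) == UNDETERMINED


class TestRuleAxis:
    def test_vertical_wall_right_neighbor(self):
        wall = fake_wall((3, 4), (4, 4, 0, 9), angle_deg=90.0)
        assert rule_axis(wall, fake_cell(3, (2, 5)), fake_cell(4, (7, 5))) == RIGHT

    def test_horizontal_wall_top_neighbor(self):
        wall = fake_wall((3, 4), (0, 9, 4, 4), angle_deg=0.0)
        assert rule_axis(wall, fake_cell(3, (5, 2)), fake_cell(4, (5, 7))) == TOP

    def test_exactly_45_degrees_undetermined(self):
        wall = fake_wall((3, 4), (0, 9, 0, 9), angle_deg=45.0)
        assert rule_axis(wall, fake_cell(3, (2, 2)), fake_cell(4, (7, 7))) == UNDETERMINED


class TestRuleRectangle:
    def test_i_above_j_below(self):
        wall = fake_wall((3, 4), (0, 9, 4, 5))
        assert rule_rectangle(wall, fake_cell(3, (5, 8)), fake_cell(4, (5, 1))) == BOTTOM

    def test_same_side_undetermined(self):
        wall = fake_wall((3, 4), (0, 9, 4, 5))
        assert rule_rectangle(wall, fake_cell(3, (5, 8)), fake_cell(4, (5, 7))) == UNDETERMINED

    def test_rect_containing_both_centroids(self):
        wall = fake_wall((3, 4), (0, 9, 0, 9))
        assert rule_rectangle(wall, fake_cell(3, (3, 3)), fake_cell(4, (6, 6))) == UNDETERMINED


class TestDirectOrientation:
    def test_all_rules_agree(self):
        wall = fake_wall((3, 4), (4.5, 4.5, 2, 7), angle_deg=90.0)
        ci, cj = fake_cell(3, (2, 4.5)), fake_cell(4, (7, 4.5))
        assert rule_extent(wall, ci, cj) == RIGHT
        assert rule_axis(wall, ci, cj) == RIGHT
        assert rule_rectangle(wall, ci, cj) == RIGHT
        assert direct_orientation(wall, ci, cj) == RIGHT

    def test_partial_agreement_accepted(self):
        # only the axis rule fires (extent and rectangle are ambiguous)
        wall = fake_wall((3, 4), (4.5, 4.5, 4.5, 4.5), angle_deg=90.0)
        ci, cj = fake_cell(3, (2, 2)), fake_cell(4, (7, 7))
        assert rule_extent(wall, ci, cj) == UNDETERMINED
        assert rule_rectangle(wall, ci, cj) == UNDETERMINED
        assert rule_axis(wall, ci, cj) == RIGHT
        assert direct_orientation(wall, ci, cj) == RIGHT

    def test_disagreement_undetermined(self):
        # axis says RIGHT, extent and rectangle say TOP
        wall = fake_wall((3, 4), (4, 5, 4, 5), angle_deg=90.0)
        ci, cj = fake_cell(3, (4.2, 1)), fake_cell(4, (4.8, 8))
        assert rule_axis(wall, ci, cj) == RIGHT
        assert rule_rectangle(wall, ci, cj) == TOP
        assert direct_orientation(wall, ci, cj) == UNDETERMINED


@pytest.mark.parametrize("rows,cols", [(2, 2), (1, 2), (2, 1), (3, 5), (8, 8)])
def test_grid_oracle_full_resolution(rows, cols):
    """Every internal wall of a rectangular grid resolves to the true code."""
    img, truth = mg.make_grid_layout(rows, cols, cell_px=10, wall_px=2)
    model = mg.extract_structural_model(grid_from_array(img))
    report = mg.orient_all(model)
    internal_unresolved = [p for p in report.unresolved if p[0] >= 3]
    assert internal_unresolved == []
    for (i, j), code in truth.orientations.items():
        assert model.orientation(i, j) == code


@pytest.mark.parametrize("fixture", ["grid_2x2", "grid_8x8", "roottip"])
def test_orientation_matrix_antisymmetry(fixture, request):
    _, _, model = request.getfixturevalue(fixture)
    M = model.orientation_matrix
    for i in range(M.shape[0]):
        for j in range(M.shape[1]):
            assert M[j, i] == opposite(int(M[i, j]))


def test_determinism_bit_identical():
    img, _ = mg.make_grid_layout(4, 4, cell_px=8, wall_px=2)
    models = []
    for _ in range(2):
        m = mg.extract_structural_model(grid_from_array(img))
        mg.orient_all(m)
        models.append(m)
    np.testing.assert_array_equal(models[0].orientation_matrix, models[1].orientation_matrix)
    np.testing.assert_array_equal(models[0].length_matrix, models[1].length_matrix)


def hand_built_common_neighbor_model():
    """Four cells: i = 3 on top, j = 6 below, q = 4 right of both, q' = 5 left.

    Rectangular grids contain no cell triangles, so the common-neighbor
    rules are exercised on a hand-assembled model whose flanking codes are
    set explicitly.
    """
    cells = {
        3: fake_cell(3, (0.0, 10.0)),
        4: fake_cell(4, (5.0, 5.0)),
        5: fake_cell(5, (-5.0, 5.0)),
        6: fake_cell(6, (2.0, 0.0)),
    }
    pairs = [(3, 4), (3, 5), (3, 6), (4, 6), (5, 6)]
    walls = [fake_wall(p, (0.0, 1.0, 0.0, 1.0)) for p in pairs]
    from morphogrid.walls import build_structural_model

    return build_structural_model(cells, walls)


class TestNeighborResolution:
    def test_perpendicularity_rule(self):
        # (3, 4) and (6, 4) both vertical -> (3, 6) is perpendicular;
        # j = 6 sits below i = 3, so the code is "bottom"
        model = hand_built_common_neighbor_model()
        model.set_orientation(3, 4, RIGHT)
        model.set_orientation(4, 6, LEFT)  # code(6, 4) = RIGHT
        pending, ambiguous, n = mg.resolve_via_neighbors(model, [(3, 6)])
        assert pending == [] and n == 1
        assert model.orientation(3, 6) == BOTTOM
        assert model.orientation(6, 3) == TOP

    def test_corner_rule(self):
        # (3, 4) vertical, (4, 6) horizontal with code(4, 6) = "bottom";
        # i = 3 is above j = 6, so (3, 6) inherits "bottom"
        model = hand_built_common_neighbor_model()
        model.cells[6].centroid = (0.0, 0.0)  # align i and j in x
        model.set_orientation(3, 4, RIGHT)
        model.set_orientation(4, 6, BOTTOM)
        pending, ambiguous, n = mg.resolve_via_neighbors(model, [(3, 6)])
        assert pending == [] and n == 1
        assert model.orientation(3, 6) == BOTTOM

    def test_conflicting_verdicts_stay_unresolved(self):
        # neighbor 4 implies "bottom", corrupted neighbor 5 implies "right"
        model = hand_built_common_neighbor_model()
        model.set_orientation(3, 4, RIGHT)
        model.set_orientation(4, 6, LEFT)
        model.set_orientation(3, 5, TOP)
        model.set_orientation(5, 6, TOP)  # code(6, 5) = BOTTOM: both horizontal
        pending, ambiguous, n = mg.resolve_via_neighbors(model, [(3, 6)])
        assert (3, 6) in pending and (3, 6) in ambiguous and n == 0
        assert model.orientation(3, 6) == UNDETERMINED

    def test_resolution_never_changes_resolved_codes(self, grid_8x8):
        _, _, model = grid_8x8
        before = model.orientation_matrix.copy()
        pending, ambiguous, n = mg.resolve_via_neighbors(model, [])
        assert n == 0
        np.testing.assert_array_equal(model.orientation_matrix, before)


class TestCorrections:
    def test_apply_sets_opposite(self, grid_2x2):
        _, _, model = grid_2x2
        table = CorrectionTable([Correction(3, 4, TOP)])
        mg.apply_corrections(model, table)
        assert model.orientation(3, 4) == TOP
        assert model.orientation(4, 3) == BOTTOM

    def test_non_adjacent_pair_rejected(self, grid_2x2):
        _, _, model = grid_2x2
        with pytest.raises(CorrectionError, match=r"\(3, 6\)"):
            mg.apply_corrections(model, CorrectionTable([Correction(3, 6, TOP)]))

    def test_empty_table_is_identity(self, grid_2x2):
        _, _, model = grid_2x2
        before = model.orientation_matrix.copy()
        mg.apply_corrections(model, CorrectionTable([]))
        np.testing.assert_array_equal(model.orientation_matrix, before)

    def test_strict_mode_raises_on_unresolved(self):
        img, _ = mg.make_grid_layout(2, 2, cell_px=10, wall_px=2)
        model = mg.extract_structural_model(grid_from_array(img))
        with pytest.raises(UnresolvedWallsError):
            mg.orient_all(model, strict=True)  # exterior corner walls stay open


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_jitter_robustness(seed):
    """Direct rules never assign a wrong code on jittered grids."""
    img, truth = mg.make_jittered_layout(4, 4, 20, 2, jitter_frac=0.2, seed=seed)
    model = mg.extract_structural_model(grid_from_array(img))
    report = mg.orient_all(model)
    for (i, j), code in truth.orientations.items():
        got = model.orientation(i, j)
        assert got in (UNDETERMINED, code)
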