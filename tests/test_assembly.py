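"""Model-spec binding, unit rescaling and the compiled ODE right-hand side."""

import numpy as np
import pytest

import morphogrid as mg
from morphogrid.assembly import (
    AnnotationError,
    Boundary,
    CompilationError,
    SpecValidationError,
)
from morphogrid.layout import grid_from_array
from conftest import two_cell_diffusion_system


class TestAnnotation:
    def test_explicit_map(self, grid_2x2):
        _, _, model = grid_2x2
        mg.annotate_cell_types(model, {3: "a", 4: "b", 5: "a", 6: "b"})
        assert model.cells[4].cell_type == "b"

    def test_centroid_rule(self, grid_8x8):
        _, truth, model = grid_8x8
        w = model.labels.shape[1]
        mg.annotate_cell_types(
            model, lambda x, y: "left" if x < w / 2 else "right"
        )
        for (r, c), cid in truth.ids.items():
            assert model.cells[cid].cell_type == ("left" if c < 4 else "right")

    def test_missing_id_rejected(self, grid_2x2):
        _, _, model = grid_2x2
        with pytest.raises(AnnotationError, match="5"):
            mg.annotate_cell_types(model, {3: "a", 4: "a", 6: "a"})

    def test_unknown_label_rejected(self, grid_2x2):
        _, _, model = grid_2x2
        with pytest.raises(AnnotationError, match="weird"):
            mg.annotate_cell_types(
                model, {i: "weird" for i in model.cell_ids}, allowed=["a"]
            )


class TestRescaleUnits:
    def test_identity_factor(self, grid_2x2):
        _, _, model = grid_2x2
        scaled = mg.rescale_units(model, 1.0)
        assert scaled.cells[3].area == model.cells[3].area
        np.testing.assert_array_equal(scaled.length_matrix, model.length_matrix)

    def test_scaling_laws(self, grid_2x2):
        _, _, model = grid_2x2
        scaled = mg.rescale_units(model, 0.5)
        assert scaled.cells[3].area == pytest.approx(model.cells[3].area * 0.25)
        assert scaled.cells[3].perimeter == pytest.approx(model.cells[3].perimeter * 0.5)
        np.testing.assert_allclose(scaled.length_matrix, model.length_matrix * 0.5)

    def test_inverse_recovers(self, grid_2x2):
        _, _, model = grid_2x2
        back = mg.rescale_units(mg.rescale_units(model, 3.7), 1 / 3.7)
        assert back.cells[5].area == pytest.approx(model.cells[5].area, rel=1e-12)

    def test_non_positive_factor_rejected(self, grid_2x2):
        _, _, model = grid_2x2
        with pytest.raises(ValueError):
            mg.rescale_units(model, 0.0)


class TestSpecValidation:
    def test_mobile_needs_transport(self):
        with pytest.raises(SpecValidationError, match="transport"):
            mg.ModelSpec(substances=[mg.Substance("a", mobile=True)])

    def test_unknown_cell_type_in_equations(self):
        with pytest.raises(SpecValidationError, match="ghost"):
            mg.ModelSpec(
                substances=[mg.Substance("a")],
                equations={"ghost": {"a": []}},
            )


def two_cell_closed_form(system, model, t):
    """Analytic solution of symmetric 2-cell diffusion: exponential to the mean."""
    i, j = model.cell_ids
    s = model.length_matrix[i - 1, j - 1]
    V = model.cells[i].area
    P = system.spec.transport["a"].permeability
    rate = 2 * P * s / V
    return rate, np.exp(-rate * np.asarray(t))


class TestCompiledSystem:
    def test_two_cell_diffusion_matches_closed_form(self):
        system, model, _ = two_cell_diffusion_system()
        y0 = np.array([1.0, 0.0])
        t = np.linspace(0.0, 3.0, 21)[1:]
        rate, decay = two_cell_closed_form(system, model, t)
        traj = mg.integrate(system, y0, t[-1], rtol=1e-8, atol=1e-12, t_eval=t)
        exact_a = 0.5 + 0.5 * decay
        exact_b = 0.5 - 0.5 * decay
        np.testing.assert_allclose(traj.states[:, 0], exact_a, rtol=1e-5)
        np.testing.assert_allclose(traj.states[:, 1], exact_b, rtol=1e-5, atol=1e-7)

    def test_uniform_state_has_zero_rhs(self, grid_8x8):
        _, _, model = grid_8x8
        mg.annotate_cell_types(model, {i: "default" for i in model.cell_ids})
        spec = mg.ModelSpec(
            substances=[mg.Substance("a", mobile=True)],
            transport={"a": mg.TransportParams(permeability=2.0)},
            initial={"*": {"a": 1.5}},
        )
        system = mg.compile_rhs(spec, model)
        np.testing.assert_allclose(system.rhs(0.0, system.initial_state()), 0.0, atol=1e-14)

    def test_immobile_substance_is_local(self, grid_2x2):
        _, _, model = grid_2x2
        mg.annotate_cell_types(model, {i: "default" for i in model.cell_ids})
        spec = mg.ModelSpec(
            substances=[mg.Substance("x")],
            equations={"*": {"x": [
                mg.ReactionTerm("michaelis_menten", {"Vmax": 1.0, "Km": 0.5}),
                mg.ReactionTerm("linear_decay", {"k": 0.2}),
            ]}},
        )
        system = mg.compile_rhs(spec, model)
        y = np.array([0.5, 1.0, 1.5, 2.0])
        base = system.rhs(0.0, y)
        bumped = y.copy()
        bumped[2] += 1.0
        diff = system.rhs(0.0, bumped) - base
        assert diff[0] == diff[1] == diff[3] == 0.0
        assert diff[2] != 0.0

    def test_conservation_transport_only(self, grid_8x8):
        _, _, model = grid_8x8
        mg.annotate_cell_types(model, {i: "default" for i in model.cell_ids})
        spec = mg.ModelSpec(
            substances=[mg.Substance("a", mobile=True)],
            transport={"a": mg.TransportParams(permeability=1.0, k_act=0.3,
                                               carriers={"default": {"top": 1.0}})},
        )
        system = mg.compile_rhs(spec, model)
        rng = np.random.default_rng(0)
        y0 = rng.uniform(0.5, 2.0, system.n)
        traj = mg.integrate(system, y0, 1000.0, rtol=1e-8, atol=1e-11)
        total0 = float(system.volumes @ y0)
        total1 = float(system.volumes @ traj.final())
        assert abs(total1 - total0) / total0 < 1e-6

    def test_permutation_equivariance(self, grid_2x2):
        _, _, model = grid_2x2
        mg.annotate_cell_types(model, {i: "default" for i in model.cell_ids})
        spec = mg.ModelSpec(
            substances=[mg.Substance("a", mobile=True)],
            equations={"*": {"a": [mg.ReactionTerm("linear_decay", {"k": 0.1})]}},
            transport={"a": mg.TransportParams(permeability=1.0)},
        )
        system = mg.compile_rhs(spec, model)

        # relabel cells by the permutation 3->5, 5->6, 6->4, 4->3
        perm = {3: 5, 5: 6, 6: 4, 4: 3}
        pmat = {i - 1: perm.get(i, i) - 1 for i in range(1, model.dim + 1)}
        idx = np.argsort([pmat[k] for k in range(model.dim)])

        import copy
        from dataclasses import replace

        permuted = copy.copy(model)
        permuted.cells = {perm.get(i, i): replace(c, id=perm.get(i, i))
                          for i, c in model.cells.items()}
        remap = np.empty(model.dim, dtype=int)
        for k in range(model.dim):
            remap[k] = pmat[k]
        P = np.zeros((model.dim, model.dim))
        P[remap, np.arange(model.dim)] = 1.0
        permuted.adjacency = P @ model.adjacency @ P.T > 0
        permuted.length_matrix = P @ model.length_matrix @ P.T
        permuted.width_matrix = P @ model.width_matrix @ P.T
        permuted.orientation_matrix = (P @ model.orientation_matrix @ P.T).astype(np.int8)
        permuted.walls = {
            tuple(sorted((perm.get(i, i), perm.get(j, j)))): replace(
                rec, pair=tuple(sorted((perm.get(i, i), perm.get(j, j))))
            )
            for (i, j), rec in model.walls.items()
        }
        system_p = mg.compile_rhs(spec, permuted)

        rng = np.random.default_rng(1)
        y = rng.uniform(0.1, 2.0, system.n)
        # cell order is ascending id; permute the state accordingly
        inv = {perm.get(i, i): i for i in system.cell_ids}
        y_p = np.array([y[system.cell_ids.index(inv[i])] for i in system_p.cell_ids])
        d = system.rhs(0.0, y)
        d_p = system_p.rhs(0.0, y_p)
        expected = np.array([d[system.cell_ids.index(inv[i])] for i in system_p.cell_ids])
        np.testing.assert_allclose(d_p, expected, rtol=0, atol=1e-13)

    def test_fixed_boundary_relaxes_to_reservoir(self):
        img, _ = mg.make_grid_layout(1, 2, cell_px=10, wall_px=2)
        model = mg.extract_structural_model(grid_from_array(img))
        mg.orient_all(model)
        mg.annotate_cell_types(model, {i: "default" for i in model.cell_ids})
        spec = mg.ModelSpec(
            substances=[mg.Substance("a", mobile=True)],
            transport={"a": mg.TransportParams(permeability=1.0)},
            boundary={1: Boundary(kind="fixed", fixed={"a": 2.0})},
        )
        system = mg.compile_rhs(spec, model)
        ss = mg.find_steady_state(system, np.zeros(system.n), tol_rel=1e-10)
        assert ss.converged
        np.testing.assert_allclose(ss.state, 2.0, rtol=1e-6)

    def test_unresolved_orientation_with_carriers_fails(self):
        img, _ = mg.make_grid_layout(1, 2, cell_px=10, wall_px=2)
        model = mg.extract_structural_model(grid_from_array(img))  # not oriented
        mg.annotate_cell_types(model, {i: "default" for i in model.cell_ids})
        spec = mg.ModelSpec(
            substances=[mg.Substance("a", mobile=True)],
            transport={"a": mg.TransportParams(
                permeability=1.0, k_act=1.0, carriers={"default": {"right": 1.0}}
            )},
        )
        with pytest.raises(CompilationError, match="unresolved"):
            mg.compile_rhs(spec, model)

    def test_unknown_cell_type_label_fails(self, grid_2x2):
        _, _, model = grid_2x2
        mg.annotate_cell_types(model, {i: "mystery" for i in model.cell_ids})
        spec = mg.ModelSpec(substances=[mg.Substance("a")])
        with pytest.raises(CompilationError, match="mystery"):
            mg.compile_rhs(spec, model)
        mg.annotate_cell_types(model, {i: "default" for i in model.cell_ids})

    def test_dynamic_carrier_scales_flux(self):
        img, _ = mg.make_grid_layout(1, 2, cell_px=10, wall_px=2)
        model = mg.extract_structural_model(grid_from_array(img))
        mg.orient_all(model)
        mg.annotate_cell_types(model, {i: "default" for i in model.cell_ids})
        spec = mg.ModelSpec(
            substances=[mg.Substance("a", mobile=True), mg.Substance("pin")],
            transport={"a": mg.TransportParams(
                k_act=0.5, carriers={"default": {"right": "pin"}}
            )},
        )
        system = mg.compile_rhs(spec, model)
        # state: a in both cells, then pin in both cells
        d1 = system.rhs(0.0, np.array([1.0, 0.0, 1.0, 0.0]))
        d2 = system.rhs(0.0, np.array([1.0, 0.0, 2.0, 0.0]))
        assert d2[0] == pytest.approx(2 * d1[0])
        assert d1[0] < 0  # left cell exports rightward
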