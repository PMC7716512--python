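import numpy as np
import pytest

import morphogrid as mg


@pytest.fixture()
def grid_2x2():
    """2x2 grid layout, extracted and oriented (fresh per test: mutable)."""
    img, truth = mg.make_grid_layout(2, 2, cell_px=10, wall_px=2)
    model = mg.extract_structural_model(mg.grid_from_array(img))
    mg.orient_all(model)
    return img, truth, model


@pytest.fixture(scope="session")
def grid_8x8():
    """8x8 grid layout at the reference geometry, extracted and oriented."""
    img, truth = mg.make_grid_layout(8, 8, cell_px=20, wall_px=2)
    model = mg.extract_structural_model(mg.grid_from_array(img))
    mg.orient_all(model)
    return img, truth, model


@pytest.fixture(scope="session")
def roottip():
    """Root-tip layout with typed files, extracted, oriented and annotated."""
    img, truth = mg.make_roottip_layout(
        ["epidermis", "cortex", "vascular", "cortex", "epidermis"],
        rows=8, cap_rows=2, cell_px=14, wall_px=2,
    )
    model = mg.extract_structural_model(mg.grid_from_array(img))
    mg.orient_all(model)
    mg.annotate_cell_types(model, truth.type_map())
    return img, truth, model


def two_cell_diffusion_system(permeability=1.0):
    """1x2 layout with one mobile substance and pure passive transport."""
    img, truth = mg.make_grid_layout(1, 2, cell_px=10, wall_px=2)
    model = mg.extract_structural_model(mg.grid_from_array(img))
    mg.orient_all(model)
    spec = mg.ModelSpec(
        substances=[mg.Substance("a", mobile=True)],
        transport={"a": mg.TransportParams(permeability=permeability)},
    )
    mg.annotate_cell_types(model, {i: "default" for i in model.cell_ids})
    system = mg.compile_rhs(spec, model)
    return system, model, truth
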