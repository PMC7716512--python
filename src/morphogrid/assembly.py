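"""Bind a model specification to a structural model and compile the ODE rhs.

The model specification declares substances (mobile or not), cell types,
per-type reaction terms, transport parameters with carrier placement by
wall side, boundary conditions toward the exterior (id 1) and excluded
tissue (id 2), and initial concentrations.  Compilation resolves the
specification against a :class:`~morphogrid.walls.StructuralModel` into a
flat state vector and a vectorized right-hand-side function.

For a mobile substance A in cell i of type tau:

    dA_i/dt = sum of reaction terms(tau, A)
            + (1/V_i) * sum over adjacent j of
                [ P*s_ij*(A_j - A_i) + k_act*s_ij*(c_ji*A_j - c_ij*A_i) ]

where V_i is the cell cross-sectional area (2D volume proxy), s_ij the
wall contact length and c_ij the carrier amount of cell i on its (i, j)
wall, resolved from (cell type, wall orientation).  Immobile substances
keep only the reaction terms.  State ordering: substances outermost,
cells innermost ascending by id.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from .kinetics import ReactionTerm, TransportParams
from .orientation import CODE_BY_NAME, SIDE_NAMES, UNDETERMINED
from .walls import StructuralModel

__all__ = [
    "Substance",
    "Boundary",
    "ModelSpec",
    "CompiledSystem",
    "AnnotationError",
    "CompilationError",
    "SpecValidationError",
    "annotate_cell_types",
    "rescale_units",
    "compile_rhs",
    "load_model_spec",
    "spec_from_dict",
    "spec_to_dict",
]


class AnnotationError(ValueError):
    """Cell-type annotation does not cover the model or uses unknown labels."""


class CompilationError(ValueError):
    """The spec cannot be resolved against the structural model."""


class SpecValidationError(ValueError):
    """The model specification is internally inconsistent."""


@dataclass(frozen=True)
class Substance:
    name: str
    mobile: bool = False


@dataclass(frozen=True)
class Boundary:
    """Boundary condition toward region 1 (exterior) or 2 (excluded).

    ``closed`` omits all flux terms across such walls; ``fixed`` treats
    the outside as a reservoir of constant concentration per substance.
    """

    kind: str = "closed"
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("closed", "fixed"):
            raise SpecValidationError(f"boundary kind must be closed|fixed, got {self.kind!r}")
        if any(v < 0 for v in self.fixed.values()):
            raise SpecValidationError("fixed boundary concentrations must be >= 0")


_CLOSED = Boundary()


@dataclass
class ModelSpec:
    """Declarative ODE model over a cell layout.

    ``equations`` and ``initial`` are keyed by cell type; the wildcard
    type ``"*"`` applies to every type and is combined with (before) any
    type-specific entries.
    """

    substances: list[Substance]
    cell_types: list[str] = field(default_factory=lambda: ["default"])
    equations: dict[str, dict[str, list[ReactionTerm]]] = field(default_factory=dict)
    transport: dict[str, TransportParams] = field(default_factory=dict)
    boundary: dict[int, Boundary] = field(default_factory=dict)
    parameters: dict[str, float] = field(default_factory=dict)
    initial: dict[str, dict[str, float]] = field(default_factory=dict)
    unit_scale: float = 1.0

    def __post_init__(self) -> None:
        names = [s.name for s in self.substances]
        if len(set(names)) != len(names):
            raise SpecValidationError("duplicate substance names")
        known = set(self.cell_types) | {"*"}
        for t in list(self.equations) + list(self.initial):
            if t not in known:
                raise SpecValidationError(f"equations/initial reference unknown cell type {t!r}")
        for s in self.substances:
            if s.mobile and s.name not in self.transport:
                raise SpecValidationError(f"mobile substance {s.name!r} has no transport entry")
        for name in self.transport:
            if name not in names:
                raise SpecValidationError(f"transport references unknown substance {name!r}")

    def substance_names(self) -> list[str]:
        return [s.name for s in self.substances]

    def terms_for(self, cell_type: str, substance: str) -> list[ReactionTerm]:
        out: list[ReactionTerm] = []
        for t in ("*", cell_type):
            out.extend(self.equations.get(t, {}).get(substance, []))
        return out

    def initial_for(self, cell_type: str, substance: str) -> float:
        for t in (cell_type, "*"):
            v = self.initial.get(t, {}).get(substance)
            if v is not None:
                return float(v)
        return 0.0

    def boundary_for(self, region_id: int) -> Boundary:
        return self.boundary.get(region_id, _CLOSED)


def annotate_cell_types(
    model: StructuralModel,
    annotation: Mapping[int, str] | Callable[[float, float], str],
    allowed: Sequence[str] | None = None,
) -> StructuralModel:
    """Attach a type label to every cell (ids >= 3), in place.

    ``annotation`` is either an explicit id -> label map covering every
    cell, or a rule mapping the cell centroid ``(x, y)`` to a label.
    """
    ids = model.cell_ids
    if callable(annotation):
        labels = {i: annotation(*model.cells[i].centroid) for i in ids}
    else:
        missing = [i for i in ids if i not in annotation]
        if missing:
            raise AnnotationError(f"annotation missing cell ids {missing}")
        labels = {i: annotation[i] for i in ids}
    if allowed is not None:
        bad = sorted({l for l in labels.values() if l not in set(allowed)})
        if bad:
            raise AnnotationError(f"unknown cell type labels {bad}")
    for i, label in labels.items():
        model.cells[i].cell_type = label
    return model


def rescale_units(model: StructuralModel, um_per_px: float) -> StructuralModel:
    """Return a copy with physical quantities rescaled by a µm/px factor.

    Areas scale by the factor squared, lengths and widths linearly;
    pixel-frame geometry (centroids, rectangles, ellipses) is untouched.
    """
    if um_per_px <= 0:
        raise ValueError("unit scale factor must be positive")
    f = float(um_per_px)
    out = copy.copy(model)
    out.cells = {
        i: replace(c, area=c.area * f**2, perimeter=c.perimeter * f)
        for i, c in model.cells.items()
    }
    out.walls = {
        p: replace(w, length=w.length * f, width=w.width * f)
        for p, w in model.walls.items()
    }
    out.length_matrix = model.length_matrix * f
    out.width_matrix = model.width_matrix * f
    out.pixel_size = model.pixel_size * f
    return out


@dataclass
class _Edges:
    """Precompiled directed transport terms for one mobile substance."""

    src: np.ndarray          # donor position
    dst: np.ndarray          # acceptor position
    coef: np.ndarray         # static amount/time per unit donor concentration
    dyn_rows: np.ndarray     # edge indices with a dynamic carrier
    dyn_coef: np.ndarray     # k_act * s for those edges
    dyn_subst: np.ndarray    # substance index supplying the carrier
    bc_loss: np.ndarray      # per-cell linear loss coefficient to fixed boundaries
    bc_gain: np.ndarray      # per-cell constant influx from fixed boundaries


@dataclass
class CompiledSystem:
    """A compiled ODE system over a structural model.

    ``rhs(t, y)`` maps the flat state vector to its derivative.  The state
    holds ``len(substances) * n_cells`` entries: substances outermost in
    spec order, cells innermost ascending by id.
    """

    spec: ModelSpec
    model: StructuralModel
    substances: list[str]
    cell_ids: list[int]
    volumes: np.ndarray
    _edges: dict[str, _Edges]
    _type_groups: dict[str, np.ndarray]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n(self) -> int:
        return len(self.substances) * self.n_cells

    def index(self, cell_id: int, substance: str) -> int:
        s = self.substances.index(substance)
        return s * self.n_cells + self.cell_ids.index(cell_id)

    def initial_state(self) -> np.ndarray:
        y0 = np.empty(self.n)
        for s_idx, name in enumerate(self.substances):
            for c_idx, cid in enumerate(self.cell_ids):
                y0[s_idx * self.n_cells + c_idx] = self.spec.initial_for(
                    self.model.cells[cid].cell_type, name
                )
        return y0

    def state_by_cell(self, y: np.ndarray, substance: str) -> dict[int, float]:
        s = self.substances.index(substance)
        block = y[s * self.n_cells : (s + 1) * self.n_cells]
        return {cid: float(block[k]) for k, cid in enumerate(self.cell_ids)}

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        N = self.n_cells
        y = np.asarray(y, dtype=float)
        conc = {name: y[k * N : (k + 1) * N] for k, name in enumerate(self.substances)}
        # reaction terms see concentrations clipped at zero: the rate laws
        # are defined on [0, inf) and the solver may undershoot slightly
        pos = {name: np.maximum(v, 0.0) for name, v in conc.items()}
        d = np.zeros_like(y)

        for s_idx, name in enumerate(self.substances):
            ds = d[s_idx * N : (s_idx + 1) * N]
            for cell_type, idx in self._type_groups.items():
                terms = self.spec.terms_for(cell_type, name)
                if not terms:
                    continue
                local = {k: v[idx] for k, v in pos.items()}
                target = local[name]
                for term in terms:
                    ds[idx] += term.rate(target, local)

        for name, e in self._edges.items():
            s_idx = self.substances.index(name)
            ds = d[s_idx * N : (s_idx + 1) * N]
            a = conc[name]
            coef = e.coef
            if len(e.dyn_rows):
                coef = coef.copy()
                carrier = np.empty(len(e.dyn_rows))
                for k, row in enumerate(e.dyn_rows):
                    carrier[k] = max(conc[self.substances[e.dyn_subst[k]]][e.src[row]], 0.0)
                coef[e.dyn_rows] += e.dyn_coef * carrier
            transfer = coef * a[e.src]          # amount/time leaving each donor
            np.subtract.at(ds, e.src, transfer / self.volumes[e.src])
            np.add.at(ds, e.dst, transfer / self.volumes[e.dst])
            ds += (e.bc_gain - e.bc_loss * a) / self.volumes
        return d


def _resolve_carrier(
    tp: TransportParams,
    cell_type: str,
    code: int,
) -> float | str:
    """Carrier amount (or dynamic substance name) for a donor wall side."""
    placement = tp.carriers.get(cell_type, {})
    if not placement:
        return 0.0
    side = SIDE_NAMES.get(code)
    if side is None:
        return 0.0
    return placement.get(side, 0.0)


def compile_rhs(spec: ModelSpec, model: StructuralModel) -> CompiledSystem:
    """Resolve the specification against the layout into an ODE system."""
    cell_ids = model.cell_ids
    if not cell_ids:
        raise CompilationError("structural model has no cells")
    pos = {cid: k for k, cid in enumerate(cell_ids)}
    known_types = set(spec.cell_types)
    bad_types = sorted(
        {model.cells[i].cell_type for i in cell_ids} - known_types
    )
    if bad_types:
        raise CompilationError(
            f"cells carry type labels absent from the spec: {bad_types}"
        )
    substances = spec.substance_names()
    mobile = {s.name for s in spec.substances if s.mobile}
    volumes = np.array([model.cells[i].area for i in cell_ids], dtype=float)

    # check that regulators referenced by equations exist
    for t, eqs in spec.equations.items():
        for target, terms in eqs.items():
            if target not in substances:
                raise CompilationError(f"equation target {target!r} is not a substance")
            for term in terms:
                for r in term.regulators:
                    if r not in substances:
                        raise CompilationError(
                            f"term regulator {r!r} is not a substance"
                        )

    type_groups: dict[str, np.ndarray] = {}
    for t in sorted({model.cells[i].cell_type for i in cell_ids}):
        type_groups[t] = np.array(
            [pos[i] for i in cell_ids if model.cells[i].cell_type == t], dtype=int
        )

    edges: dict[str, _Edges] = {}
    for name in substances:
        if name not in mobile:
            continue
        tp = spec.transport[name]
        needs_orientation = any(tp.carriers.get(t) for t in known_types) or bool(
            tp.orientation_factors
        )
        src, dst, coef = [], [], []
        dyn_rows, dyn_coef, dyn_subst = [], [], []
        bc_loss = np.zeros(len(cell_ids))
        bc_gain = np.zeros(len(cell_ids))
        unresolved_walls: list[tuple[int, int]] = []

        def wall_factor(i: int, j: int) -> float:
            s = model.length_matrix[i - 1, j - 1]
            if tp.width_scaled:
                s *= model.width_matrix[i - 1, j - 1]
            return s

        for (i, j) in sorted(model.walls):
            boundary_pair = i < 3 or j < 3
            if boundary_pair:
                b, c = (i, j) if i < 3 else (j, i)  # b boundary region, c cell
                bc = spec.boundary_for(b)
                if bc.kind == "closed":
                    continue
                code = model.orientation(c, b)
                ctype = model.cells[c].cell_type
                if needs_orientation and code == UNDETERMINED and tp.carriers.get(ctype):
                    unresolved_walls.append((c, b))
                    continue
                s = wall_factor(c, b)
                factor = tp.orientation_factors.get(SIDE_NAMES.get(code, ""), 1.0)
                carrier = _resolve_carrier(tp, ctype, code)
                if isinstance(carrier, str):
                    raise CompilationError(
                        "dynamic carriers are not supported on boundary walls"
                    )
                a_out = float(bc.fixed.get(name, 0.0))
                k = pos[c]
                bc_loss[k] += tp.permeability * factor * s + tp.k_act * s * carrier
                bc_gain[k] += tp.permeability * factor * s * a_out
                continue
            for donor, acceptor in ((i, j), (j, i)):
                code = model.orientation(donor, acceptor)
                ctype = model.cells[donor].cell_type
                if needs_orientation and code == UNDETERMINED and tp.carriers.get(ctype):
                    if (min(i, j), max(i, j)) not in unresolved_walls:
                        unresolved_walls.append((min(i, j), max(i, j)))
                    continue
                s = wall_factor(donor, acceptor)
                factor = tp.orientation_factors.get(SIDE_NAMES.get(code, ""), 1.0)
                carrier = _resolve_carrier(tp, ctype, code)
                c_static = 0.0
                dyn_name = None
                if isinstance(carrier, str):
                    dyn_name = carrier
                else:
                    c_static = float(carrier)
                row = len(src)
                src.append(pos[donor])
                dst.append(pos[acceptor])
                coef.append(tp.permeability * factor * s + tp.k_act * s * c_static)
                if dyn_name is not None:
                    if dyn_name not in substances or dyn_name in mobile:
                        raise CompilationError(
                            f"dynamic carrier {dyn_name!r} must be an immobile substance"
                        )
                    dyn_rows.append(row)
                    dyn_coef.append(tp.k_act * s)
                    dyn_subst.append(substances.index(dyn_name))
        if unresolved_walls:
            raise CompilationError(
                f"carrier placement for {name!r} needs orientations, but walls "
                f"{sorted(set(unresolved_walls))} are unresolved"
            )
        edges[name] = _Edges(
            src=np.array(src, dtype=int),
            dst=np.array(dst, dtype=int),
            coef=np.array(coef, dtype=float),
            dyn_rows=np.array(dyn_rows, dtype=int),
            dyn_coef=np.array(dyn_coef, dtype=float),
            dyn_subst=np.array(dyn_subst, dtype=int),
            bc_loss=bc_loss,
            bc_gain=bc_gain,
        )

    system = CompiledSystem(
        spec=spec,
        model=model,
        substances=substances,
        cell_ids=cell_ids,
        volumes=volumes,
        _edges=edges,
        _type_groups=type_groups,
    )
    # the compiled rhs must be evaluable at the initial state
    system.rhs(0.0, system.initial_state())
    return system


# ---------------------------------------------------------------------------
# YAML model configuration


def _term_from_dict(d: Mapping) -> ReactionTerm:
    d = dict(d)
    kind = d.pop("kind")
    regs: tuple[str, ...] = ()
    if "regulator" in d:
        regs = (d.pop("regulator"),)
    elif "regulators" in d:
        regs = tuple(d.pop("regulators"))
    return ReactionTerm(kind=kind, params=d, regulators=regs)


def _term_to_dict(t: ReactionTerm) -> dict:
    d = {"kind": t.kind, **t.params}
    if len(t.regulators) == 1:
        d["regulator"] = t.regulators[0]
    elif t.regulators:
        d["regulators"] = list(t.regulators)
    return d


def spec_from_dict(raw: Mapping) -> ModelSpec:
    """Build a ModelSpec from the parsed YAML model configuration."""
    substances = [
        Substance(name=s["name"], mobile=bool(s.get("mobile", False)))
        for s in raw.get("substances", [])
    ]
    cell_types = list(raw.get("cell_types", ["default"]))
    equations = {
        ct: {
            subst: [_term_from_dict(t) for t in terms]
            for subst, terms in eqs.items()
        }
        for ct, eqs in raw.get("equations", {}).items()
    }
    transport = {}
    for name, t in raw.get("transport", {}).items():
        transport[name] = TransportParams(
            permeability=float(t.get("permeability", 0.0)),
            k_act=float(t.get("k_act", 0.0)),
            carriers={
                ct: dict(placement) for ct, placement in t.get("carriers", {}).items()
            },
            orientation_factors=dict(t.get("orientation_factors", {})),
            width_scaled=bool(t.get("width_scaled", False)),
        )
    boundary = {}
    for rid, b in raw.get("boundary", {}).items():
        if b == "closed":
            boundary[int(rid)] = Boundary()
        else:
            boundary[int(rid)] = Boundary(kind="fixed", fixed=dict(b.get("fixed", b)))
    initial = {ct: dict(v) for ct, v in raw.get("initial", {}).items()}
    units = raw.get("units", {})
    return ModelSpec(
        substances=substances,
        cell_types=cell_types,
        equations=equations,
        transport=transport,
        boundary=boundary,
        parameters=dict(raw.get("parameters", {})),
        initial=initial,
        unit_scale=float(units.get("pixel_size", 1.0)),
    )


def spec_to_dict(spec: ModelSpec) -> dict:
    """Serialize a ModelSpec to a YAML-ready dictionary."""
    out: dict = {
        "substances": [{"name": s.name, "mobile": s.mobile} for s in spec.substances],
        "cell_types": list(spec.cell_types),
        "equations": {
            ct: {subst: [_term_to_dict(t) for t in terms] for subst, terms in eqs.items()}
            for ct, eqs in spec.equations.items()
        },
        "transport": {},
        "boundary": {},
        "initial": {ct: dict(v) for ct, v in spec.initial.items()},
        "units": {"pixel_size": spec.unit_scale},
    }
    for name, t in spec.transport.items():
        entry: dict = {"permeability": t.permeability, "k_act": t.k_act}
        if t.carriers:
            entry["carriers"] = {ct: dict(p) for ct, p in t.carriers.items()}
        if t.orientation_factors:
            entry["orientation_factors"] = dict(t.orientation_factors)
        if t.width_scaled:
            entry["width_scaled"] = True
        out["transport"][name] = entry
    for rid, b in spec.boundary.items():
        out["boundary"][rid] = "closed" if b.kind == "closed" else {"fixed": dict(b.fixed)}
    if spec.parameters:
        out["parameters"] = dict(spec.parameters)
    return out


def load_model_spec(path: str | Path) -> ModelSpec:
    """Load a model configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return spec_from_dict(raw or {})
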