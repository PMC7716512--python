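"""Stiff integration, steady-state detection and layout rendering.

Integration uses SciPy's BDF implicit variable-order method (the
backward-differentiation family used for stiff reaction-transport
systems); the method is selectable.  Steady states are detected by
integrating over doubling time windows until the infinity norm of the
right-hand side falls below a relative tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
from PIL import Image
from scipy.integrate import solve_ivp

from .assembly import CompiledSystem
from .layout import PixelClass
from .walls import StructuralModel

__all__ = [
    "Trajectory",
    "SteadyState",
    "IntegrationError",
    "DivergenceError",
    "integrate",
    "find_steady_state",
    "render_concentrations",
]


class IntegrationError(RuntimeError):
    """The stiff solver failed (for example by step-size collapse)."""


class DivergenceError(RuntimeError):
    """The state norm grew past the overflow guard; no steady state exists."""


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # (len(times), n)
    converged: bool
    final_residual: float

    def final(self) -> np.ndarray:
        return self.states[-1]


@dataclass
class SteadyState:
    state: np.ndarray
    converged: bool
    t_end: float
    residual: float


def integrate(
    system: CompiledSystem,
    y0: np.ndarray,
    t_end: float,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    t_eval: np.ndarray | None = None,
    method: str = "BDF",
) -> Trajectory:
    """Integrate the compiled system from 0 to ``t_end``."""
    y0 = np.asarray(y0, dtype=float)
    if len(y0) != system.n:
        raise ValueError(f"state length {len(y0)} != system size {system.n}")
    if t_end <= 0 or rtol <= 0 or atol <= 0:
        raise ValueError("t_end and tolerances must be positive")
    sol = solve_ivp(
        system.rhs, (0.0, float(t_end)), y0,
        method=method, rtol=rtol, atol=atol, t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")
    states = sol.y.T
    residual = float(np.max(np.abs(system.rhs(sol.t[-1], states[-1]))))
    return Trajectory(
        times=sol.t, states=states, converged=True, final_residual=residual
    )


def find_steady_state(
    system: CompiledSystem,
    y0: np.ndarray,
    tol_rel: float = 1e-8,
    t_max: float = 1e6,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "BDF",
) -> SteadyState:
    """Integrate over doubling windows until the rhs norm vanishes.

    The criterion is ``||rhs(y)||_inf < tol_rel * max(||y||_inf, atol)``.
    Returns the last state with a convergence flag; raises
    :class:`DivergenceError` when the state norm passes the overflow guard.
    """
    y = np.asarray(y0, dtype=float)

    def residual_ok(yv: np.ndarray) -> tuple[bool, float]:
        r = float(np.max(np.abs(system.rhs(0.0, yv))))
        return r < tol_rel * max(float(np.max(np.abs(yv))), atol), r

    ok, r = residual_ok(y)
    if ok:
        return SteadyState(state=y, converged=True, t_end=0.0, residual=r)
    t, window = 0.0, 1.0
    guard = 1e12
    while t < t_max:
        window = min(window, t_max - t)
        traj = integrate(system, y, window, rtol=rtol, atol=atol, method=method)
        y = traj.final()
        t += window
        window *= 2.0
        if np.max(np.abs(y)) > guard:
            raise DivergenceError(f"state norm exceeded {guard:g} at t = {t:g}")
        ok, r = residual_ok(y)
        if ok:
            return SteadyState(state=y, converged=True, t_end=t, residual=r)
    return SteadyState(state=y, converged=False, t_end=t, residual=r)


def render_concentrations(
    model: StructuralModel,
    values: dict[int, float],
    out_path: str | Path,
    colormap: str = "viridis",
    value_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Paint per-cell concentrations onto the layout and write a PNG.

    ``values`` maps cell id -> concentration.  Colors are normalized from
    the minimum to the maximum over cells unless a fixed ``value_range``
    is given; wall pixels are black and the exterior/excluded regions a
    neutral gray.  Returns the rendered RGB array.
    """
    missing = [i for i in model.cell_ids if i not in values]
    if missing:
        raise ValueError(f"no concentration value for cell ids {missing}")
    cmap = matplotlib.colormaps[colormap]
    if value_range is None:
        lo = min(values[i] for i in model.cell_ids)
        hi = max(values[i] for i in model.cell_ids)
    else:
        lo, hi = value_range
    span = hi - lo

    any_region = next(iter(model.cells.values())).region
    h = any_region.height
    if model.labels is not None:
        w = model.labels.shape[1]
    else:
        w = int(max(c.region.cols.max() for c in model.cells.values())) + 1
    img = np.zeros((h, w, 3), dtype=np.uint8)  # walls black
    gray = np.array([128, 128, 128], dtype=np.uint8)
    for i, cell in model.cells.items():
        if i < 3:
            img[cell.region.rows, cell.region.cols] = gray
            continue
        frac = 0.5 if span == 0 else (values[i] - lo) / span
        rgb = (np.array(cmap(float(np.clip(frac, 0.0, 1.0)))[:3]) * 255).round()
        img[cell.region.rows, cell.region.cols] = rgb.astype(np.uint8)
    Image.fromarray(img).save(out_path, format="PNG")
    return img
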