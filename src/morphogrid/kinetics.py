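"""Reaction and transport rate laws.

Reaction terms (per cell, per substance):

* ``constant`` — zeroth-order synthesis, rate ``c0``;
* ``linear_decay`` — first-order turnover, rate ``-k * x``;
* ``michaelis_menten`` — saturable production ``Vmax * r / (Km + r)``
  driven by a regulator r (default: the substance itself);
* ``hill_activation`` / ``hill_repression`` — ``Vmax`` times a generalized
  Hill factor of one regulator;
* ``product`` — ``Vmax`` times a product of Hill factors over several
  regulators (multiplicative gene-regulatory input function).

Transport across a wall of contact length s_ij (µm):

* passive (Fick): ``J = P * s_ij * (a_j - a_i)`` into cell i;
* active (mass action on a membrane carrier): a donor cell i with carrier
  concentration c_ij on its (i, j) wall exports ``k_act * c_ij * s_ij * a_i``.

Fluxes are amounts per time; the assembly module divides by cell area
(the 2D volume proxy) to convert to concentration change, which makes
pairwise conservation exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ReactionTerm",
    "TransportParams",
    "michaelis_menten",
    "generalized_hill",
    "passive_flux",
    "active_flux",
]


def michaelis_menten(x, Vmax: float, Km: float):
    """Saturable rate Vmax*x/(Km+x); half-maximal at x = Km."""
    x = np.asarray(x, dtype=float)
    if Km <= 0:
        raise ValueError("Km must be positive")
    if np.any(x < 0):
        raise ValueError("concentration must be non-negative")
    return Vmax * x / (Km + x)


def generalized_hill(x, K: float, h: float, mode: str = "activation"):
    """Monotone Hill factor in [0, 1].

    activation: (x/K)^h / (1 + (x/K)^h); repression: 1 / (1 + (x/K)^h).
    The two modes sum to 1 at any x, and both equal 1/2 at x = K.
    """
    x = np.asarray(x, dtype=float)
    if K <= 0 or h <= 0:
        raise ValueError("K and h must be positive")
    if np.any(x < 0):
        raise ValueError("concentration must be non-negative")
    r = (x / K) ** h
    if mode == "activation":
        return r / (1.0 + r)
    if mode == "repression":
        return 1.0 / (1.0 + r)
    raise ValueError(f"unknown Hill mode {mode!r}")


def passive_flux(a_i, a_j, P: float, s_ij: float):
    """Fickian flux P*s*(a_j - a_i), amount/time into cell i; antisymmetric."""
    if P < 0 or s_ij <= 0:
        raise ValueError("require P >= 0 and s_ij > 0")
    return P * s_ij * (np.asarray(a_j, dtype=float) - np.asarray(a_i, dtype=float))


def active_flux(a_donor, carrier, k_act: float, s_ij: float):
    """Carrier-mediated export k_act*carrier*s*a_donor, amount/time out of the donor."""
    if k_act < 0 or s_ij <= 0:
        raise ValueError("require k_act >= 0 and s_ij > 0")
    a = np.asarray(a_donor, dtype=float)
    c = np.asarray(carrier, dtype=float)
    if np.any(a < 0) or np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    return k_act * c * s_ij * a


_KINDS = {
    "constant",
    "linear_decay",
    "michaelis_menten",
    "hill_activation",
    "hill_repression",
    "product",
}


@dataclass(frozen=True)
class ReactionTerm:
    """One term of a cell-local rate equation.

    ``regulators`` names the substances the term reads (empty means the
    target substance itself where one is needed).  ``params`` holds the
    kind-specific named rates; ``product`` additionally takes ``factors``,
    a sequence of dicts with keys regulator/K/h/mode.
    """

    kind: str
    params: Mapping[str, float] = field(default_factory=dict)
    regulators: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown reaction term kind {self.kind!r}")
        p = self.params
        if self.kind == "linear_decay" and p.get("k", 0.0) < 0:
            raise ValueError("decay rate k must be >= 0")
        if self.kind in ("michaelis_menten", "hill_activation", "hill_repression", "product"):
            if p.get("Vmax", 1.0) < 0:
                raise ValueError("Vmax must be >= 0")

    def rate(self, target: np.ndarray, values: Mapping[str, np.ndarray]) -> np.ndarray:
        """Evaluate the term for a vector of cells.

        ``target`` is the target substance's concentration in those cells;
        ``values`` maps substance name to the same-shaped vectors.
        """
        p = self.params
        if self.kind == "constant":
            return np.full_like(np.asarray(target, dtype=float), p["c0"])
        if self.kind == "linear_decay":
            return -p["k"] * np.asarray(target, dtype=float)
        if self.kind == "michaelis_menten":
            x = values[self.regulators[0]] if self.regulators else target
            return michaelis_menten(x, p["Vmax"], p["Km"])
        if self.kind in ("hill_activation", "hill_repression"):
            x = values[self.regulators[0]] if self.regulators else target
            mode = "activation" if self.kind == "hill_activation" else "repression"
            return p.get("Vmax", 1.0) * generalized_hill(x, p["K"], p["h"], mode)
        # product of Hill factors
        out = np.full_like(np.asarray(target, dtype=float), p.get("Vmax", 1.0))
        for f in p["factors"]:
            out = out * generalized_hill(
                values[f["regulator"]], f["K"], f["h"], f.get("mode", "activation")
            )
        return out


@dataclass(frozen=True)
class TransportParams:
    """Transport law parameters for one mobile substance.

    ``carriers`` maps cell type -> side name ("top"/"bottom"/"right"/
    "left") -> carrier amount, or the name of an immobile substance to use
    as a dynamic, uniformly placed carrier.  ``orientation_factors``
    optionally scales the passive permeability per wall side of the donor
    cell.  ``width_scaled`` multiplies both laws by the wall width in µm.
    """

    permeability: float = 0.0
    k_act: float = 0.0
    carriers: Mapping[str, Mapping[str, float | str]] = field(default_factory=dict)
    orientation_factors: Mapping[str, float] = field(default_factory=dict)
    width_scaled: bool = False

    def __post_init__(self) -> None:
        if self.permeability < 0 or self.k_act < 0:
            raise ValueError("permeability and k_act must be >= 0")
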