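"""Initial tissue states for pericentral (CV-centered) damage.

The injury pattern starts as a fully stressed region next to the central
vein: the first ``stressed_count`` sites of a chain, or every site within
``stressed_layers`` rings of the CV on a hexagonal lobule.  An asymmetric
variant stresses each site in those layers independently with a given
probability.  The initial state never contains empty sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CellState, TissueState
from .lattice import Lattice

__all__ = ["InitSpec", "init_pericentral", "damage_count_for_fraction"]


@dataclass(frozen=True)
class InitSpec:
    """Damage convention for the initial state.

    ``mode`` is ``pericentral_count`` (chain: number of stressed sites
    nearest the CV), ``pericentral_layers`` (hex: fully stressed rings) or
    ``asymmetric_layers`` (hex: each site of those rings stressed with
    probability ``stress_probability``).
    """

    mode: str
    stressed_count: int = 0
    stressed_layers: int = 0
    stress_probability: float = 0.8

    def __post_init__(self):
        if self.mode not in ("pericentral_count", "pericentral_layers", "asymmetric_layers"):
            raise ValueError(f"unknown init mode: {self.mode!r}")
        if not 0.0 <= self.stress_probability <= 1.0:
            raise ValueError("stress_probability must lie in [0, 1]")


def damage_count_for_fraction(n_sites: int, fraction: float) -> int:
    """Stressed-site count for a damage fraction on a chain (nearest integer)."""
    return int(round(fraction * n_sites))


def init_pericentral(
    lattice: Lattice, spec: InitSpec, rng: np.random.Generator | None = None
) -> TissueState:
    """Build the initial :class:`TissueState` for a damage specification."""
    states = np.full(lattice.n_sites, int(CellState.H), dtype=np.uint8)
    if spec.mode == "pericentral_count":
        k = int(spec.stressed_count)
        if not 0 <= k <= lattice.n_sites:
            raise ValueError(
                f"stressed_count={k} outside [0, {lattice.n_sites}]"
            )
        if lattice.geometry != "chain":
            raise ValueError("pericentral_count applies to chain lattices")
        # chain sites are ordered by distance from the CV
        states[:k] = int(CellState.S)
    else:
        k = int(spec.stressed_layers)
        if not 0 <= k <= lattice.nl:
            raise ValueError(f"stressed_layers={k} outside [0, {lattice.nl}]")
        in_region = lattice.layer_of <= k
        if spec.mode == "pericentral_layers":
            states[in_region] = int(CellState.S)
        else:
            if rng is None:
                raise ValueError("asymmetric_layers mode needs an rng")
            draws = rng.random(lattice.n_sites)
            states[in_region & (draws < spec.stress_probability)] = int(CellState.S)
    return TissueState(states)
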