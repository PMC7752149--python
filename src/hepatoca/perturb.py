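"""Step perturbations applied to running simulations.

Two kinds are supported, mirroring the perturbation protocols used to
probe the stability of the coexistence state:

* ``state_convert`` — at a given time, rewrite a random fraction of the
  sites currently in one state to another state (e.g. convert 95% of the
  stressed cells to healthy, or to dead).  ``fraction="all_but_one"``
  leaves exactly one uniformly chosen site in the source state.
* ``param_switch`` — replace the model parameters for all later steps
  (e.g. drop gamma/beta from a coexistence ratio to a recovery ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import CellState, Parameters, TissueState

__all__ = ["Perturbation", "apply_perturbation"]

_STATE_CODES = {"H": int(CellState.H), "S": int(CellState.S), "D": int(CellState.D)}


@dataclass(frozen=True)
class Perturbation:
    """A scheduled intervention.

    ``at_time`` is in hours and must align with the timestep grid.  For
    ``kind="state_convert"``, ``from_state``/``to_state`` are "H"/"S"/"D"
    and ``fraction`` is a value in (0, 1] or the string ``"all_but_one"``.
    For ``kind="param_switch"``, ``new_params`` replaces the parameter set.
    """

    at_time: float
    kind: str
    from_state: str | None = None
    to_state: str | None = None
    fraction: float | str = 1.0
    new_params: Parameters | None = None

    def __post_init__(self):
        if self.kind not in ("state_convert", "param_switch"):
            raise ValueError(f"unknown perturbation kind: {self.kind!r}")
        if self.kind == "state_convert":
            if self.from_state not in _STATE_CODES or self.to_state not in _STATE_CODES:
                raise ValueError("state_convert needs from_state/to_state in {H, S, D}")
            if self.fraction != "all_but_one" and not 0.0 < float(self.fraction) <= 1.0:
                raise ValueError("fraction must lie in (0, 1] or be 'all_but_one'")
        elif self.new_params is None:
            raise ValueError("param_switch needs new_params")


def _select(eligible: np.ndarray, fraction, rng: np.random.Generator) -> np.ndarray:
    """Chosen site indices among ``eligible`` (without replacement)."""
    n = eligible.size
    if fraction == "all_but_one":
        k = max(n - 1, 0)
    else:
        k = int(round(float(fraction) * n))
    if k == 0:
        return np.empty(0, dtype=np.int64)
    return rng.choice(eligible, size=k, replace=False)


def apply_perturbation_batch(
    states: np.ndarray,
    divisions: np.ndarray,
    perturbation: Perturbation,
    rng: np.random.Generator,
    params: Parameters,
) -> Parameters:
    """Apply to an (R, N) ensemble in place; returns the active parameters."""
    if perturbation.kind == "param_switch":
        return perturbation.new_params
    src = _STATE_CODES[perturbation.from_state]
    dst = _STATE_CODES[perturbation.to_state]
    for r in range(states.shape[0]):
        eligible = np.flatnonzero(states[r] == src)
        if eligible.size == 0:
            warnings.warn(
                f"state_convert at t={perturbation.at_time} h: no sites in state "
                f"{perturbation.from_state}; no-op",
                stacklevel=2,
            )
            continue
        chosen = _select(eligible, perturbation.fraction, rng)
        states[r, chosen] = dst
        if dst == int(CellState.D):
            divisions[r, chosen] = 0
    return params


def apply_perturbation(
    state: TissueState, perturbation: Perturbation, rng: np.random.Generator
) -> tuple[TissueState, Parameters | None]:
    """Apply to a single tissue state; returns (new state, new params or None)."""
    out = state.copy()
    if perturbation.kind == "param_switch":
        return out, perturbation.new_params
    apply_perturbation_batch(
        out.states[None, :], out.divisions_used[None, :], perturbation, rng, None
    )
    return out, None
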