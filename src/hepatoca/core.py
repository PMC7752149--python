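"""Cell states, model parameters and the stochastic update rules.

The model is a discrete-time probabilistic cellular automaton.  Every site
holds a healthy cell (H), a stressed cell (S) or is empty after a cell has
died (D).  Per timestep ``dt`` three rules apply, each controlled by a
characteristic timescale in hours:

* conversion (``beta``): a healthy cell with stressed neighbors becomes
  stressed when two independent uniform draws satisfy ``r1 <= dt/beta``
  and ``r2 <= N_s/T``, where ``N_s`` is the number of stressed neighbors
  and ``T`` the site's total neighbor count;
* death (``gamma``): a stressed cell dies with probability ``dt/gamma``;
* proliferation (``alpha``): a healthy cell next to at least one empty
  site enters a division queue with probability ``dt/alpha``; each queued
  cell claims one of its empty contact neighbors uniformly at random, and
  when several cells claim the same site a random shuffle decides the
  single winner.

Within a step the rules are composed conversion -> death -> proliferation,
with conversion and death decided from the start-of-step snapshot (a cell
converted this step cannot die this step) and proliferation seeing the
vacancies created this step.  Both choices are configurable
(``update_order``, ``same_step_vacancies``) since alternative schedulers
are plausible readings of the rule set.

All rule functions are vectorized over an ensemble axis: states have shape
``(n_replicas, n_sites)``.  Random draws are consumed in a fixed
(rule, replica, site) order, so runs are bit-reproducible given a seed.
"""

from __future__ import annotations

import enum

from dataclasses import dataclass, replace

import numpy as np

from .lattice import Lattice

__all__ = [
    "CellState",
    "Parameters",
    "TissueState",
    "conversion_step",
    "death_step",
    "proliferation_step",
    "step",
]


class CellState(enum.IntEnum):
    """The three site states; ``D`` denotes an empty site left by a death."""

    H = 0
    S = 1
    D = 2


H, S, D = CellState.H, CellState.S, CellState.D


@dataclass(frozen=True)
class Parameters:
    """Timescales (hours) and rule switches of the automaton.

    ``alpha``, ``beta``, ``gamma`` are the proliferation, conversion and
    death timescales; the per-step probabilities are ``p_p = dt/alpha``,
    ``p_c = dt/beta`` and ``p_d = dt/gamma``, which requires
    ``0 < dt <= min(alpha, beta, gamma)``.

    ``epsilon`` adds baseline noise inside the conversion rule: the
    neighbor gate becomes ``r2 <= N_s/T + epsilon``, so a healthy cell
    with no stressed neighbors still converts at rate ``p_c * epsilon``
    per step.  ``neighbor_order`` selects the shell the conversion rule sees:
    contact neighbors only (``"first"``) or contact plus the distance-2
    shell (``"first_and_second"``).  ``division_cap`` bounds the number of
    divisions any single cell may perform (``None`` = unbounded; a
    daughter cell starts with a fresh budget).
    """

    alpha: float
    beta: float
    gamma: float
    dt: float = 0.25
    epsilon: float = 0.0
    neighbor_order: str = "first"
    division_cap: int | None = None
    update_order: str = "conversion_first"  # or "death_first"
    same_step_vacancies: bool = True
    t_norm: str = "auto"  # "per_site" | "bulk" | "auto" (chain: bulk, hex: per_site)

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "dt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.dt > min(self.alpha, self.beta, self.gamma) + 1e-12:
            raise ValueError(
                f"dt={self.dt} must not exceed min(alpha, beta, gamma)="
                f"{min(self.alpha, self.beta, self.gamma)}"
            )
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must lie in [0, 1], got {self.epsilon}")
        if self.neighbor_order not in ("first", "first_and_second"):
            raise ValueError(f"unknown neighbor_order: {self.neighbor_order!r}")
        if self.division_cap is not None and self.division_cap < 1:
            raise ValueError(f"division_cap must be >= 1 or None, got {self.division_cap}")
        if self.update_order not in ("conversion_first", "death_first"):
            raise ValueError(f"unknown update_order: {self.update_order!r}")
        if self.t_norm not in ("auto", "bulk", "per_site"):
            raise ValueError(f"unknown t_norm: {self.t_norm!r}")

    def rule_probs(self) -> "RuleProbs":
        """Per-step probabilities in the form the batch kernels consume."""
        return RuleProbs(
            p_p=self.p_p,
            p_c=self.p_c,
            p_d=self.p_d,
            epsilon=self.epsilon,
            neighbor_order=self.neighbor_order,
            division_cap=self.division_cap,
            update_order=self.update_order,
            same_step_vacancies=self.same_step_vacancies,
            t_norm=self.t_norm,
        )

    @property
    def p_p(self) -> float:
        """Per-step division probability dt/alpha."""
        return self.dt / self.alpha

    @property
    def p_c(self) -> float:
        """Per-step conversion probability gate dt/beta."""
        return self.dt / self.beta

    @property
    def p_d(self) -> float:
        """Per-step death probability dt/gamma."""
        return self.dt / self.gamma

    def with_ratios(self, *, alpha=None, beta=None, gamma=None) -> "Parameters":
        """Copy with some timescales replaced (hours)."""
        return replace(
            self,
            alpha=self.alpha if alpha is None else alpha,
            beta=self.beta if beta is None else beta,
            gamma=self.gamma if gamma is None else gamma,
        )


@dataclass
class TissueState:
    """Mutable per-site simulation state.

    ``states`` holds a :class:`CellState` code per site, ``divisions_used``
    the number of divisions performed by the cell currently at each site,
    and ``time`` the simulated hours elapsed.
    """

    states: np.ndarray
    divisions_used: np.ndarray = None
    time: float = 0.0

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.divisions_used is None:
            self.divisions_used = np.zeros_like(self.states, dtype=np.int32)
        else:
            self.divisions_used = np.asarray(self.divisions_used, dtype=np.int32)

    @property
    def n_sites(self) -> int:
        return self.states.shape[-1]

    def counts(self) -> tuple[int, int, int]:
        """(H, S, D) census; always sums to the number of sites."""
        return (
            int(np.count_nonzero(self.states == H)),
            int(np.count_nonzero(self.states == S)),
            int(np.count_nonzero(self.states == D)),
        )

    def copy(self) -> "TissueState":
        return TissueState(self.states.copy(), self.divisions_used.copy(), self.time)


@dataclass
class RuleProbs:
    """Per-step rule probabilities as consumed by the batch kernels.

    ``p_p``, ``p_c`` and ``p_d`` may be scalars or ``(R, 1)`` arrays, one
    value per ensemble row; the sweep driver uses the array form to step
    many parameter combinations in a single stacked ensemble.
    """

    p_p: float | np.ndarray
    p_c: float | np.ndarray
    p_d: float | np.ndarray
    epsilon: float = 0.0
    neighbor_order: str = "first"
    division_cap: int | None = None
    update_order: str = "conversion_first"
    same_step_vacancies: bool = True
    t_norm: str = "auto"

    def rule_probs(self) -> "RuleProbs":
        return self

    def take(self, rows: np.ndarray) -> "RuleProbs":
        """Restrict per-row probability arrays to the given rows."""
        pick = lambda v: v[rows] if isinstance(v, np.ndarray) else v
        return RuleProbs(
            p_p=pick(self.p_p),
            p_c=pick(self.p_c),
            p_d=pick(self.p_d),
            epsilon=self.epsilon,
            neighbor_order=self.neighbor_order,
            division_cap=self.division_cap,
            update_order=self.update_order,
            same_step_vacancies=self.same_step_vacancies,
            t_norm=self.t_norm,
        )


# ---------------------------------------------------------------------------
# batch rule kernels: states has shape (R, N), uint8
# ---------------------------------------------------------------------------


def _pad_mask(mask: np.ndarray) -> np.ndarray:
    """Append an all-False sentinel column so padded adjacency gathers it."""
    r = mask.shape[0]
    return np.concatenate([mask, np.zeros((r, 1), dtype=bool)], axis=1)


def batch_conversion_mask(
    states: np.ndarray, lattice: Lattice, params: Parameters, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (R, N) mask of healthy sites that convert H->S this step."""
    idx, counts = lattice.adjacency(params.neighbor_order)
    stressed = _pad_mask(states == S)
    n_s = stressed[:, idx].sum(axis=2)
    healthy = states == H
    # the two independent gates r1 <= P_c and r2 <= N_s/T + epsilon fuse
    # into a single uniform draw against their product probability; the
    # baseline noise term sits inside the neighbor gate, so the effective
    # spontaneous rate is P_c * epsilon per step
    t_norm = resolve_t_norm(params.t_norm, lattice)
    t = counts[None, :] if t_norm == "per_site" else int(counts.max())
    p = params.p_c * np.minimum(n_s / t + params.epsilon, 1.0)
    u = rng.random(states.shape, dtype=np.float32)
    return healthy & (u < p)


def batch_death_mask(
    states: np.ndarray, params: Parameters, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (R, N) mask of stressed sites that die S->D this step."""
    rd = rng.random(states.shape, dtype=np.float32)
    return (states == S) & (rd < params.p_d)


def batch_proliferation(
    states: np.ndarray,
    empties: np.ndarray,
    divisions: np.ndarray,
    lattice: Lattice,
    params: Parameters,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve the division queue.

    Returns ``(replica_idx, parent_idx, target_idx)`` arrays of the
    divisions that actually occur.  ``empties`` is the boolean (R, N) mask
    of sites a daughter may occupy (normally the post-death D sites).
    Conflicts on a target are resolved equivalently to shuffling the queue
    and letting the first claimant win: every claimant draws a uniform
    priority and the minimum wins, which is uniform among claimants and
    independent across distinct targets.
    """
    n_rep, n = states.shape
    idx, _ = lattice.adjacency("first")
    rp = rng.random(states.shape, dtype=np.float32)

    eligible = states == H
    if params.division_cap is not None:
        eligible &= divisions < params.division_cap
    emp_nbr = _pad_mask(empties)[:, idx]  # (R, N, deg)
    n_empty = emp_nbr.sum(axis=2)
    queue = eligible & (rp < params.p_p) & (n_empty > 0)
    if not queue.any():
        empty_i = np.empty(0, dtype=np.int64)
        return empty_i, empty_i, empty_i
    tsel = rng.random(states.shape, dtype=np.float32)
    prio = rng.random(states.shape)

    # k-th empty neighbor, k uniform in [0, n_empty)
    k = np.minimum((tsel * n_empty).astype(np.int64), np.maximum(n_empty - 1, 0))
    order = np.cumsum(emp_nbr, axis=2)
    sel = emp_nbr & (order == (k + 1)[:, :, None])
    loc = sel.argmax(axis=2)
    target = idx[np.arange(n)[None, :], loc]  # (R, N), valid where queue

    rr, pp = np.nonzero(queue)
    tt = target[rr, pp]
    best = np.full((n_rep, n), np.inf)
    np.minimum.at(best, (rr, tt), prio[rr, pp])
    win = prio[rr, pp] == best[rr, tt]
    return rr[win], pp[win], tt[win]


def resolve_t_norm(t_norm: str, lattice: Lattice) -> str:
    """Geometry default for the conversion normalizer T.

    On the chain the cord terminates in the CV and the portal field:
    every cell keeps the full coordination T = 2, the missing lattice
    neighbor being vasculature that is never stressed.  On hexagonal
    lobules T is the actual neighbor-list length, shorter at the rim.
    """
    if t_norm == "auto":
        return "bulk" if lattice.geometry == "chain" else "per_site"
    return t_norm


def batch_frozen_mask(
    states: np.ndarray,
    divisions: np.ndarray,
    n_h: np.ndarray,
    n_s: np.ndarray,
    lattice: Lattice,
    probs,
) -> np.ndarray:
    """Replica rows that can never change again under the current rules.

    All-dead rows are always frozen.  With no spontaneous stress
    (epsilon = 0) all-healthy rows are frozen too, and under a finite
    division cap so are rows whose stressed cells are gone while every
    remaining healthy cell is out of divisions or has no empty contact
    neighbor.
    """
    n_rep, n = states.shape
    done = (n_h == 0) & (n_s == 0)
    if probs.epsilon == 0.0:
        done |= n_h == n
        if probs.division_cap is not None:
            quiet = (n_s == 0) & (n_h > 0) & (n_h < n)
            if quiet.any():
                idx, _ = lattice.adjacency("first")
                emp_pad = _pad_mask(states == D)
                can = (
                    (states == H)
                    & (divisions < probs.division_cap)
                    & emp_pad[:, idx].any(axis=2)
                )
                done |= quiet & ~can.any(axis=1)
    return done


def batch_step(
    states: np.ndarray,
    divisions: np.ndarray,
    lattice: Lattice,
    params: Parameters,
    rng: np.random.Generator,
) -> dict:
    """Advance the whole ensemble by one timestep, in place.

    Returns per-replica counts of conversions, deaths and divisions.
    """
    snap_d = states == D
    if params.update_order == "conversion_first":
        conv = batch_conversion_mask(states, lattice, params, rng)
        die = batch_death_mask(states, params, rng)
        states[conv] = S
        states[die] = D
    else:  # death first: dying cells do not convert their neighbors
        die = batch_death_mask(states, params, rng)
        states[die] = D
        conv = batch_conversion_mask(states, lattice, params, rng)
        states[conv] = S

    empties = states == D if params.same_step_vacancies else snap_d
    rr, pp, tt = batch_proliferation(states, empties, divisions, lattice, params, rng)
    states[rr, tt] = H
    divisions[rr, tt] = 0
    divisions[rr, pp] += 1

    n_div = np.zeros(states.shape[0], dtype=np.int64)
    np.add.at(n_div, rr, 1)
    return {
        "conversions": conv.sum(axis=1),
        "deaths": die.sum(axis=1),
        "divisions": n_div,
    }


# ---------------------------------------------------------------------------
# single-state API over the batch kernels
# ---------------------------------------------------------------------------


def conversion_step(
    state: TissueState, lattice: Lattice, params: Parameters, rng: np.random.Generator
) -> np.ndarray:
    """Site indices that would convert H->S this step (snapshot semantics)."""
    mask = batch_conversion_mask(state.states[None, :], lattice, params, rng)
    return np.flatnonzero(mask[0])


def death_step(
    state: TissueState, params: Parameters, rng: np.random.Generator
) -> np.ndarray:
    """Site indices that would die S->D this step (snapshot semantics)."""
    mask = batch_death_mask(state.states[None, :], params, rng)
    return np.flatnonzero(mask[0])


def proliferation_step(
    state: TissueState, lattice: Lattice, params: Parameters, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Resolved (parent, target) division pairs for the current state."""
    states = state.states[None, :]
    _, pp, tt = batch_proliferation(
        states, states == D, state.divisions_used[None, :], lattice, params, rng
    )
    return list(zip(pp.tolist(), tt.tolist()))


def step(
    state: TissueState, lattice: Lattice, params: Parameters, rng: np.random.Generator
) -> tuple[TissueState, dict]:
    """Apply one full scheduler step and return the advanced state + log."""
    out = state.copy()
    states = out.states[None, :]
    divisions = out.divisions_used[None, :]
    log = batch_step(states, divisions, lattice, params, rng)
    out.states = states[0]
    out.divisions_used = divisions[0]
    out.time = state.time + params.dt
    return out, {k: int(v[0]) for k, v in log.items()}
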