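"""Trajectories, seeded ensembles and the exact small-chain oracle.

``run_single`` advances one tissue to an absorbing state or a time
horizon and records a trajectory.  ``run_ensemble`` runs independent
replicas (vectorized over a replica axis, one master-seeded stream) and
aggregates survival probability, outcome counts and coexistence
statistics.  ``exact_absorption`` enumerates the full Markov chain of a
small chain lattice and solves the absorption equations exactly; it is
the independent reference the Monte-Carlo path is validated against.

Outcome classification: a run *recovers* when every site is healthy
(H = N), *dies* when every site is empty (D = N), and *coexists* when the
horizon is reached with live cells of both kinds still present.  With a
finite division cap the tissue can freeze with healthy cells that can no
longer divide; the relaxed survival criterion (healthy cells present, no
stressed cells) is then used, matching how capped runs are scored.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CellState, Parameters, TissueState, batch_frozen_mask, batch_step
from .lattice import Lattice

H, S, D = CellState.H, CellState.S, CellState.D

__all__ = [
    "Trajectory",
    "RunResult",
    "EnsembleResult",
    "AbsorptionResult",
    "run_single",
    "run_ensemble",
    "exact_absorption",
    "recovery_time",
]


def recovery_time(result: "RunResult", onset_offset: float = 0.0) -> float | None:
    """Hours until full recovery, or None for other outcomes.

    ``onset_offset`` shifts the clock to time-after-injury: the simulated
    initial condition represents the first appearance of pericentral
    stressed cells, which in vivo lags the insult by about 2 hours, so
    ``onset_offset=2.0`` reports time since dosing.
    """
    if result.outcome != "recovered" or result.t_absorb is None:
        return None
    return result.t_absorb + onset_offset


@dataclass
class Trajectory:
    """Recorded (H, S, D) time series of one run."""

    times: np.ndarray
    counts: np.ndarray  # (n_records, 3) in (H, S, D) order
    divisions_cum: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "n_healthy": self.counts[:, 0],
                "n_stressed": self.counts[:, 1],
                "n_dead": self.counts[:, 2],
                "divisions_cum": self.divisions_cum,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class RunResult:
    """Per-run summary."""

    outcome: str  # "recovered" | "died" | "coexisting"
    min_h: int
    max_h: int
    new_cells: int
    t_absorb: float | None
    final_fractions: tuple[float, float, float]
    steady_mean: tuple[float, float, float] | None = None
    steady_sd: tuple[float, float, float] | None = None


@dataclass
class EnsembleResult:
    """Aggregate over seeded replicas.

    ``survival_probability`` is the ensemble mean of the final healthy
    fraction H/N, identical to the fraction of recovered runs when every
    replica reaches an absorbing state.
    """

    n_replicas: int
    n_sites: int
    runs: list[RunResult]
    survival_probability: float
    outcome_counts: dict[str, int]
    steady_fractions_mean: tuple[float, float, float] | None = None
    steady_fractions_sd: tuple[float, float, float] | None = None

    def summary_dict(self) -> dict:
        out = {
            "n_replicas": self.n_replicas,
            "n_sites": self.n_sites,
            "survival_probability": self.survival_probability,
            "outcome_counts": self.outcome_counts,
        }
        if self.steady_fractions_mean is not None:
            out["steady_fractions_mean"] = list(self.steady_fractions_mean)
            out["steady_fractions_sd"] = list(self.steady_fractions_sd)
        return out

    def runs_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replica": np.arange(self.n_replicas),
                "outcome": [r.outcome for r in self.runs],
                "min_h": [r.min_h for r in self.runs],
                "max_h": [r.max_h for r in self.runs],
                "new_cells": [r.new_cells for r in self.runs],
                "t_absorb": [r.t_absorb for r in self.runs],
                "final_h_frac": [r.final_fractions[0] for r in self.runs],
            }
        )


# ---------------------------------------------------------------------------
# batch runner
# ---------------------------------------------------------------------------


def _apply_perturbations_batch(states, divisions, perturbations, t, dt, rng, params):
    """Apply due perturbations in place; returns possibly replaced params."""
    from .perturb import apply_perturbation_batch  # local import, no cycle at module load

    for p in perturbations:
        if abs(p.at_time - t) < dt / 2:
            params = apply_perturbation_batch(states, divisions, p, rng, params)
    return params


def _run_batch(
    lattice: Lattice,
    params: Parameters,
    states: np.ndarray,
    divisions: np.ndarray,
    rng: np.random.Generator,
    t_max: float,
    record_every: int | None = None,
    trailing_frac: float = 0.2,
    perturbations=(),
    survival_criterion: str = "auto",
):
    """Advance an (R, N) ensemble to absorption or ``t_max``.

    Returns (records, run results).  ``records`` is None unless
    ``record_every`` is given.
    """
    if t_max < params.dt:
        raise ValueError(f"t_max={t_max} is below one timestep dt={params.dt}")
    if survival_criterion == "auto":
        survival_criterion = (
            "healthy_remaining" if params.division_cap is not None else "full_recovery"
        )

    n_rep, n = states.shape
    n_steps = int(math.floor(t_max / params.dt + 1e-9))
    trail_start = int(math.ceil((1.0 - trailing_frac) * n_steps))

    n_h = (states == H).sum(axis=1)
    n_s = (states == S).sum(axis=1)
    min_h = n_h.copy()
    max_h = n_h.copy()
    new_cells = np.zeros(n_rep, dtype=np.int64)
    frozen = np.zeros(n_rep, dtype=bool)
    t_absorb = np.full(n_rep, np.nan)

    trail_sum = np.zeros((n_rep, 3))
    trail_sumsq = np.zeros((n_rep, 3))
    trail_n = 0

    records = [] if record_every is not None else None
    if records is not None:
        records.append((0.0, np.stack([n_h, n_s, n - n_h - n_s], axis=1), new_cells.copy()))

    def _freeze_check(n_h, n_s):
        return batch_frozen_mask(states, divisions, n_h, n_s, lattice, params)

    frozen = _freeze_check(n_h, n_s)
    t_absorb[frozen] = 0.0
    cur_params = params

    t = 0.0
    for k in range(1, n_steps + 1):
        if frozen.all():
            break
        if perturbations:
            cur_params = _apply_perturbations_batch(
                states, divisions, perturbations, t, params.dt, rng, cur_params
            )
        log = batch_step(states, divisions, lattice, cur_params, rng)
        t = k * params.dt
        n_h = (states == H).sum(axis=1)
        n_s = (states == S).sum(axis=1)
        np.minimum(min_h, n_h, out=min_h)
        np.maximum(max_h, n_h, out=max_h)
        new_cells += log["divisions"]

        newly = _freeze_check(n_h, n_s) & ~frozen
        t_absorb[newly] = t
        frozen |= newly

        if k >= trail_start:
            frac = np.stack([n_h, n_s, n - n_h - n_s], axis=1) / n
            trail_sum += frac
            trail_sumsq += frac * frac
            trail_n += 1
        if records is not None and (k % record_every == 0 or k == n_steps):
            records.append((t, np.stack([n_h, n_s, n - n_h - n_s], axis=1), new_cells.copy()))

    # classify
    runs: list[RunResult] = []
    n_d = n - n_h - n_s
    for r in range(n_rep):
        if frozen[r]:
            if n_h[r] == 0:
                outcome = "died"
            elif n_h[r] == n:
                outcome = "recovered"
            elif survival_criterion == "healthy_remaining" and n_s[r] == 0:
                outcome = "recovered"
            else:
                outcome = "coexisting"
            tab = float(t_absorb[r])
        else:
            outcome = "coexisting"
            tab = None
        steady_mean = steady_sd = None
        if outcome == "coexisting" and trail_n > 0 and not frozen[r]:
            m = trail_sum[r] / trail_n
            v = np.maximum(trail_sumsq[r] / trail_n - m * m, 0.0)
            steady_mean = tuple(m)
            steady_sd = tuple(np.sqrt(v))
        runs.append(
            RunResult(
                outcome=outcome,
                min_h=int(min_h[r]),
                max_h=int(max_h[r]),
                new_cells=int(new_cells[r]),
                t_absorb=tab,
                final_fractions=(n_h[r] / n, n_s[r] / n, n_d[r] / n),
                steady_mean=steady_mean,
                steady_sd=steady_sd,
            )
        )
    return records, runs, frozen, (trail_sum, trail_sumsq, trail_n)


def run_single(
    lattice: Lattice,
    initial: TissueState,
    params: Parameters,
    rng,
    t_max: float = 12000.0,
    record_every: int = 1,
    perturbations=(),
    survival_criterion: str = "auto",
) -> tuple[Trajectory, RunResult]:
    """Run one tissue to absorption or ``t_max`` hours.

    ``rng`` may be a seed or a :class:`numpy.random.Generator`.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    states = initial.states[None, :].copy()
    divisions = initial.divisions_used[None, :].copy()
    records, runs, _, _ = _run_batch(
        lattice,
        params,
        states,
        divisions,
        rng,
        t_max,
        record_every=record_every,
        perturbations=perturbations,
        survival_criterion=survival_criterion,
    )
    times = np.array([rec[0] for rec in records])
    counts = np.stack([rec[1][0] for rec in records])
    div = np.array([rec[2][0] for rec in records])
    return Trajectory(times, counts, div), runs[0]


def run_ensemble(
    lattice: Lattice,
    initial,
    params: Parameters,
    n_replicas: int,
    master_seed,
    t_max: float = 12000.0,
    perturbations=(),
    survival_criterion: str = "auto",
    trailing_frac: float = 0.2,
    engine: str = "auto",
) -> EnsembleResult:
    """Run ``n_replicas`` independent replicas from one master seed.

    ``initial`` is a :class:`TissueState` shared by all replicas, or a
    callable ``f(lattice, rng) -> TissueState`` invoked once per replica
    (for randomized initial conditions).  ``engine`` selects the compiled
    batch kernel (``"numba"``, the default when numba is importable) or
    the pure-numpy one (``"numpy"``); both implement the same scheduler
    but consume different random streams.  Perturbation schedules run on
    the numpy engine.
    """
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    if isinstance(master_seed, np.random.SeedSequence):
        ss = master_seed
    else:
        ss = np.random.SeedSequence(master_seed)
    init_ss, dyn_ss = ss.spawn(2)
    init_rng = np.random.default_rng(init_ss)

    n = lattice.n_sites
    states = np.empty((n_replicas, n), dtype=np.uint8)
    divisions = np.zeros((n_replicas, n), dtype=np.int32)
    if callable(initial):
        for r in range(n_replicas):
            st = initial(lattice, init_rng)
            states[r] = st.states
            divisions[r] = st.divisions_used
    else:
        states[:] = initial.states
        divisions[:] = initial.divisions_used

    from ._fast import HAVE_NUMBA

    use_fast = HAVE_NUMBA and not perturbations and engine in ("auto", "numba")
    if engine == "numba" and not HAVE_NUMBA:
        raise RuntimeError("numba engine requested but numba is not importable")

    if use_fast:
        from ._fast import simulate_rows

        if survival_criterion == "auto":
            survival_criterion = (
                "healthy_remaining" if params.division_cap is not None else "full_recovery"
            )
        n_steps = int(math.floor(t_max / params.dt + 1e-9))
        if n_steps < 1:
            raise ValueError(f"t_max={t_max} is below one timestep dt={params.dt}")
        trail_start = int(math.ceil((1.0 - trailing_frac) * n_steps))
        seed = int(dyn_ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        stats = simulate_rows(
            lattice,
            params.rule_probs(),
            states,
            divisions,
            n_steps,
            seed,
            trail_start=trail_start,
        )
        runs = _runs_from_stats(stats, n, params.dt, survival_criterion)
        frozen = stats["frozen"]
        tsum, tsumsq, tn = stats["trail_sum"], stats["trail_sumsq"], stats["trail_n"]
    else:
        rng = np.random.default_rng(dyn_ss)
        _, runs, frozen, (tsum, tsumsq, tn) = _run_batch(
            lattice,
            params,
            states,
            divisions,
            rng,
            t_max,
            perturbations=perturbations,
            survival_criterion=survival_criterion,
            trailing_frac=trailing_frac,
        )

    final_h = np.array([r.final_fractions[0] for r in runs])
    counts = {"recovered": 0, "died": 0, "coexisting": 0}
    for r in runs:
        counts[r.outcome] += 1

    steady_mean = steady_sd = None
    coexist = ~frozen
    if coexist.any() and tn > 0:
        # pool trailing-window samples over all coexisting replicas
        m = tsum[coexist].sum(axis=0) / (tn * coexist.sum())
        ex2 = tsumsq[coexist].sum(axis=0) / (tn * coexist.sum())
        steady_mean = tuple(m)
        steady_sd = tuple(np.sqrt(np.maximum(ex2 - m * m, 0.0)))

    return EnsembleResult(
        n_replicas=n_replicas,
        n_sites=n,
        runs=runs,
        survival_probability=float(final_h.mean()),
        outcome_counts=counts,
        steady_fractions_mean=steady_mean,
        steady_fractions_sd=steady_sd,
    )


def _runs_from_stats(stats: dict, n: int, dt: float, survival_criterion: str) -> list[RunResult]:
    """Build per-replica :class:`RunResult` objects from engine stat arrays."""
    runs = []
    frozen = stats["frozen"]
    nh, ns = stats["final_nh"], stats["final_ns"]
    tn = stats["trail_n"]
    for r in range(len(frozen)):
        if frozen[r]:
            if nh[r] == 0:
                outcome = "died"
            elif nh[r] == n:
                outcome = "recovered"
            elif survival_criterion == "healthy_remaining" and ns[r] == 0:
                outcome = "recovered"
            else:
                outcome = "coexisting"
            tab = float(stats["t_absorb_step"][r]) * dt
        else:
            outcome = "coexisting"
            tab = None
        steady_mean = steady_sd = None
        if outcome == "coexisting" and not frozen[r] and tn > 0:
            m = stats["trail_sum"][r] / tn
            v = np.maximum(stats["trail_sumsq"][r] / tn - m * m, 0.0)
            steady_mean = tuple(m)
            steady_sd = tuple(np.sqrt(v))
        runs.append(
            RunResult(
                outcome=outcome,
                min_h=int(stats["min_h"][r]),
                max_h=int(stats["max_h"][r]),
                new_cells=int(stats["new_cells"][r]),
                t_absorb=tab,
                final_fractions=(nh[r] / n, ns[r] / n, (n - nh[r] - ns[r]) / n),
                steady_mean=steady_mean,
                steady_sd=steady_sd,
            )
        )
    return runs


# ---------------------------------------------------------------------------
# exact Markov-chain oracle for small chains
# ---------------------------------------------------------------------------


@dataclass
class AbsorptionResult:
    """Exact absorption split and expected time for a small system."""

    p_recover: float  # absorbed into the all-healthy state
    p_death: float  # absorbed into the all-dead state
    p_other: float  # frozen in any other fixed point (finite caps only)
    expected_time: float  # hours until a fixed point, from the initial state
    n_states: int


def _enumerate_transitions(state, lattice: Lattice, params: Parameters):
    """Exact one-step transition distribution from ``state``.

    ``state`` is a tuple of per-site ``(cell_state, divisions_used)``
    pairs (divisions tracked only under a finite cap, else 0).  Built
    directly from the written rules by exhaustive enumeration; it shares
    no code with the vectorized kernels.
    """
    n = lattice.n_sites
    cap = params.division_cap
    idx1 = lattice.neighbors1
    if params.neighbor_order == "first":
        conv_nbrs = idx1
    else:
        conv_nbrs = tuple(
            a + b for a, b in zip(lattice.neighbors1, lattice.neighbors2)
        )

    t_bulk = max(len(v) for v in conv_nbrs)
    from .core import resolve_t_norm

    per_site_t = resolve_t_norm(params.t_norm, lattice) == "per_site"

    def conv_probs(cells):
        probs = {}
        for i, (c, _) in enumerate(cells):
            if c != int(H):
                continue
            t_i = len(conv_nbrs[i]) if per_site_t else t_bulk
            n_s = sum(1 for j in conv_nbrs[i] if cells[j][0] == int(S))
            probs[i] = params.p_c * min(n_s / t_i + params.epsilon, 1.0)
        return probs

    def subsets(items, probs):
        """Yield (chosen_subset, probability) over independent Bernoullis."""
        items = list(items)
        for bits in itertools.product([0, 1], repeat=len(items)):
            p = 1.0
            chosen = []
            for b, it in zip(bits, items):
                q = probs[it]
                p *= q if b else (1.0 - q)
                if b:
                    chosen.append(it)
            if p > 0.0:
                yield chosen, p

    out: dict[tuple, float] = {}
    snapshot = list(state)
    stressed = [i for i, (c, _) in enumerate(snapshot) if c == int(S)]
    death_p = {i: params.p_d for i in stressed}

    if params.update_order == "conversion_first":
        first_sets = [
            ((c_set, d_set), pc * pd)
            for c_set, pc in subsets(list(conv_probs(snapshot)), conv_probs(snapshot))
            for d_set, pd in subsets(stressed, death_p)
        ]
    else:  # death resolved first, conversion sees the post-death state
        first_sets = []
        for d_set, pd in subsets(stressed, death_p):
            mid = list(snapshot)
            for i in d_set:
                mid[i] = (int(D), 0)
            cp = conv_probs(mid)
            for c_set, pc in subsets(list(cp), cp):
                first_sets.append(((c_set, d_set), pd * pc))

    for (c_set, d_set), p0 in first_sets:
        mid = list(snapshot)
        for i in c_set:
            mid[i] = (int(S), mid[i][1])
        for i in d_set:
            mid[i] = (int(D), 0)
        if params.same_step_vacancies:
            empties = {i for i, (c, _) in enumerate(mid) if c == int(D)}
        else:
            empties = {i for i, (c, _) in enumerate(snapshot) if c == int(D)}

        eligible = [
            i
            for i, (c, dv) in enumerate(mid)
            if c == int(H)
            and (cap is None or dv < cap)
            and any(j in empties for j in idx1[i])
        ]
        queue_p = {i: params.p_p for i in eligible}
        for q_set, pq in subsets(eligible, queue_p):
            if not q_set:
                key = tuple(mid)
                out[key] = out.get(key, 0.0) + p0 * pq
                continue
            choice_lists = [
                [j for j in idx1[i] if j in empties] for i in q_set
            ]
            for targets in itertools.product(*choice_lists):
                pt = p0 * pq
                for lst in choice_lists:
                    pt /= len(lst)
                claim: dict[int, list[int]] = {}
                for parent, tgt in zip(q_set, targets):
                    claim.setdefault(tgt, []).append(parent)
                for winners in itertools.product(*claim.values()):
                    pw = pt
                    for cl in claim.values():
                        pw /= len(cl)
                    fin = list(mid)
                    for tgt, parent in zip(claim.keys(), winners):
                        fin[tgt] = (int(H), 0)
                        c, dv = fin[parent]
                        fin[parent] = (c, min(dv + 1, cap) if cap is not None else 0)
                    key = tuple(fin)
                    out[key] = out.get(key, 0.0) + pw
    return out


def exact_absorption(
    lattice: Lattice,
    params: Parameters,
    initial: TissueState,
    max_states: int = 20000,
) -> AbsorptionResult:
    """Exact absorption probabilities and expected absorption time.

    Enumerates every state reachable from ``initial`` (division counters
    included when a cap is set), builds the exact one-step kernel induced
    by the scheduler and solves the linear absorption equations.  Refuses
    with an error when the reachable state space exceeds ``max_states``.
    """
    cap = params.division_cap

    def encode(st: TissueState):
        divs = st.divisions_used if cap is not None else np.zeros(st.n_sites, int)
        return tuple(
            (int(c), int(min(d, cap)) if cap is not None else 0)
            for c, d in zip(st.states, divs)
        )

    start = encode(initial)
    trans: dict[tuple, dict[tuple, float]] = {}
    frontier = [start]
    while frontier:
        s = frontier.pop()
        if s in trans:
            continue
        t = _enumerate_transitions(s, lattice, params)
        trans[s] = t
        if len(trans) > max_states:
            raise ValueError(
                f"reachable state space exceeds max_states={max_states}"
            )
        frontier.extend(k for k in t if k not in trans)

    absorbing = {
        s for s, t in trans.items() if len(t) == 1 and abs(t.get(s, 0.0) - 1.0) < 1e-12
    }
    transient = [s for s in trans if s not in absorbing]
    t_index = {s: i for i, s in enumerate(transient)}

    n_cells = lattice.n_sites

    def klass(s):
        cells = [c for c, _ in s]
        if all(c == int(H) for c in cells):
            return "recover"
        if all(c == int(D) for c in cells):
            return "death"
        return "other"

    if start in absorbing:
        k = klass(start)
        return AbsorptionResult(
            p_recover=float(k == "recover"),
            p_death=float(k == "death"),
            p_other=float(k == "other"),
            expected_time=0.0,
            n_states=len(trans),
        )

    m = len(transient)
    q = np.zeros((m, m))
    r = np.zeros((m, 3))  # recover, death, other
    kmap = {"recover": 0, "death": 1, "other": 2}
    for s in transient:
        i = t_index[s]
        for s2, p in trans[s].items():
            if s2 in absorbing:
                r[i, kmap[klass(s2)]] += p
            else:
                q[i, t_index[s2]] += p

    a = np.eye(m) - q
    probs = np.linalg.solve(a, r)
    times = np.linalg.solve(a, np.full(m, params.dt))
    i0 = t_index[start]
    return AbsorptionResult(
        p_recover=float(probs[i0, 0]),
        p_death=float(probs[i0, 1]),
        p_other=float(probs[i0, 2]),
        expected_time=float(times[i0]),
        n_states=len(trans),
    )
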