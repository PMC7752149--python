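"""Parameter-grid drivers, phase classification and critical-ratio fits.

A sweep fixes one timescale and varies the other two on rectangular axes
(hours).  Each grid point runs a seeded ensemble and keeps only summary
statistics, so grids stay cheap to hold in memory.  The transition out of
the always-recovers region is summarised by the critical ratio
``gamma/beta*``: per column of the grid, the first scanned ratio at which
the ensemble survival probability drops to ~0.95, averaged over columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import (
    CellState,
    Parameters,
    RuleProbs,
    batch_frozen_mask,
    batch_step,
)
from .lattice import Lattice

_H, _S = CellState.H, CellState.S

__all__ = [
    "SweepGrid",
    "CriticalRatio",
    "PhaseMap",
    "run_sweep",
    "scan_first_death",
    "estimate_critical_ratio",
    "fit_size_scaling",
    "classify_phase",
]


@dataclass
class SweepGrid:
    """Ensemble summaries on a rectangular (row x column) parameter grid.

    Rows carry the parameter whose ratio is scanned for crossings
    (typically ``gamma``); columns carry the second varied parameter.
    All per-point arrays have shape ``(n_rows, n_cols)``.
    """

    fixed_param: str
    fixed_value: float
    row_param: str
    col_param: str
    row_values: np.ndarray
    col_values: np.ndarray
    n_replicas: int
    n_sites: int
    survival: np.ndarray
    n_recovered: np.ndarray
    n_died: np.ndarray
    n_coexisting: np.ndarray
    mean_divisions: np.ndarray
    mean_min_h_recovered: np.ndarray  # NaN where no replica recovered
    mean_max_h_died: np.ndarray  # NaN where no replica died

    def param_value(self, name: str) -> np.ndarray:
        """(n_rows, n_cols) array of the named timescale at each point."""
        if name == self.fixed_param:
            return np.full((len(self.row_values), len(self.col_values)), self.fixed_value)
        if name == self.row_param:
            return np.broadcast_to(
                self.row_values[:, None], (len(self.row_values), len(self.col_values))
            )
        if name == self.col_param:
            return np.broadcast_to(
                self.col_values[None, :], (len(self.row_values), len(self.col_values))
            )
        raise ValueError(f"{name!r} is not a parameter of this sweep")

    def ratio(self, num: str = "gamma", den: str = "beta") -> np.ndarray:
        return self.param_value(num) / self.param_value(den)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table, one row per grid point."""
        rows, cols = np.meshgrid(self.row_values, self.col_values, indexing="ij")
        return pd.DataFrame(
            {
                "fixed_param": self.fixed_param,
                "fixed_value_h": self.fixed_value,
                f"{self.row_param}_h": rows.ravel(),
                f"{self.col_param}_h": cols.ravel(),
                "gamma_beta_ratio": self.ratio().ravel(),
                "survival_probability": self.survival.ravel(),
                "n_recovered": self.n_recovered.ravel(),
                "n_died": self.n_died.ravel(),
                "n_coexisting": self.n_coexisting.ravel(),
                "mean_divisions": self.mean_divisions.ravel(),
                "mean_min_h_recovered": self.mean_min_h_recovered.ravel(),
                "mean_max_h_died": self.mean_max_h_died.ravel(),
            }
        )


@dataclass
class CriticalRatio:
    """Mean +- sd of per-column threshold crossings of the survival map."""

    value: float
    sd: float
    crossings: dict[float, float]  # column value (hours) -> crossing ratio
    threshold: float = 0.95


@dataclass
class PhaseMap:
    """Per-point sets of observed outcomes (subsets of {S, D, C})."""

    labels: np.ndarray  # (n_rows, n_cols) of strings like "S", "SD", "SDC"
    row_values: np.ndarray
    col_values: np.ndarray
    first_death_ratio: float | None
    first_death_sd: float | None
    first_death_by_column: dict[float, float]

    def to_dataframe(self) -> pd.DataFrame:
        rows, cols = np.meshgrid(self.row_values, self.col_values, indexing="ij")
        return pd.DataFrame(
            {
                "row_value_h": rows.ravel(),
                "col_value_h": cols.ravel(),
                "label": self.labels.ravel(),
            }
        )


def run_sweep(
    lattice: Lattice,
    initial,
    base_params: Parameters,
    fixed_param: str,
    fixed_value: float,
    row_param: str,
    row_values,
    col_param: str,
    col_values,
    n_replicas: int,
    master_seed,
    t_max: float = 4000.0,
    survival_criterion: str = "auto",
    engine: str = "auto",
) -> SweepGrid:
    """Run one seeded ensemble per grid point.

    ``initial`` is a TissueState or an ``f(lattice, rng)`` initializer as
    in :func:`hepatoca.simulate.run_ensemble`.  Point seeds derive
    deterministically from ``master_seed``.
    """
    names = {fixed_param, row_param, col_param}
    if names != {"alpha", "beta", "gamma"}:
        raise ValueError("fixed/row/col parameters must cover alpha, beta, gamma")
    row_values = np.asarray(row_values, dtype=float)
    col_values = np.asarray(col_values, dtype=float)
    for vals in (row_values, col_values, np.array([fixed_value])):
        if (vals < base_params.dt - 1e-12).any():
            raise ValueError("axis values must not fall below the timestep dt")
    if survival_criterion == "auto":
        survival_criterion = (
            "healthy_remaining" if base_params.division_cap is not None else "full_recovery"
        )

    shape = (len(row_values), len(col_values))
    n_pts = shape[0] * shape[1]
    n = lattice.n_sites
    m = n_pts * n_replicas
    dt = base_params.dt

    if isinstance(master_seed, np.random.SeedSequence):
        ss = master_seed
    else:
        ss = np.random.SeedSequence(master_seed)
    init_ss, dyn_ss = ss.spawn(2)
    init_rng = np.random.default_rng(init_ss)

    # stacked ensemble: every grid point contributes n_replicas rows, with
    # per-row rule probabilities; frozen rows are compacted away as the
    # stack advances
    states = np.empty((m, n), dtype=np.uint8)
    divisions = np.zeros((m, n), dtype=np.int32)
    if callable(initial):
        for r in range(m):
            st = initial(lattice, init_rng)
            states[r] = st.states
            divisions[r] = st.divisions_used
    else:
        states[:] = initial.states
        divisions[:] = initial.divisions_used

    vals = {fixed_param: np.full(shape, fixed_value)}
    vals[row_param] = np.broadcast_to(row_values[:, None], shape).copy()
    vals[col_param] = np.broadcast_to(col_values[None, :], shape).copy()
    per_row = lambda name: np.repeat(dt / vals[name].ravel(), n_replicas)[:, None]
    probs = RuleProbs(
        p_p=per_row("alpha"),
        p_c=per_row("beta"),
        p_d=per_row("gamma"),
        epsilon=base_params.epsilon,
        neighbor_order=base_params.neighbor_order,
        division_cap=base_params.division_cap,
        update_order=base_params.update_order,
        same_step_vacancies=base_params.same_step_vacancies,
        t_norm=base_params.t_norm,
    )

    n_steps = int(np.floor(t_max / dt + 1e-9))
    from ._fast import HAVE_NUMBA

    if HAVE_NUMBA and engine in ("auto", "numba"):
        from ._fast import simulate_rows

        seed = int(dyn_ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        stats = simulate_rows(lattice, probs, states, divisions, n_steps, seed)
        min_h = stats["min_h"]
        max_h = stats["max_h"]
        new_cells = stats["new_cells"]
        frozen = stats["frozen"]
        final_nh = stats["final_nh"]
        final_ns = stats["final_ns"]
    else:
        if engine == "numba":
            raise RuntimeError("numba engine requested but numba is not importable")
        rng = np.random.default_rng(dyn_ss)
        n_h = (states == _H).sum(axis=1)
        n_s = (states == _S).sum(axis=1)
        min_h = n_h.copy()
        max_h = n_h.copy()
        new_cells = np.zeros(m, dtype=np.int64)
        final_nh = n_h.copy()
        final_ns = n_s.copy()
        frozen = np.zeros(m, dtype=bool)

        active = np.arange(m)
        cur_frozen = batch_frozen_mask(states, divisions, n_h, n_s, lattice, probs)
        frozen[active] = cur_frozen
        compact_every = 8
        for k in range(1, n_steps + 1):
            if k % compact_every == 1 or k == 1:
                keep = ~cur_frozen
                if not keep.all():
                    active = active[keep]
                    states = states[keep]
                    divisions = divisions[keep]
                    probs = probs.take(keep)
                    cur_frozen = cur_frozen[keep]
                    n_h = n_h[keep]
                    n_s = n_s[keep]
                if active.size == 0:
                    break
            log = batch_step(states, divisions, lattice, probs, rng)
            n_h = n_h + log["divisions"] - log["conversions"]
            n_s = n_s + log["conversions"] - log["deaths"]
            min_h[active] = np.minimum(min_h[active], n_h)
            max_h[active] = np.maximum(max_h[active], n_h)
            new_cells[active] += log["divisions"]
            final_nh[active] = n_h
            final_ns[active] = n_s
            cur_frozen = batch_frozen_mask(states, divisions, n_h, n_s, lattice, probs)
            frozen[active] = cur_frozen

    # classify rows, then aggregate per grid point
    recovered = frozen & (
        (final_nh == n)
        | ((survival_criterion == "healthy_remaining") & (final_nh > 0) & (final_ns == 0))
    )
    died = frozen & (final_nh == 0) & (final_ns == 0)
    coexisting = ~(recovered | died)

    def agg(arr, red, mask=None):
        a = arr.reshape(n_pts, n_replicas).astype(float)
        if mask is not None:
            a = np.where(mask.reshape(n_pts, n_replicas), a, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return red(a, axis=1).reshape(shape)

    survival = agg(final_nh / n, np.mean)
    n_rec = agg(recovered, np.sum).astype(np.int64)
    n_die = agg(died, np.sum).astype(np.int64)
    n_co = agg(coexisting, np.sum).astype(np.int64)
    mdiv = agg(new_cells, np.mean)
    mminh = agg(min_h, np.nanmean, mask=recovered)
    mmaxh = agg(max_h, np.nanmean, mask=died)

    return SweepGrid(
        fixed_param=fixed_param,
        fixed_value=fixed_value,
        row_param=row_param,
        col_param=col_param,
        row_values=row_values,
        col_values=col_values,
        n_replicas=n_replicas,
        n_sites=lattice.n_sites,
        survival=survival,
        n_recovered=n_rec,
        n_died=n_die,
        n_coexisting=n_co,
        mean_divisions=mdiv,
        mean_min_h_recovered=mminh,
        mean_max_h_died=mmaxh,
    )


def estimate_critical_ratio(
    grid: SweepGrid,
    threshold: float = 0.95,
    tol: float = 0.01,
    min_offset_columns: int = 0,
    direction: str = "falls_below",
) -> CriticalRatio | None:
    """Per-column first crossing of the survival threshold, averaged.

    Scanning each column by ascending row ratio, the crossing is the first
    point with survival <= ``threshold + tol`` (``falls_below``) or
    >= ``threshold - tol`` (``rises_above``).  The leading
    ``min_offset_columns`` columns are excluded from the average (near the
    origin the boundary still depends on the second parameter).  Returns
    ``None``, with a warning, when no retained column crosses.
    """
    ratios = grid.ratio("gamma", "beta") if direction == "falls_below" else grid.ratio(
        "beta", "gamma"
    )
    crossings: dict[float, float] = {}
    for j in range(min_offset_columns, len(grid.col_values)):
        col_ratio = ratios[:, j]
        order = np.argsort(col_ratio, kind="stable")
        surv = grid.survival[order, j]
        if direction == "falls_below":
            hit = np.nonzero(surv <= threshold + tol)[0]
        else:
            hit = np.nonzero(surv >= threshold - tol)[0]
        if hit.size:
            crossings[float(grid.col_values[j])] = float(col_ratio[order][hit[0]])
    if not crossings:
        warnings.warn("no column crosses the survival threshold; no critical ratio")
        return None
    vals = np.array(list(crossings.values()))
    return CriticalRatio(
        value=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        crossings=crossings,
        threshold=threshold,
    )


def fit_size_scaling(pairs) -> tuple[float, float]:
    """Least-squares slope through the origin of gamma/beta* against N.

    ``pairs`` is a sequence of ``(n_sites, ratio)`` where ``ratio`` is a
    float or a :class:`CriticalRatio`.  Returns ``(slope, stderr)``.
    """
    if len(pairs) < 3:
        raise ValueError("size scaling needs at least 3 tissue sizes")
    n = np.array([p[0] for p in pairs], dtype=float)
    r = np.array(
        [p[1].value if isinstance(p[1], CriticalRatio) else float(p[1]) for p in pairs]
    )
    slope = float((n * r).sum() / (n * n).sum())
    resid = r - slope * n
    dof = len(pairs) - 1
    se = float(np.sqrt((resid**2).sum() / dof / (n * n).sum()))
    return slope, se


def scan_first_death(
    lattice: Lattice,
    initial,
    base_params: Parameters,
    fixed_value: float,
    col_param: str,
    col_values,
    ratios,
    n_replicas: int,
    master_seed,
    t_max: float = 12000.0,
    engine: str = "auto",
) -> tuple[float | None, float | None, dict[float, float]]:
    """First gamma/beta ratio with at least one all-dead replica, per column.

    Ascends ``ratios`` (gamma expressed as a multiple of the fixed beta)
    column by column and stops each column at the first ensemble
    containing a dead replica, which makes long-horizon boundary scans
    affordable; the full-grid equivalent is :func:`classify_phase` on a
    :func:`run_sweep` grid.  Returns ``(mean, sd, per-column ratios)``.
    """
    from .simulate import run_ensemble

    ratios = np.asarray(ratios, dtype=float)
    col_values = np.asarray(col_values, dtype=float)
    if isinstance(master_seed, np.random.SeedSequence):
        ss = master_seed
    else:
        ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(col_values) * len(ratios))
    found: dict[float, float] = {}
    for j, cv in enumerate(col_values):
        for i, ratio in enumerate(ratios):
            params = replace(
                base_params,
                beta=fixed_value,
                gamma=ratio * fixed_value,
                **{col_param: cv},
            )
            ens = run_ensemble(
                lattice,
                initial,
                params,
                n_replicas,
                children[j * len(ratios) + i],
                t_max=t_max,
                engine=engine,
            )
            if ens.outcome_counts["died"] > 0:
                found[float(cv)] = float(ratio)
                break
    if not found:
        return None, None, found
    vals = np.array(list(found.values()))
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd, found


def classify_phase(grid: SweepGrid) -> PhaseMap:
    """Observed-outcome labels per point plus the first-death boundary.

    The label at a point is the set of outcomes seen across its replicas:
    S (some replica recovered), D (some replica died), C (some replica
    coexisted), concatenated in that order.  The first-death boundary is,
    per column, the smallest scanned ratio with at least one dead replica;
    it is reported as mean +- sd over the columns where death appears.
    """
    shape = grid.survival.shape
    labels = np.empty(shape, dtype=object)
    for i in range(shape[0]):
        for j in range(shape[1]):
            lab = ""
            if grid.n_recovered[i, j] > 0:
                lab += "S"
            if grid.n_died[i, j] > 0:
                lab += "D"
            if grid.n_coexisting[i, j] > 0:
                lab += "C"
            labels[i, j] = lab

    ratios = grid.ratio("gamma", "beta")
    by_col: dict[float, float] = {}
    for j in range(shape[1]):
        order = np.argsort(ratios[:, j], kind="stable")
        died = grid.n_died[order, j] > 0
        hit = np.nonzero(died)[0]
        if hit.size:
            by_col[float(grid.col_values[j])] = float(ratios[order, j][hit[0]])
    if by_col:
        vals = np.array(list(by_col.values()))
        fd, fd_sd = float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    else:
        fd = fd_sd = None
    return PhaseMap(
        labels=labels,
        row_values=grid.row_values,
        col_values=grid.col_values,
        first_death_ratio=fd,
        first_death_sd=fd_sd,
        first_death_by_column=by_col,
    )
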