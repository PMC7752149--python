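"""Derived ensemble statistics: Loss, Gain, healthy-population thresholds.

Loss quantifies how far below its initial value the healthy population
dips in runs that eventually recover:

    Loss = (<min(H)> - H_i) / H_i * 100%      (over recovered runs)

Gain is the mirror statistic for runs that end in complete death:

    Gain = (<max(H)> - H_i) / H_i * 100%      (over died runs)

min/max include the initial time point, so Loss <= 0 <= Gain always.
``min_healthy_threshold`` extracts the saturation value of the rescaled
minimum healthy population <min(H)>/N: binned by the final mean healthy
fraction, the survivor minimum flattens to a critical fraction below
which damage tends to be irreversible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import EnsembleResult
from .sweep import SweepGrid

__all__ = [
    "DamageStats",
    "loss_gain",
    "grid_loss_gain",
    "mean_gain",
    "min_healthy_threshold",
    "new_hepatocyte_surface",
]


@dataclass
class DamageStats:
    """Loss/Gain summary of one ensemble; absent statistics are None."""

    loss_pct: float | None
    gain_pct: float | None
    min_h_frac: float | None
    h_i: int
    n_recovered: int
    n_died: int
    n_excluded: int  # runs that reached neither absorbing state


def loss_gain(ensemble: EnsembleResult, h_i: int) -> DamageStats:
    """Loss over recovered runs, Gain over died runs.

    Non-absorbing (coexisting) runs are excluded from both statistics and
    reported in ``n_excluded``.  A statistic with no qualifying runs is
    ``None`` rather than zero.
    """
    rec = [r for r in ensemble.runs if r.outcome == "recovered"]
    die = [r for r in ensemble.runs if r.outcome == "died"]
    loss = gain = min_frac = None
    if rec:
        mean_min = float(np.mean([r.min_h for r in rec]))
        loss = (mean_min - h_i) / h_i * 100.0
        min_frac = mean_min / ensemble.n_sites
    if die:
        mean_max = float(np.mean([r.max_h for r in die]))
        gain = (mean_max - h_i) / h_i * 100.0
    return DamageStats(
        loss_pct=loss,
        gain_pct=gain,
        min_h_frac=min_frac,
        h_i=h_i,
        n_recovered=len(rec),
        n_died=len(die),
        n_excluded=ensemble.n_replicas - len(rec) - len(die),
    )


def grid_loss_gain(grid: SweepGrid, h_i: int) -> pd.DataFrame:
    """Per-grid-point Loss and Gain (NaN where the statistic is absent)."""
    df = grid.to_dataframe()
    df["loss_pct"] = (df["mean_min_h_recovered"] - h_i) / h_i * 100.0
    df["gain_pct"] = (df["mean_max_h_died"] - h_i) / h_i * 100.0
    return df


def mean_gain(grid: SweepGrid, h_i: int) -> float:
    """Mean Gain (%) across the grid points where any replica died."""
    gain = (grid.mean_max_h_died - h_i) / h_i * 100.0
    vals = gain[np.isfinite(gain)]
    if vals.size == 0:
        raise ValueError("no grid point has a replica that died; Gain undefined")
    return float(vals.mean())


def min_healthy_threshold(
    grids,
    n_bins: int = 10,
    max_survival: float = 0.5,
) -> tuple[float, float, pd.DataFrame]:
    """Saturation value of <min(H)>/N among surviving runs.

    Pools grid points from one or more sweeps (possibly at different
    tissue sizes), bins the per-point survivor minimum fraction by the
    point's final mean healthy fraction <H>/N (``n_bins`` equal-width bins
    on [0, 1]) and averages the per-bin means over the low-survival bins
    (bin center <= ``max_survival``), where the curve has flattened to its
    plateau.  Returns ``(plateau, sd across plateau bins, bin table)``.
    """
    if isinstance(grids, SweepGrid):
        grids = [grids]
    surv, frac = [], []
    for g in grids:
        m = np.isfinite(g.mean_min_h_recovered)
        surv.append(g.survival[m].ravel())
        frac.append((g.mean_min_h_recovered[m] / g.n_sites).ravel())
    surv = np.concatenate(surv)
    frac = np.concatenate(frac)
    if surv.size == 0:
        raise ValueError("no surviving runs anywhere; threshold undefined")

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(surv, edges) - 1, 0, n_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rows = []
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            rows.append(
                {
                    "bin_center_h_frac": centers[b],
                    "mean_min_h_frac": float(frac[sel].mean()),
                    "n_points": int(sel.sum()),
                }
            )
    table = pd.DataFrame(rows)
    plateau_bins = table[table["bin_center_h_frac"] <= max_survival]
    if plateau_bins.empty:
        raise ValueError("no populated bins below the plateau cutoff")
    plateau = float(plateau_bins["mean_min_h_frac"].mean())
    sd = float(plateau_bins["mean_min_h_frac"].std(ddof=1)) if len(plateau_bins) > 1 else 0.0
    return plateau, sd, table


def new_hepatocyte_surface(grid: SweepGrid) -> tuple[np.ndarray, tuple[float, float]]:
    """Mean total divisions per grid point, plus the peak's location.

    Returns ``(surface, (row_value, col_value))`` where the surface has
    the grid's (n_rows, n_cols) shape and the location is in hours.
    """
    surface = grid.mean_divisions
    i, j = np.unravel_index(np.nanargmax(surface), surface.shape)
    return surface, (float(grid.row_values[i]), float(grid.col_values[j]))
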