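"""Numba-accelerated ensemble engine.

A single jitted kernel advances a stack of independent replica rows (each
with its own rule probabilities) through all timesteps, applying the same
scheduler as the numpy kernels in :mod:`hepatoca.core`: conversion and
death decided from the start-of-step snapshot, then queued proliferation
with uniform-winner conflict resolution (implemented by reservoir
sampling, which draws the winner uniformly among the claimants of each
contested site, independently across sites — equivalent to shuffling the
queue and letting the first claimant win).

The kernel uses numba's own legacy-numpy RNG, seeded once per call, so
results are deterministic given the seed but drawn from a different
stream than the numpy engine.  Statistical agreement between the two
engines is checked against the exact Markov-chain oracle in the tests.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (a and callable(a[0])) else a[0]


@njit(cache=True)
def _simulate_rows(
    states,  # (R, N) uint8, modified in place
    divisions,  # (R, N) int32, modified in place
    p_p,  # (R,) float64
    p_c,  # (R,) float64
    p_d,  # (R,) float64
    eps,  # float64
    nbr1,  # (N, d1) int64, padded with -1
    nbr1_cnt,  # (N,) int64
    conv,  # (N, dc) int64, padded with -1
    conv_cnt,  # (N,) int64
    t_div,  # (N,) float64 conversion-rule normalizer per site
    cap,  # int64, negative = unbounded
    death_first,  # boolean
    snapshot_vacancies,  # boolean
    n_steps,  # int64
    seed,  # int64
    trail_start,  # int64 step index where trailing-window stats begin
    min_h,  # (R,) int64 in/out
    max_h,  # (R,) int64 in/out
    new_cells,  # (R,) int64 out
    frozen,  # (R,) bool in/out
    t_absorb_step,  # (R,) int64 out, -1 while unabsorbed
    trail_sum,  # (R, 3) float64 out
    trail_sumsq,  # (R, 3) float64 out
):
    np.random.seed(seed)
    n_rows, n = states.shape
    snap = np.empty(n, dtype=np.uint8)
    convert = np.empty(n, dtype=np.uint8)
    claim_t = np.empty(n, dtype=np.int64)
    claim_cnt = np.empty(n, dtype=np.int64)
    winner = np.empty(n, dtype=np.int64)
    trail_n = 0

    for k in range(1, n_steps + 1):
        in_trail = k >= trail_start
        if in_trail:
            trail_n += 1
        any_active = False
        for r in range(n_rows):
            if frozen[r]:
                continue
            any_active = True
            row = states[r]
            div = divisions[r]
            for i in range(n):
                snap[i] = row[i]

            if death_first:
                for i in range(n):
                    if snap[i] == 1 and np.random.random() < p_d[r]:
                        row[i] = 2
                for i in range(n):
                    convert[i] = 0
                    if row[i] == 0:
                        ns = 0
                        for m in range(conv_cnt[i]):
                            if row[conv[i, m]] == 1:
                                ns += 1
                        frac = ns / t_div[i] + eps
                        if frac > 1.0:
                            frac = 1.0
                        if np.random.random() < p_c[r] * frac:
                            convert[i] = 1
                for i in range(n):
                    if convert[i] == 1:
                        row[i] = 1
            else:
                for i in range(n):
                    convert[i] = 0
                    if snap[i] == 0:
                        ns = 0
                        for m in range(conv_cnt[i]):
                            if snap[conv[i, m]] == 1:
                                ns += 1
                        frac = ns / t_div[i] + eps
                        if frac > 1.0:
                            frac = 1.0
                        if np.random.random() < p_c[r] * frac:
                            convert[i] = 1
                for i in range(n):
                    if snap[i] == 1 and np.random.random() < p_d[r]:
                        row[i] = 2
                for i in range(n):
                    if convert[i] == 1:
                        row[i] = 1

            # proliferation: queue entry, uniform target choice, uniform
            # winner per contested target via reservoir sampling
            for i in range(n):
                claim_t[i] = -1
                claim_cnt[i] = 0
                winner[i] = -1
            for i in range(n):
                if row[i] != 0:
                    continue
                if cap >= 0 and div[i] >= cap:
                    continue
                n_empty = 0
                for m in range(nbr1_cnt[i]):
                    j = nbr1[i, m]
                    e = snap[j] == 2 if snapshot_vacancies else row[j] == 2
                    if e:
                        n_empty += 1
                if n_empty == 0:
                    continue
                if np.random.random() >= p_p[r]:
                    continue
                pick = int(np.random.random() * n_empty)
                if pick >= n_empty:
                    pick = n_empty - 1
                seen = 0
                for m in range(nbr1_cnt[i]):
                    j = nbr1[i, m]
                    e = snap[j] == 2 if snapshot_vacancies else row[j] == 2
                    if e:
                        if seen == pick:
                            claim_t[i] = j
                            break
                        seen += 1
            for i in range(n):
                t = claim_t[i]
                if t < 0:
                    continue
                claim_cnt[t] += 1
                if np.random.random() < 1.0 / claim_cnt[t]:
                    winner[t] = i
            for t in range(n):
                i = winner[t]
                if i < 0:
                    continue
                row[t] = 0
                div[t] = 0
                div[i] += 1
                new_cells[r] += 1

            # censuses, extremes, freeze check
            nh = 0
            ns_tot = 0
            for i in range(n):
                if row[i] == 0:
                    nh += 1
                elif row[i] == 1:
                    ns_tot += 1
            if nh < min_h[r]:
                min_h[r] = nh
            if nh > max_h[r]:
                max_h[r] = nh
            if in_trail:
                fh = nh / n
                fs = ns_tot / n
                fd = 1.0 - fh - fs
                trail_sum[r, 0] += fh
                trail_sum[r, 1] += fs
                trail_sum[r, 2] += fd
                trail_sumsq[r, 0] += fh * fh
                trail_sumsq[r, 1] += fs * fs
                trail_sumsq[r, 2] += fd * fd

            done = nh == 0 and ns_tot == 0
            if eps == 0.0:
                if nh == n:
                    done = True
                elif cap >= 0 and ns_tot == 0 and nh > 0:
                    can = False
                    for i in range(n):
                        if row[i] == 0 and div[i] < cap:
                            for m in range(nbr1_cnt[i]):
                                if row[nbr1[i, m]] == 2:
                                    can = True
                                    break
                        if can:
                            break
                    if not can:
                        done = True
            if done:
                frozen[r] = True
                t_absorb_step[r] = k
        if not any_active:
            break
    return trail_n


def simulate_rows(
    lattice,
    probs,
    states: np.ndarray,
    divisions: np.ndarray,
    n_steps: int,
    seed: int,
    trail_start: int | None = None,
):
    """Run the jitted kernel over an (R, N) stack; returns a stats dict.

    ``probs`` is a :class:`hepatoca.core.RuleProbs` whose p_p/p_c/p_d may
    be scalars or per-row arrays.  ``seed`` must be a non-negative int
    below 2**32.  ``trail_start`` is the step index from which
    trailing-window fraction statistics accumulate (defaults to no
    accumulation).
    """
    n_rows, n = states.shape
    idx1, cnt1 = lattice.adjacency("first")
    idxc, cntc = lattice.adjacency(probs.neighbor_order)
    # replace the n_sites padding sentinel with -1 for the kernel
    nbr1 = np.where(idx1 == n, -1, idx1).astype(np.int64)
    conv = np.where(idxc == n, -1, idxc).astype(np.int64)
    from .core import resolve_t_norm

    if resolve_t_norm(probs.t_norm, lattice) == "per_site":
        t_div = cntc.astype(np.float64)
    else:
        t_div = np.full(n, float(cntc.max()))

    def rowvec(v):
        a = np.asarray(v, dtype=np.float64).reshape(-1)
        return np.full(n_rows, a[0]) if a.size == 1 else np.ascontiguousarray(a)

    n_h = (states == 0).sum(axis=1).astype(np.int64)
    n_s = (states == 1).sum(axis=1).astype(np.int64)
    min_h = n_h.copy()
    max_h = n_h.copy()
    new_cells = np.zeros(n_rows, dtype=np.int64)
    t_absorb_step = np.full(n_rows, -1, dtype=np.int64)
    trail_sum = np.zeros((n_rows, 3))
    trail_sumsq = np.zeros((n_rows, 3))

    # rows frozen from the start
    from .core import batch_frozen_mask

    frozen = batch_frozen_mask(states, divisions, n_h, n_s, lattice, probs)
    t_absorb_step[frozen] = 0

    trail_n = _simulate_rows(
        states,
        divisions,
        rowvec(probs.p_p),
        rowvec(probs.p_c),
        rowvec(probs.p_d),
        float(probs.epsilon),
        nbr1,
        cnt1.astype(np.int64),
        conv,
        cntc.astype(np.int64),
        t_div,
        np.int64(-1 if probs.division_cap is None else probs.division_cap),
        probs.update_order == "death_first",
        not probs.same_step_vacancies,
        np.int64(n_steps),
        np.int64(seed),
        np.int64(trail_start if trail_start is not None else n_steps + 1),
        min_h,
        max_h,
        new_cells,
        frozen,
        t_absorb_step,
        trail_sum,
        trail_sumsq,
    )
    return {
        "min_h": min_h,
        "max_h": max_h,
        "new_cells": new_cells,
        "frozen": frozen,
        "t_absorb_step": t_absorb_step,
        "trail_sum": trail_sum,
        "trail_sumsq": trail_sumsq,
        "trail_n": trail_n,
        "final_nh": (states == 0).sum(axis=1),
        "final_ns": (states == 1).sum(axis=1),
    }
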