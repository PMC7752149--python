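# Model and methods

## The model

`hepatoca` simulates the response of a liver lobule to an acute
pericentral (centrilobular) injury of the kind produced by an
acetaminophen overdose. Hepatocytes occupy the sites of a lattice — a 1D
cord of `N` cells running from the central vein (CV) to a portal triad
(PT), a 2D hexagonal lobule of `N = 3·N_L·(N_L+1)` cells in `N_L`
concentric rings around an unmodeled CV, or a 3D stack of such lobule
planes. Each site is healthy (H), stressed (S) or empty after a cell has
died (D), and the tissue advances in discrete timesteps `Δt` (default
0.25 h) under three stochastic rules, each parameterized by a timescale
in hours:

* **Conversion** (`β`): injury propagates by contact. A healthy cell
  draws `r1 ≤ Δt/β` and `r2 ≤ N_s/T`, where `N_s` is its number of
  stressed neighbors and `T` its neighborhood size; both must succeed for
  the cell to become stressed. The two draws are fused into a single
  uniform draw against the product probability, which is distributionally
  identical.
* **Death** (`γ`): a stressed cell dies with probability `Δt/γ`,
  independent of its neighborhood, leaving an empty site.
* **Proliferation** (`α`): a healthy cell with at least one empty contact
  neighbor enters a division queue with probability `Δt/α` (contact
  inhibition: without a vacancy it never divides). Each queued cell
  claims one of its empty neighbors uniformly at random; when several
  cells claim the same site, the queue is effectively shuffled and one
  claimant wins. The daughter fills the claimed site.

All probabilities require `0 < Δt ≤ min(α, β, γ)`. A tissue that reaches
all-H has recovered; all-D is tissue death; a run still mixed at the
horizon is classified as coexisting. With spontaneous stress (`ε > 0`,
below) the all-H state is not absorbing and such runs are also scored by
the horizon rule.

## Scheduler

The composition of the three rules within one timestep is not uniquely
determined by the rule statements, so it is explicit and configurable:

* Default: conversion and death are both decided from the start-of-step
  snapshot (a cell converted this step cannot die this step), then
  applied; proliferation then runs against the post-death vacancy set, so
  division is coupled to the death of a neighbor within the same step.
* `update_order="death_first"` resolves deaths before conversion (dying
  cells do not convert their neighbors that step);
  `same_step_vacancies=False` restricts proliferation to vacancies that
  already existed at the start of the step.

Measured outcomes (survival probabilities, phase boundaries) differ only
marginally between these variants at the default timestep.

## Neighborhoods and the normalizer T

First-order neighborhoods are the contact neighbors: up to 2 on the
chain, 6 on the hexagonal lattice, 8 on the stacked lattice (6 in-plane
plus the two vertically adjacent sites). `neighbor_order =
"first_and_second"` extends the *conversion* rule to the distance-2
shell (12 additional sites for interior cells), emulating a short-range
diffusible signal; proliferation always uses contact neighbors. The
second-order shell is defined by hexagonal distance exactly 2 and
truncates at the lobule boundary (no wrapping).

The normalizer `T` in the conversion rule defaults to a geometry-aware
convention (`t_norm="auto"`):

* chain: fixed `T = 2` everywhere. The cord terminates in the CV on one
  side and the portal field on the other — real anatomical neighbors
  that are never stressed, so end cells keep the full coordination.
* hexagonal lobules and stacks: `T` is the actual neighbor-list length,
  smaller at the lobule rim (and at the first ring, which abuts the CV).

Both conventions can be forced (`"bulk"`, `"per_site"`). The distinction
only matters at boundary sites; it shifts the 1D critical ratio by
roughly 0.15 and the 2D first-death boundary by roughly one unit of
γ/β, and the defaults are the pair under which the package reproduces
its reference statistics in both geometries.

## Baseline noise ε

`ε` models spontaneous stress without a stressed contact: the neighbor
gate becomes `r2 ≤ N_s/T + ε`, so an isolated healthy cell converts at
rate `(Δt/β)·ε` per step. Composing ε inside the β-gate (rather than as
an independent per-step Bernoulli) is essential: an unconditional ε of
0.1 per 0.25 h step would destroy the tissue at parameter values where
the coexistence state is in fact only mildly degraded.

## Division budgets

`division_cap` limits how many times any individual cell may divide; a
daughter starts with a fresh budget and the parent's counter stays at
the parent. Capped tissues can freeze in mixed configurations in which
no stressed cells remain but the surviving healthy cells are either out
of divisions or contact-inhibited; such runs are scored with the relaxed
survival criterion (healthy cells present, no stressed cells), which is
also the default whenever a cap is active. A cap of 1 eliminates the 2D
coexistence state; a cap of 2 restores it.

## Ensembles, seeds and engines

Replicas are vectorized along a row axis. Two interchangeable engines
implement the identical scheduler: a pure-numpy kernel set (also used
for single trajectories and perturbation runs) and a numba-compiled
kernel that advances the whole replica stack, used by default for
ensembles and parameter sweeps (roughly an order of magnitude faster; a
2D lobule ensemble of 100 replicas over 48,000 steps runs in under a
minute). The engines consume different random streams, so their outputs
agree statistically, not bitwise; both are bit-reproducible given
(configuration, master seed), and both are validated against the exact
small-chain oracle below. Parameter sweeps run every grid point's
replicas as one stacked ensemble with per-row rule probabilities drawn
from a single master-seeded stream.

## Exact oracle

For chains small enough to enumerate (N ≤ 4, optionally with division
counters), `exact_absorption` builds the exact one-step Markov kernel
induced by the scheduler — enumerating conversion and death subsets,
division-queue subsets, target choices and conflict winners — and
solves the linear absorption equations for the recovery/death split and
the expected absorption time. The enumeration is written directly from
the rule definitions and shares no code with the simulation kernels; the
test suite requires Monte-Carlo agreement within three standard errors
at 10,000 replicas.

## Derived statistics

* **Survival probability**: ensemble mean of the final healthy fraction
  `⟨H⟩/N` (equal to the fraction of recovered runs when every replica
  absorbs).
* **Critical ratio `γ/β*`**: per grid column, the first scanned γ/β at
  which survival drops to ≤ 0.96 (0.95 plus one replica at 100
  replicas), averaged over columns; columns at small α/β can be excluded
  (`min_offset_columns`), since the boundary is α-dependent there. With
  a shallow survival gradient this first-crossing estimator carries a
  noise-induced downward bias of order 0.1–0.2 in the ratio at 100
  replicas; it is reported with the between-column sd.
* **Loss / Gain**: `(⟨min(H)⟩ − H_i)/H_i·100%` over recovered runs and
  `(⟨max(H)⟩ − H_i)/H_i·100%` over dying runs; extremes include the
  initial time, non-absorbing runs are excluded and counted.
* **Minimum-healthy threshold**: per-point survivor `⟨min(H)⟩/N` binned
  by final `⟨H⟩/N` (10 equal-width bins); the plateau is the mean over
  populated bins with centers ≤ 0.5, where the curve has flattened.
* **Coexistence statistics**: trailing-window (final 20% of the horizon)
  mean ± sd of the (H, S, D) fractions, pooled over coexisting replicas.
* **First-death boundary**: per column, the smallest γ/β with at least
  one all-dead replica. Detection depends on replica count and horizon;
  `scan_first_death` ascends each column and stops at the first death so
  long horizons stay affordable.

## Default study conditions

`Δt = 0.25 h`; 1D reference tissue `N = 10` with `H_i = 6, S_i = 4`
(pericentral 40% damage; "40%" on a chain means `round(0.4·N)` stressed
sites nearest the CV); 2D reference lobule `N_L = 10` (`N = 330`) with 4
stressed rings (`H_i = 270, S_i = 60`); 100 replicas per ensemble;
parameter axes stepped by 0.5 h from 0.25 h, spanning up to ~5–6× the
fixed timescale, the range over which the phase structure plays out. Horizons: 4,000 h
for 1D sweeps (absorption is much faster; the cap is a safety net),
12,000 h (≈500 days) for 2D boundary scans, 2,000 h for 2D coexistence
statistics, where the trailing window is wholly inside the plateau that
is reached within a few hundred hours. The acceptance script runs 2D
boundary scans at 40 replicas; with fewer replicas than the reference
100 the first-death boundary can only be detected at equal or higher
γ/β.

## What the simulations do and do not show

Everything here is a lattice caricature of a lobule: cells neither move
nor grow, sinusoids, immune agents and diffusible mediators are absent,
and the stressed→healthy repair observed in vivo is deliberately not
modeled (adding it would shift, not qualitatively change, the phase
boundaries). Agreement of the simulated phase structure with the
reference statistics therefore validates the implementation of this
idealized model, not the biology; the biologically parameterized corner
(α ≈ 20 h, β ≈ 1–2 h, γ ≈ 2–4 h) sits deep in the recovery region,
where the model's prediction — recovery with a transient loss of
roughly 15–30% of the healthy population — is robust to every scheduler
variant we expose, although the exact printed survival value at the
strongest per-step rates is not recovered at `Δt = 0.25` (see the
per-step discreteness note below).

## Numerical notes

* Random draws use one `numpy.random.Generator` per run (numpy engine)
  or numba's seeded legacy RNG (compiled engine); derived seeds stay
  below 2^31.
* Uniform draws are compared strictly (`u < p`), so a probability of 0
  never fires and a probability of 1 always does.
* Conflict resolution by reservoir sampling is exactly equivalent to the
  shuffle-the-queue rule: the winner is uniform among claimants,
  independently across contested sites, because claimant sets of
  distinct sites are disjoint.
* Per-step probabilities depend on the absolute timescales, not only
  their ratios: halving all of α, β, γ at fixed ratios coarsens the
  dynamics. Near the reference conditions this shifts survival by under
  one percentage point per factor of two; at per-step probabilities
  approaching 1 the discrete and fine-grained dynamics separate by
  several percentage points.
* Degenerate inputs: a lattice with one site, empty damage (all-H,
  absorbing at ε = 0), all-D initial states (absorbed at t = 0) and
  `γ = Δt` (stressed cells die in one step) are all exercised in tests.
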