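# hepatoca

Stochastic cellular-automaton simulation of liver-lobule damage and
repair.

An acetaminophen (APAP) overdose kills hepatocytes around the central
vein (CV) of each liver lobule; the injury then propagates outward as
stressed cells sensitize their neighbors, while surviving hepatocytes
proliferate into the space left by the dead. Whether the tissue
recovers, dies, or settles into a persistently damaged state is decided
by the competition between three timescales. `hepatoca` implements this
competition as a probabilistic cellular automaton for anyone studying
the phase structure of such injury–repair dynamics: each lattice site is
a hepatocyte in state H (healthy), S (stressed) or D (dead/empty), and
per timestep Δt

* a healthy cell converts H→S with probability `(Δt/β) · N_s/T`
  (`N_s` stressed neighbors out of `T`),
* a stressed cell dies S→D with probability `Δt/γ`,
* a healthy cell next to an empty site divides with probability `Δt/α`,
  the daughter filling the vacancy (contact-inhibited growth; contested
  vacancies are resolved by a random shuffle).

Lattices are a 1D CV→PT cord, a 2D hexagonal lobule (`N = 3·N_L·(N_L+1)`
sites in `N_L` rings around an unmodeled CV), or a 3D stack of lobule
planes. On top of single runs the package provides seeded replica
ensembles, survival-probability phase diagrams, critical-ratio
estimation (`γ/β*`, where ensemble survival first drops to ≈0.95),
Loss/Gain damage statistics, minimum-healthy-population thresholds,
coexistence-state statistics, perturbation protocols, an exact
Markov-chain oracle for small chains, and a CLI. See
[docs/methods.md](docs/methods.md) for the full model description.

## Worked example

The exact oracle for a single stressed cell: death is the only
applicable rule, so the tissue dies with certainty after a geometric
waiting time with mean γ.

```python
>>> import numpy as np, hepatoca as hc
>>> lat = hc.build_chain(1)
>>> state = hc.TissueState(np.array([1], dtype=np.uint8))   # one S cell
>>> res = hc.exact_absorption(lat, hc.Parameters(alpha=5, beta=5, gamma=2.5), state)
>>> round(res.p_death, 6), round(res.expected_time, 6)
(1.0, 2.5)
```

A lobule ensemble in the coexistence band (`γ/β = 2.45` with
`α = β = 5 h`): no replica ever recovers or dies; the three populations
fluctuate around a mixed steady state.

```python
>>> lobule = hc.build_hex_lobule(10)                        # N = 330
>>> init = hc.init_pericentral(lobule, hc.InitSpec("pericentral_layers", stressed_layers=4))
>>> ens = hc.run_ensemble(lobule, init, hc.Parameters(5, 5, 12.25), 20, 555, t_max=2000)
>>> ens.outcome_counts
{'recovered': 0, 'died': 0, 'coexisting': 20}
>>> [round(f, 2) for f in ens.steady_fractions_mean]
[0.54, 0.34, 0.12]
```

The trailing-window fractions say the settled tissue is 54% healthy,
34% stressed and 12% empty (± 0.06/0.04/0.04 across time and replicas).

From the command line, the base 1D experiment (N = 10, 40% pericentral
damage, 100 replicas):

```bash
$ hepatoca run -c configs/chain_run.yaml -o out/
survival_probability=0.9800 -> out
```

which writes `trajectory.csv` (one recorded step per row),
`replicas.csv` (per-replica outcome, min/max healthy count, divisions)
and `summary.json`. `hepatoca sweep` produces survival/divisions/Loss
maps over a parameter grid plus the `γ/β*` boundary estimate,
`hepatoca phase` the S/D/C phase classification, and `hepatoca perturb`
trajectories under scheduled state rewrites or parameter switches; the
`configs/` directory holds ready-made bundles for each.

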