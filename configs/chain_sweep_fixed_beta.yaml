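# survival phase space gamma x alpha at fixed beta = 5 h (1D, N = 10)
geometry: {kind: chain, n: 10}
params: {alpha: 5.0, beta: 5.0, gamma: 5.0, dt: 0.25}
init: {mode: pericentral_count, stressed_count: 4}
replicas: 100
seed: 1
t_max: 4000
out_dir: hepatoca_out/chain_sweep_fixed_beta
sweep:
  fixed: {param: beta, value: 5.0}
  rows: {param: gamma, start: 0.25, stop: 17.75, step: 0.5}
  cols: {param: alpha, start: 0.25, stop: 30.25, step: 0.5}
  min_offset_columns: 10   # exclude alpha/beta < 1 from the boundary average
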