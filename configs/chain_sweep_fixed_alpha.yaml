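# survival phase space gamma x beta at fixed alpha = 5 h (1D, N = 10)
geometry: {kind: chain, n: 10}
params: {alpha: 5.0, beta: 5.0, gamma: 5.0, dt: 0.25}
init: {mode: pericentral_count, stressed_count: 4}
replicas: 100
seed: 1
t_max: 4000
out_dir: hepatoca_out/chain_sweep_fixed_alpha
sweep:
  fixed: {param: alpha, value: 5.0}
  rows: {param: gamma, start: 0.25, stop: 26.25, step: 0.5}
  cols: {param: beta, start: 0.25, stop: 26.25, step: 0.5}
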