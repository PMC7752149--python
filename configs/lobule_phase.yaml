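# 2D hexagonal lobule phase map at fixed beta = 5 h, reduced replica count
geometry: {kind: hex_lobule, nl: 10}
params: {alpha: 5.0, beta: 5.0, gamma: 5.0, dt: 0.25}
init: {mode: pericentral_layers, stressed_layers: 4}
replicas: 20
seed: 1
t_max: 2000
out_dir: hepatoca_out/lobule_phase
sweep:
  fixed: {param: beta, value: 5.0}
  rows: {param: gamma, start: 0.25, stop: 36.25, step: 1.0}
  cols: {param: alpha, start: 5.25, stop: 50.25, step: 9.0}
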