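# coexistence state perturbed by a parameter switch to a recovery ratio
geometry: {kind: hex_lobule, nl: 10}
params: {alpha: 5.0, beta: 5.0, gamma: 12.25, dt: 0.25}
init: {mode: pericentral_layers, stressed_layers: 4}
replicas: 1
seed: 1
t_max: 8000
record_every: 40
out_dir: hepatoca_out/lobule_perturb
perturbations:
  - {at_time: 5000.25, kind: param_switch, params: {gamma: 0.25}}
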