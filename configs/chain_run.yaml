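# 1D hepatocyte cord, N = 10, 40% pericentral damage, base conditions
geometry: {kind: chain, n: 10}
params: {alpha: 5.0, beta: 5.0, gamma: 5.0, dt: 0.25}
init: {mode: pericentral_count, stressed_count: 4}
replicas: 100
seed: 1
t_max: 4000
record_every: 1
out_dir: hepatoca_out/chain_run
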