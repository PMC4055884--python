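# Sample-size planning: sustained 10-point difference in normalized activity
delta_pct: 10.0
n_grid: [5, 10, 15, 20, 25, 30]
alpha: 0.05
target_power: 0.80
reps: 500
seed: 7
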