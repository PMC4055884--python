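# Dose-finding study: saline vs 5% vs 10% acetic acid (biosensor arm)
seed: 5
fidelity: counts        # counts | events | trace
bin_width_min: 15
stable_window_min: 20
gamma_per_tail: 0.10
alpha: 0.05
timeline:
  acclimation_min: 30
  baseline_min: 60
  recovery_min: 30
  post_min: 80
groups:
  - {label: saline, n_fish: 12}
  - {label: acid_5pct, n_fish: 6}
  - {label: acid_10pct, n_fish: 8}
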