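cohort_n: 30000
master_seed: 42
out_dir: runs/desk
schedulers:
- FIFO
- HYPERBAND
- ASHA
- PBT
policy:
  n_trials: 16
  max_t: 50
fractions:
- 0.8
- 0.1
- 0.1
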