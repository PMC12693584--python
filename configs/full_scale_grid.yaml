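# Full-scale constant-population grid: the neutral control plus six
# synonymous-selection conditions (constant and 22%-partial at
# s in {1e-5, 1e-4, 1e-3}), 20 replicates of 22 x ~1.4 Mb exonic chunks
# at N=10,000.  This reproduces the unrescaled study design and is
# cluster-scale: expect thousands of CPU-hours.
defaults:
  n_replicates: 20
  n_chunks: 22
  rescale_Q: 1
  sim_overrides:
    target_exonic_bp: 1400000
scenarios:
  - name: control
    syn_model: neutral
    seed: 1000
  - name: constant_s1e-5
    syn_model: {kind: constant, s: 1.0e-5}
    seed: 2000
  - name: constant_s1e-4
    syn_model: {kind: constant, s: 1.0e-4}
    seed: 3000
  - name: constant_s1e-3
    syn_model: {kind: constant, s: 1.0e-3}
    seed: 4000
  - name: partial_s1e-5
    syn_model: {kind: partial, s: 1.0e-5, selected_fraction: 0.22}
    seed: 5000
  - name: partial_s1e-4
    syn_model: {kind: partial, s: 1.0e-4, selected_fraction: 0.22}
    seed: 6000
  - name: partial_s1e-3
    syn_model: {kind: partial, s: 1.0e-3, selected_fraction: 0.22}
    seed: 7000
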