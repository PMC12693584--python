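# Desk-scale experiment grid: neutral control plus pervasive weak and
# strong selection on synonymous mutations, rescaled by Q=40 with ~3.1 Mb
# of coding sequence per replicate.  Runs in a few minutes on one CPU:
#   dfesim pipeline --config configs/desk_scale_grid.yaml --out out/
defaults:
  n_replicates: 5
  n_chunks: 4
  rescale_Q: 40
  sim_overrides:
    target_exonic_bp: 775000
    burn_in_generations: 20000
    init: equilibrium
scenarios:
  - name: control
    syn_model: neutral
    seed: 11
  - name: constant_s1e-4
    syn_model: {kind: constant, s: 1.0e-4}
    seed: 22
  - name: constant_s1e-3
    syn_model: {kind: constant, s: 1.0e-3}
    seed: 33
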