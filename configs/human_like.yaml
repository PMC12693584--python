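# Human-like scenario: four-deme out-of-Africa demography (approximate
# Gutenkunst-style parameter values; see docs/methods.md) with a gamma
# DFE on synonymous mutations (shape 0.14, 2Ns-scale 55).  The full-scale
# design (10 replicates x 800 Mb) is cluster-scale; lower rescale_Q and
# raise target_exonic_bp to approach it.
defaults:
  n_replicates: 2
  n_chunks: 2
  rescale_Q: 100
  demography: out_of_africa
  sim_overrides:
    N: 7300
    mu: 1.44e-8
    target_exonic_bp: 100000
    burn_in_generations: 73000
    init: equilibrium
scenarios:
  - name: human_neutral_syn
    syn_model: neutral
    seed: 41
  - name: human_gamma_syn
    syn_model: {kind: gamma, gamma_shape: 0.14, gamma_scale_2Ns: 55.0}
    seed: 42
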