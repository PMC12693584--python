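# dfesim

Forward simulation and site-frequency-spectrum (SFS) inference for
studying how **selection on synonymous mutations** biases demographic
inference and the inferred **distribution of fitness effects (DFE)** of
nonsynonymous mutations.

The standard workflow for DFE inference from polymorphism data proceeds
in two steps: demographic parameters are estimated from the synonymous
SFS (assumed neutral), and a gamma DFE is then fit to the nonsynonymous
SFS conditional on that demography.  `dfesim` lets you violate the
neutrality assumption on purpose and watch what happens: a diploid
Wright–Fisher forward simulator generates exon/intron mosaic sequence
with linked selection under configurable models of synonymous selection
(neutral; constant `s`; partial — 22% of mutations selected; gamma), and
re-implementations of the two inference stages quantify the resulting
bias and its rescue.

The package is aimed at population geneticists who want a self-contained,
tested sandbox for this model-misspecification problem — for method
robustness checks, teaching, or extending the simulation designs.

## The model

- **Expected spectra (Poisson random field).**  Each unfolded SFS bin is
  an independent Poisson count.  At equilibrium
  `E[X_i] = θ ∫ C(n,i) x^(i-1) (1-x)^(n-i-1) R(x;γ) dx` with
  `R(x;γ) = (1-e^(-2γ(1-x)))/(1-e^(-2γ))`, `θ = 4N_a μ L` and
  `γ = 2 N_a s_het` (neutral limit `θ/i`).  Two-epoch (single size change
  `ν = N_cur/N_a` at time `T` in units of `2N_a` generations) spectra are
  solved exactly from the closed linear moment ODE of the sample spectrum
  (jackknife closure under selection).
- **Demographic fitting.**  Poisson composite likelihood over polymorphic
  bins, `θ` profiled analytically; 25-start Nelder–Mead in
  `(log ν, log T)` with bounds `ν ∈ (0, 3000]`, `T ∈ (0, 500]`; the
  two-epoch model is preferred when ΔLL > 3 (half the χ²(2 df) 95th
  percentile).  `N̂_a = θ̂_s / (4 μ L_s)`.
- **DFE fitting.**  `E[SFS_ns] = θ_ns ∫ SFS_unit(γ) dGamma(γ; shape, scale)`
  over a cached log grid of single-γ spectra under the fitted demography,
  with `θ_ns = 2.31 θ̂_s` (the NS:S mutational opportunity ratio); scale
  conversions via `s_dhet = γ / 2N_a`; discretization into the
  [0, 1e-5, 1e-4, 1e-3, 1e-2, ∞) bins by exact gamma-CDF differences.
- **Simulator.**  Wright–Fisher with multiplicative fitness
  `(1-hs)^het (1-s)^hom` (h = 0.5), Poisson recombination and mutation,
  NS:S ratio 2.31:1, the human nonsynonymous gamma DFE (shape 0.186,
  scale 706.899 on the 2Ns scale), optional multi-deme out-of-Africa
  histories, and exact population-genetic rescaling (`Q`).

See `docs/methods.md` for the numerics and design decisions.

## Worked example

Simulate one replicate (~3.1 Mb coding equivalent, rescaled Q=40) in
which **all synonymous mutations are weakly deleterious (s = 1e-4)**,
then run the standard inference pipeline on it:

```bash
$ dfesim simulate --config sim.yaml --replicates 1 --chunks 4 --seed 7 --out sim_out
replicate 0: 2018 syn / 2814 ns segregating sites

$ dfesim fit-demography --sfs sim_out/rep0_syn.fs --ls 936555 --starts 25 --seed 1 --out fit.json
two_epoch: LL=-232.24 theta_s=245

$ dfesim fit-dfe --ns-sfs sim_out/rep0_ns.fs --demog fit.json --starts 25 --seed 1 --out dfe.json
shape=0.0643 s_dhet=2.52669
```

(`sim.yaml` holds the SimConfig fields; see `configs/desk_scale_grid.yaml`
for the schema.)  The numbers tell the story of the bias:

- although the population never changed size, the synonymous spectrum is
  skewed toward rare variants by selection, and the two-epoch model wins
  decisively (`delta_ll = 47.2` in `fit.json`) with a spurious
  **2.0-fold expansion** (`nu = 1.98`);
- conditioning on that wrong demography distorts the nonsynonymous DFE:
  `dfe.json` reports discretized masses `[0.46, 0.07, 0.09, 0.10, 0.28]`
  across the neutral → strongly-deleterious bins, inflating the neutral
  (0.46 vs true 0.23) and strongly deleterious (0.28 vs true 0.20) ends,
  while a neutral-synonymous control replicate recovers shape ≈ 0.19 and
  `s_dhet` ≈ 0.02–0.03 (true shape 0.186).

The rescue: pair the same nonsynonymous spectrum with a demography fit
from known-neutral variants (`dfesim neutral-swap`), and the true DFE
parameters come back — the acceptance run below reports a swapped median
shape of 0.181 against the true 0.186.

The whole grid (control + selection conditions + swap) runs with:

```bash
dfesim pipeline --config configs/desk_scale_grid.yaml --out out/
dfesim neutral-swap --selected out/constant_s1e-4 --neutral out/control --out out/swap
dfesim report --in out/
```

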