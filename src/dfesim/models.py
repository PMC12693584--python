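"""Configuration types for the forward simulator.

``SelectionModel`` describes fitness effects per mutation class,
``GenomeLayout`` the exon/intron mosaic, ``SimConfig`` one simulation run,
``DemographyModel`` an optional multi-deme history that overrides the
constant population size.  All selection coefficients are stored as
homozygous magnitudes (deleterious); dominance defaults to additive
(h = 0.5), so the heterozygote coefficient is s/2 and the
population-scaled coefficient is gamma = 2*N*s_het = N*s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SelectionModel",
    "GenomeLayout",
    "generate_layout",
    "SimConfig",
    "DemographyModel",
    "rescale",
    "NS_GAMMA_SHAPE",
    "NS_GAMMA_SCALE_2NS",
    "NS_TO_S_RATIO",
]

#: Human nonsynonymous DFE: gamma distribution over 2*N*s with these
#: parameters; mean homozygous s = 0.186 * 706.899 / N = 0.013 at N=10,000.
NS_GAMMA_SHAPE = 0.186
NS_GAMMA_SCALE_2NS = 706.899

#: Mutational opportunity ratio of nonsynonymous to synonymous changes.
NS_TO_S_RATIO = 2.31


@dataclass(frozen=True)
class SelectionModel:
    """Fitness-effect model for one mutation class.

    kind:
      - ``neutral``: s = 0 always
      - ``constant``: every mutation gets the same homozygous s
      - ``partial``: fraction ``selected_fraction`` gets s, the rest 0
      - ``gamma``: s drawn from a gamma distribution specified on the
        2*N*s scale (``gamma_shape``, ``gamma_scale_2Ns``)
    """

    kind: str
    s: float = 0.0
    selected_fraction: float = 1.0
    gamma_shape: float | None = None
    gamma_scale_2Ns: float | None = None
    h: float = 0.5

    def __post_init__(self):
        if self.kind not in ("neutral", "constant", "partial", "gamma"):
            raise ValueError(f"unknown selection model kind {self.kind!r}")
        if self.s < 0:
            raise ValueError("s is stored as a deleterious magnitude, must be >= 0")
        if not 0.0 <= self.selected_fraction <= 1.0:
            raise ValueError("selected_fraction must lie in [0, 1]")
        if self.kind == "gamma":
            if not (self.gamma_shape and self.gamma_scale_2Ns) or min(
                self.gamma_shape, self.gamma_scale_2Ns
            ) <= 0:
                raise ValueError("gamma model needs positive shape and scale")


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered exon/intron mosaic tiling [0, total_length)."""

    segments: tuple  # of (start, end, kind) with kind in {"exon", "intron"}
    total_length: int
    exonic_length: int

    def __post_init__(self):
        prev = 0
        exonic = 0
        for start, end, kind in self.segments:
            if start != prev or end <= start:
                raise ValueError("segments must tile [0, total_length) without gaps")
            if kind not in ("exon", "intron"):
                raise ValueError(f"unknown segment kind {kind!r}")
            if kind == "exon":
                exonic += end - start
            prev = end
        if prev != self.total_length:
            raise ValueError("segments must end at total_length")
        if exonic != self.exonic_length:
            raise ValueError("exonic_length does not match segments")

    def exon_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(exon start positions, cumulative exonic length before each exon);
        maps an exonic coordinate to a genomic bp via searchsorted."""
        starts, cums = [], []
        acc = 0
        for start, end, kind in self.segments:
            if kind == "exon":
                starts.append(start)
                cums.append(acc)
                acc += end - start
        return np.asarray(starts, dtype=np.int64), np.asarray(cums, dtype=np.int64)


def generate_layout(
    mean_exon_len: float,
    mean_intron_len: float,
    target_exonic_bp: int,
    rng: np.random.Generator,
) -> GenomeLayout:
    """Draw a random alternating exon/intron mosaic.

    Exon and intron lengths are exponential with the given means (rounded,
    min 1 bp); exons are appended until the cumulative exonic sequence
    reaches ``target_exonic_bp``, so the realised exonic total is within
    one exon of the target.  ``mean_intron_len = 0`` yields a single exon.
    """
    if mean_exon_len <= 0 or target_exonic_bp <= 0:
        raise ValueError("mean_exon_len and target_exonic_bp must be positive")
    if mean_intron_len < 0:
        raise ValueError("mean_intron_len must be >= 0")
    if mean_intron_len == 0:
        L = int(target_exonic_bp)
        return GenomeLayout(((0, L, "exon"),), L, L)
    segments = []
    pos = 0
    exonic = 0
    while exonic < target_exonic_bp:
        e = max(1, int(round(rng.exponential(mean_exon_len))))
        e = min(e, int(target_exonic_bp) - exonic + max(1, int(mean_exon_len) // 4))
        segments.append((pos, pos + e, "exon"))
        pos += e
        exonic += e
        i = max(1, int(round(rng.exponential(mean_intron_len))))
        segments.append((pos, pos + i, "intron"))
        pos += i
    return GenomeLayout(tuple(segments), pos, exonic)


@dataclass(frozen=True)
class DemographyModel:
    """Multi-deme piecewise-constant demography.

    demes: tuple of (name, epochs) with epochs a tuple of
        (duration_generations, diploid_size); epochs run forward in time
        and a deme's first epoch starts at its founding.
    splits: tuple of (time_generations_from_start, parent, child).
    migration: tuple of (time_from_start, matrix) where matrix[d][src] is
        the per-generation probability that an offspring in deme d draws
        its parents from deme src (rows sum to <= 1; the remainder is
        same-deme); applies from that time until the next entry.
    """

    demes: tuple
    splits: tuple = ()
    migration: tuple = ()

    def __post_init__(self):
        for name, epochs in self.demes:
            for dur, size in epochs:
                if dur <= 0 or size < 1:
                    raise ValueError("epoch durations must be > 0 and sizes >= 1")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one forward simulation run (unscaled units).

    The defaults are the constant-size study design: N = 10,000 diploids,
    mu = 1.5e-8, r = 1e-8 per bp per generation, 100,000 burn-in plus
    1,000 further generations, a 100-haplotype sample, 1.4 Mb exonic /
    19.6 Mb intronic mosaic, NS:S ratio 2.31:1, and the human
    nonsynonymous gamma DFE.  ``rescale_Q`` divides N and the generation
    counts and multiplies mu, r and all s by Q, preserving N*mu, N*r and
    N*s.
    """

    N: int = 10_000
    mu: float = 1.5e-8
    r: float = 1e-8
    burn_in_generations: int = 100_000
    extra_generations: int = 1_000
    sample_n: int = 100
    target_exonic_bp: int = 1_400_000
    mean_exon_len: float = 300.0
    mean_intron_len: float = 4_200.0
    ns_to_s_ratio: float = NS_TO_S_RATIO
    ns_model: SelectionModel = field(
        default_factory=lambda: SelectionModel(
            "gamma", gamma_shape=NS_GAMMA_SHAPE, gamma_scale_2Ns=NS_GAMMA_SCALE_2NS
        )
    )
    syn_model: SelectionModel = field(default_factory=lambda: SelectionModel("neutral"))
    rescale_Q: int = 1
    seed: int | None = None
    demography: DemographyModel | None = None
    init: str = "blank"  # or "equilibrium": seed standing variation analytically
    purge_interval: int = 100
    #: multiplier applied to constant/partial selection coefficients at draw
    #: time; set by ``rescale`` so that N*s is invariant.  Gamma-model draws
    #: are specified on the 2*N*s scale and are converted with the current N,
    #: which makes them rescale-invariant automatically.
    s_scale: float = 1.0

    def __post_init__(self):
        if self.N < 2 or self.mu < 0 or self.r < 0:
            raise ValueError("need N >= 2 and non-negative mu, r")
        if self.sample_n > 2 * self.N // max(self.rescale_Q, 1):
            raise ValueError("sample_n exceeds the (rescaled) number of haplotypes")
        if self.init not in ("blank", "equilibrium"):
            raise ValueError("init must be 'blank' or 'equilibrium'")


def rescale(config: SimConfig, Q: int) -> SimConfig:
    """Return the config with population-genetic rescaling applied.

    N -> N/Q, mu -> mu*Q, r -> r*Q, generation counts -> /Q; selection
    coefficients are scaled at draw time inside the simulator so that
    N*s is invariant.  A constant/partial synonymous s that would reach
    s*Q >= 1 is an error (fitness would go non-positive)."""
    if Q < 1:
        raise ValueError("Q must be >= 1")
    if Q == 1:
        return config
    if config.syn_model.kind in ("constant", "partial") and config.syn_model.s * Q >= 1.0:
        raise ValueError(
            f"rescaled synonymous s = {config.syn_model.s * Q} >= 1 at Q = {Q}"
        )
    return replace(
        config,
        N=max(2, int(round(config.N / Q))),
        mu=config.mu * Q,
        r=config.r * Q,
        burn_in_generations=max(1, int(round(config.burn_in_generations / Q))),
        extra_generations=max(1, int(round(config.extra_generations / Q))),
        rescale_Q=1,
        s_scale=config.s_scale * Q,
        demography=_rescale_demography(config.demography, Q),
    )


def _rescale_demography(dem: DemographyModel | None, Q: int) -> DemographyModel | None:
    if dem is None:
        return None
    founded = {child: t for t, _, child in dem.splits}
    demes = []
    for name, epochs in dem.demes:
        # round absolute boundary times, not durations, so that epoch ends
        # stay aligned with (identically rounded) split times
        t0 = founded.get(name, 0)
        bounds = t0 + np.cumsum([d for d, _ in epochs])
        t0_s = int(round(t0 / Q))
        bounds_s = [int(round(b / Q)) for b in bounds]
        new_epochs = []
        prev = t0_s
        for b, (_, size) in zip(bounds_s, epochs):
            if b > prev:
                new_epochs.append((b - prev, max(2, int(round(size / Q)))))
                prev = b
        if not new_epochs:
            new_epochs = [(1, max(2, int(round(epochs[-1][1] / Q))))]
        demes.append((name, tuple(new_epochs)))
    splits = tuple((int(round(t / Q)), p, c) for t, p, c in dem.splits)
    migration = tuple((int(round(t / Q)), tuple(tuple(Q * m for m in row) for row in mat))
                      for t, mat in dem.migration)
    return DemographyModel(demes=tuple(demes), splits=splits, migration=migration)
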