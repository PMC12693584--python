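"""Diploid Wright-Fisher forward simulator with recombination and linked
selection.

Discrete generations; parents are drawn with probability proportional to
multiplicative fitness prod (1 - h*s)^het * (1 - s)^hom; each transmitted
gamete receives Poisson(r * L_total) uniformly placed crossovers and
Poisson(mu * L_exonic) new mutations at uniformly drawn unoccupied exonic
base pairs (infinite sites within the bp grid).  Intronic sites carry no
tracked mutations -- neutral intronic variants would not alter dynamics and
no analysed statistic uses them -- so introns act purely as recombination
spacers.  Fixed mutations are purged periodically and logged as
substitutions.

The population is stored as a dense haplotype-by-site 0/1 matrix; the
generation loop is compiled with numba.  Optional multi-deme demographies
(piecewise-constant sizes, splits, per-generation migration) reuse the same
kernel with per-deme row offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .models import DemographyModel, GenomeLayout, SelectionModel, SimConfig, generate_layout, rescale
from .sfs import SFS, sum_sfs

__all__ = [
    "PopulationState",
    "draw_mutation_effect",
    "simulate_population",
    "sample_sfs",
    "simulate_replicate",
    "single_locus_counts",
]

_KIND_CODE = {"neutral": 0, "constant": 1, "partial": 2, "gamma": 3}


def _pack_model(model: SelectionModel, N: int, s_scale: float) -> tuple:
    """(code, effective constant s, selected fraction, gamma shape,
    gamma scale in homozygous-s units)."""
    code = _KIND_CODE[model.kind]
    s_eff = min(model.s * s_scale, 1.0) if code in (1, 2) else 0.0
    p = model.selected_fraction if code == 2 else 1.0
    gshape = model.gamma_shape or 0.0
    gscale_s = (model.gamma_scale_2Ns or 0.0) / N  # 2Ns-scale draw -> homozygous s
    return (code, s_eff, p, gshape, gscale_s)


@njit(cache=True)
def _draw_s(code, s_eff, p, gshape, gscale_s):
    if code == 0:
        return 0.0
    if code == 1:
        return s_eff
    if code == 2:
        return s_eff if np.random.random() < p else 0.0
    return min(np.random.gamma(gshape) * gscale_s, 1.0)


@njit(cache=True)
def _make_gamete(dst, row, src, r0, cur, k, xp, pos, S_sorted, S, L_total):
    """Copy one recombinant gamete.

    Columns [0, S_sorted) are sorted by genomic position, so each
    inter-crossover interval is a contiguous column range copied with a
    vectorisable loop; the unsorted tail [S_sorted, S) of recent mutations
    is handled with a per-column crossover-parity scan."""
    if k == 0:
        prow = r0 + cur
        for j in range(S):
            dst[row, j] = src[prow, j]
        return
    w = cur
    a = 0
    for c in range(k + 1):
        b = np.searchsorted(pos[:S_sorted], xp[c], side="left") if c < k else S_sorted
        prow = r0 + w
        for j in range(a, b):
            dst[row, j] = src[prow, j]
        a = b
        w ^= 1
    for j in range(S_sorted, S):
        pj = pos[j]
        w = cur
        for c in range(k):
            if xp[c] <= pj:
                w ^= 1
        dst[row, j] = src[r0 + w, j]


@njit(cache=True)
def _evolve_kernel(
    A, B, pos, exo, s_arr, a_log, b_log, is_ns, origin,
    sel_cols, n_sel, S, S_sorted,
    src_offs, dst_offs, mig_cum,
    gens, gen0, mu_per_gamete, rL, L_total,
    exon_starts, exon_cums, L_exonic, occupied,
    p_ns, ns_pack, syn_pack, seed,
):
    """Evolve up to ``gens`` generations; returns (S, gens_done, n_sel,
    status) with status 0=ok, 1=all fitnesses zero, 2=capacity reached."""
    np.random.seed(seed)
    cap = pos.shape[0]
    n_src = src_offs.shape[0] - 1
    n_dst = dst_offs.shape[0] - 1
    R_dst = dst_offs[n_dst]
    max_ind = max(src_offs[n_src], R_dst) // 2
    wcs = np.empty(max_ind, dtype=np.float64)
    margin = int(mu_per_gamete * R_dst * 2.0) + 32
    gens_done = 0
    status = 0
    xp = np.empty(64)
    for t in range(gens):
        if S + margin > cap:
            status = 2
            break
        offs = src_offs if t == 0 else dst_offs
        nsrc_t = offs.shape[0] - 1
        src = A if (t % 2 == 0) else B
        dst = B if (t % 2 == 0) else A
        # --- fitness: per-deme cumulative weights over individuals
        for d in range(nsrc_t):
            lo = offs[d] // 2
            hi = offs[d + 1] // 2
            acc = 0.0
            for i in range(lo, hi):
                lw = 0.0
                for c in range(n_sel):
                    j = sel_cols[c]
                    g = src[2 * i, j] + src[2 * i + 1, j]
                    if g == 1:
                        lw += a_log[j]
                    elif g == 2:
                        lw += b_log[j]
                acc += np.exp(lw)
                wcs[i] = acc
            if acc <= 0.0:
                return S, gens_done, n_sel, 1
        # --- offspring
        for d in range(n_dst):
            lo2 = dst_offs[d] // 2
            hi2 = dst_offs[d + 1] // 2
            for i in range(lo2, hi2):
                u = np.random.random()
                sd = d if d < nsrc_t else nsrc_t - 1
                csum = 0.0
                for cand in range(nsrc_t):
                    csum += mig_cum[d, cand]
                    if u < csum:
                        sd = cand
                        break
                plo = offs[sd] // 2
                phi = offs[sd + 1] // 2
                tot = wcs[phi - 1]
                base = 0.0 if plo == 0 else wcs[plo - 1]
                tot_d = tot - base
                for par in range(2):
                    uu = base + np.random.random() * tot_d
                    a_i = plo
                    b_i = phi - 1
                    while a_i < b_i:
                        m = (a_i + b_i) // 2
                        if wcs[m] < uu:
                            a_i = m + 1
                        else:
                            b_i = m
                    p_idx = a_i
                    row = 2 * i + par
                    cur = 0 if np.random.random() < 0.5 else 1
                    k = np.random.poisson(rL) if rL > 0 else 0
                    if k > 64:
                        k = 64
                    for c in range(k):
                        xp[c] = np.random.random() * L_total
                    xp[:k].sort()
                    _make_gamete(dst, row, src, 2 * p_idx, cur, k, xp, pos,
                                 S_sorted, S, L_total)
        # --- new mutations in offspring gametes
        for row in range(R_dst):
            m = np.random.poisson(mu_per_gamete)
            for _ in range(m):
                if S >= cap:
                    break
                e = np.random.randint(0, L_exonic)
                tries = 0
                while occupied[e] == 1 and tries < 1000:
                    e = np.random.randint(0, L_exonic)
                    tries += 1
                if occupied[e] == 1:
                    continue
                occupied[e] = 1
                idx = np.searchsorted(exon_cums, e, side="right") - 1
                gpos = exon_starts[idx] + (e - exon_cums[idx])
                nsyn = 1 if np.random.random() < p_ns else 0
                if nsyn == 1:
                    s = _draw_s(ns_pack[0], ns_pack[1], ns_pack[2], ns_pack[3], ns_pack[4])
                else:
                    s = _draw_s(syn_pack[0], syn_pack[1], syn_pack[2], syn_pack[3], syn_pack[4])
                j = S
                for rr in range(R_dst):
                    dst[rr, j] = 0
                dst[row, j] = 1
                pos[j] = gpos
                exo[j] = e
                s_arr[j] = s
                is_ns[j] = nsyn
                origin[j] = gen0 + t
                if s > 0.0:
                    a_log[j] = np.log1p(-0.5 * s)
                    b_log[j] = np.log1p(-s) if s < 1.0 else -745.0
                    sel_cols[n_sel] = j
                    n_sel += 1
                else:
                    a_log[j] = 0.0
                    b_log[j] = 0.0
                S += 1
        gens_done = t + 1
    return S, gens_done, n_sel, status


@dataclass
class PopulationState:
    """Final population: haplotype matrix plus per-mutation metadata."""

    H: np.ndarray            # uint8 (R, S)
    pos: np.ndarray          # genomic bp per column
    s: np.ndarray            # homozygous selection coefficient per column
    is_ns: np.ndarray        # bool per column
    origin: np.ndarray       # generation of origin per column
    deme_offsets: np.ndarray  # haplotype-row offsets per deme
    layout: GenomeLayout
    config: SimConfig
    substitutions: list      # (pos, is_ns, s, origin_gen, fixed_gen)
    generation: int


class _Sim:
    """Mutable simulation workspace around the numba kernel."""

    def __init__(self, config: SimConfig, layout: GenomeLayout, rng: np.random.Generator):
        self.cfg = config
        self.layout = layout
        self.rng = rng
        self.N = config.N
        self.R = 2 * config.N
        self.mu_per_gamete = config.mu * layout.exonic_length
        self.rL = config.r * layout.total_length
        self.L_total = float(layout.total_length)
        self.exon_starts, self.exon_cums = layout.exon_arrays()
        self.L_exonic = layout.exonic_length
        self.occupied = np.zeros(self.L_exonic, dtype=np.uint8)
        self.p_ns = config.ns_to_s_ratio / (1.0 + config.ns_to_s_ratio)
        self.ns_pack = _pack_model(config.ns_model, config.N, config.s_scale)
        self.syn_pack = _pack_model(config.syn_model, config.N, config.s_scale)
        self.generation = 0
        self.substitutions: list = []
        self.offs = np.array([0, self.R], dtype=np.int64)
        self.mig = np.eye(1)
        self._alloc(256)
        self.S = 0
        self.S_sorted = 0  # columns [0, S_sorted) are position-sorted
        self.n_sel = 0
        self.final = self.A  # buffer holding the current generation

    def _alloc(self, cap: int):
        R = self.offs[-1]
        self.A = np.zeros((R, cap), dtype=np.uint8)
        self.B = np.zeros((R, cap), dtype=np.uint8)
        self.pos = np.zeros(cap, dtype=np.int64)
        self.exo = np.zeros(cap, dtype=np.int64)
        self.s_arr = np.zeros(cap, dtype=np.float64)
        self.a_log = np.zeros(cap, dtype=np.float64)
        self.b_log = np.zeros(cap, dtype=np.float64)
        self.is_ns = np.zeros(cap, dtype=np.uint8)
        self.origin = np.zeros(cap, dtype=np.int64)
        self.sel_cols = np.zeros(cap, dtype=np.int64)
        self.cap = cap

    def _grow(self, need: int):
        newcap = max(need, int(self.cap * 1.6) + 64)
        fin = self.final
        old = (fin, self.pos, self.exo, self.s_arr, self.a_log, self.b_log,
               self.is_ns, self.origin)
        S = self.S
        self._alloc(newcap)
        self.A[:, :S] = old[0][:, :S]
        self.pos[:S], self.exo[:S] = old[1][:S], old[2][:S]
        self.s_arr[:S], self.a_log[:S], self.b_log[:S] = old[3][:S], old[4][:S], old[5][:S]
        self.is_ns[:S], self.origin[:S] = old[6][:S], old[7][:S]
        sel = np.nonzero(self.s_arr[:S] > 0)[0]
        self.sel_cols[: sel.size] = sel
        self.n_sel = sel.size
        self.final = self.A

    def _compact(self):
        """Drop lost columns, purge and log fixed ones, restore position order."""
        S = self.S
        if S == 0:
            return
        H = self.final[:, :S]
        counts = H.sum(axis=0, dtype=np.int64)
        R = self.offs[-1]
        fixed = counts == R
        keep = (counts > 0) & ~fixed
        for j in np.nonzero(fixed)[0]:
            self.substitutions.append(
                (int(self.pos[j]), int(self.is_ns[j]), float(self.s_arr[j]),
                 int(self.origin[j]), self.generation)
            )
        drop = np.nonzero(~keep)[0]
        self.occupied[self.exo[drop]] = 0
        idx = np.nonzero(keep)[0]
        idx = idx[np.argsort(self.pos[idx], kind="stable")]
        Snew = idx.size
        tgt = self.final
        tgt[:, :Snew] = H[:, idx]
        for arr in (self.pos, self.exo, self.s_arr, self.a_log, self.b_log,
                    self.is_ns, self.origin):
            arr[:Snew] = arr[idx]
        self.S = Snew
        self.S_sorted = Snew
        sel = np.nonzero(self.s_arr[:Snew] > 0)[0]
        self.sel_cols[: sel.size] = sel
        self.n_sel = sel.size

    def run(self, gens: int, dst_offs: np.ndarray | None = None, mig: np.ndarray | None = None):
        """Advance ``gens`` generations (sizes constant after the first)."""
        dst_offs = self.offs if dst_offs is None else dst_offs
        mig = mig if mig is not None else np.eye(dst_offs.size - 1)
        if dst_offs.size != self.offs.size or np.any(dst_offs != self.offs):
            self._transition(dst_offs, mig)
            gens -= 1
            if gens <= 0:
                return
            mig = np.eye(dst_offs.size - 1) if mig.shape[0] != mig.shape[1] else mig
        done = 0
        muts_per_gen = self.mu_per_gamete * self.offs[-1]
        while done < gens:
            # keep the unsorted/dead column tail small: compaction is cheap,
            # dragging dead columns through the copy loops is not
            tail_cap = max(2, int(max(self.S, 512) * 0.25 / max(muts_per_gen, 1e-9)))
            block = min(self.cfg.purge_interval, gens - done, tail_cap)
            need = self.S + int(muts_per_gen * block * 2.0) + 256
            if need > self.cap:
                self._grow(need)
            src_is_A = self.final is self.A
            A, B = (self.A, self.B) if src_is_A else (self.B, self.A)
            seed = int(self.rng.integers(0, 2**31 - 1))
            S, gdone, n_sel, status = _evolve_kernel(
                A, B, self.pos, self.exo, self.s_arr, self.a_log, self.b_log,
                self.is_ns, self.origin, self.sel_cols, self.n_sel, self.S,
                self.S_sorted,
                self.offs, self.offs, mig,
                block, self.generation, self.mu_per_gamete, self.rL, self.L_total,
                self.exon_starts, self.exon_cums, self.L_exonic, self.occupied,
                self.p_ns, self.ns_pack, self.syn_pack, seed,
            )
            if status == 1:
                raise RuntimeError(
                    "simulation error: total population fitness reached zero"
                )
            self.S, self.n_sel = S, n_sel
            self.generation += gdone
            done += gdone
            if gdone > 0:
                self.final = B if gdone % 2 == 1 else A
            if status == 2 and gdone == 0:
                self._grow(int(self.cap * 2))
                continue
            self._compact()

    def _transition(self, dst_offs: np.ndarray, mig: np.ndarray):
        """One generation with a different destination population shape."""
        R_new = int(dst_offs[-1])
        src_is_A = self.final is self.A
        src = self.A if src_is_A else self.B
        dstbuf = np.zeros((R_new, self.cap), dtype=np.uint8)
        seed = int(self.rng.integers(0, 2**31 - 1))
        S, gdone, n_sel, status = _evolve_kernel(
            src, dstbuf, self.pos, self.exo, self.s_arr, self.a_log, self.b_log,
            self.is_ns, self.origin, self.sel_cols, self.n_sel, self.S,
            self.S_sorted,
            self.offs, dst_offs, mig,
            1, self.generation, self.mu_per_gamete, self.rL, self.L_total,
            self.exon_starts, self.exon_cums, self.L_exonic, self.occupied,
            self.p_ns, self.ns_pack, self.syn_pack, seed,
        )
        if status == 1:
            raise RuntimeError("simulation error: total population fitness reached zero")
        self.S, self.n_sel = S, n_sel
        self.generation += 1
        self.offs = dst_offs.copy()
        self.A = dstbuf
        self.B = np.zeros_like(dstbuf)
        self.final = self.A
        self._compact()

    def seed_equilibrium(self):
        """Seed standing variation from the stationary sojourn density.

        Sites are drawn per selection class with Poisson counts around the
        diffusion-equilibrium expectation at population size N, carriers
        assigned at linkage equilibrium; a short burn-in then establishes
        linkage and interference correlations."""
        R = self.offs[-1]
        theta_exonic = 4.0 * self.N * self.cfg.mu * self.L_exonic
        classes: list[tuple[float, float, int]] = []  # (theta, gamma_prf, is_ns)
        p_ns = self.p_ns
        for is_ns, pack, frac in ((1, self.ns_pack, p_ns), (0, self.syn_pack, 1 - p_ns)):
            code, s_eff, p, gshape, gscale_s = pack
            theta_c = theta_exonic * frac
            if code == 0:
                classes.append((theta_c, 0.0, is_ns))
            elif code == 1:
                classes.append((theta_c, self.N * s_eff, is_ns))
            elif code == 2:
                classes.append((theta_c * p, self.N * s_eff, is_ns))
                classes.append((theta_c * (1 - p), 0.0, is_ns))
            else:
                # discretize the gamma DFE over 2Ns cells
                from scipy import stats
                edges = np.geomspace(1e-2, max(10.0, self.N), 40)
                cdf = stats.gamma.cdf(edges / (gscale_s * self.N), a=gshape)
                classes.append((theta_c * cdf[0], 0.0, is_ns))
                for kcell in range(len(edges) - 1):
                    mass = cdf[kcell + 1] - cdf[kcell]
                    if mass <= 0:
                        continue
                    gmid = np.sqrt(edges[kcell] * edges[kcell + 1])
                    classes.append((theta_c * mass, gmid, is_ns))
        # expected sites with population count k: tau(k/R)/R (midpoint
        # approximation of the beta-kernel projection; exact for gamma=0)
        from .expected_sfs import sojourn_ratio

        kk = np.arange(1, R)
        x = kk / R
        cols = []
        for theta_c, gam, is_ns in classes:
            if theta_c <= 0:
                continue
            lam = theta_c * sojourn_ratio(x, -float(gam)) / (x * (1.0 - x)) / R
            counts = self.rng.poisson(lam)
            for k in np.nonzero(counts)[0]:
                for _ in range(int(counts[k])):
                    cols.append((k + 1, gam, is_ns))
        need = len(cols) + 512
        if need > self.cap:
            self._grow(need)
        H = self.final
        free = np.nonzero(self.occupied == 0)[0]
        epos = self.rng.choice(free, size=len(cols), replace=False)
        for j, ((k, gam, is_ns), e) in enumerate(zip(cols, epos)):
            rows = self.rng.choice(R, size=k, replace=False)
            H[rows, j] = 1
            self.occupied[e] = 1
            idx = np.searchsorted(self.exon_cums, e, side="right") - 1
            self.pos[j] = self.exon_starts[idx] + (e - self.exon_cums[idx])
            self.exo[j] = e
            s = gam / self.N
            self.s_arr[j] = s
            self.a_log[j] = np.log1p(-0.5 * s) if s > 0 else 0.0
            self.b_log[j] = (np.log1p(-s) if s < 1 else -745.0) if s > 0 else 0.0
            self.is_ns[j] = is_ns
            self.origin[j] = 0
        self.S = len(cols)
        sel = np.nonzero(self.s_arr[: self.S] > 0)[0]
        self.sel_cols[: sel.size] = sel
        self.n_sel = sel.size
        self._compact()  # also restores position order

    def state(self) -> PopulationState:
        S = self.S
        return PopulationState(
            H=self.final[:, :S].copy(),
            pos=self.pos[:S].copy(),
            s=self.s_arr[:S].copy(),
            is_ns=self.is_ns[:S].astype(bool),
            origin=self.origin[:S].copy(),
            deme_offsets=self.offs.copy(),
            layout=self.layout,
            config=self.cfg,
            substitutions=list(self.substitutions),
            generation=self.generation,
        )


def draw_mutation_effect(
    site_kind: str,
    ns_model: SelectionModel,
    syn_model: SelectionModel,
    N: int,
    rng: np.random.Generator,
    *,
    ns_to_s_ratio: float = 2.31,
    s_scale: float = 1.0,
) -> tuple[str, float, float]:
    """Draw (class_label, homozygous s, h) for a new exonic mutation.

    The mutation is nonsynonymous with probability ratio/(1+ratio); gamma
    model draws are on the 2*N*s scale and converted with the supplied N.
    """
    if site_kind != "exon":
        raise ValueError("only exonic sites produce tracked mutations")
    p_ns = ns_to_s_ratio / (1.0 + ns_to_s_ratio)
    if rng.random() < p_ns:
        label, model = "nonsynonymous", ns_model
    else:
        label, model = "synonymous", syn_model
    if model.kind == "neutral":
        s = 0.0
    elif model.kind == "constant":
        s = min(model.s * s_scale, 1.0)
    elif model.kind == "partial":
        s = min(model.s * s_scale, 1.0) if rng.random() < model.selected_fraction else 0.0
    else:
        s = min(rng.gamma(model.gamma_shape) * model.gamma_scale_2Ns / N, 1.0)
    return label, s, model.h


def _demography_schedule(dem: DemographyModel):
    """Flatten a DemographyModel into stages of constant sizes/migration.

    Returns (stages, founding) where each stage is (gens, active_names,
    sizes, migration_matrix) and founding maps child -> parent deme name.
    """
    times = {0}
    founding = {}
    founded_at = {}
    for t, parent, child in dem.splits:
        times.add(t)
        founding[child] = parent
        founded_at[child] = t
    names = [name for name, _ in dem.demes]
    for name, epochs in dem.demes:
        acc = founded_at.get(name, 0)
        for dur, _ in epochs:
            acc += dur
            times.add(acc)
    for t, _ in dem.migration:
        times.add(t)
    end = max(
        founded_at.get(name, 0) + sum(d for d, _ in epochs)
        for name, epochs in dem.demes
    )
    times = sorted(t for t in times if t <= end)

    def size_at(name, epochs, t):
        acc = founded_at.get(name, 0)
        if t < acc:
            return None
        for dur, size in epochs:
            if t < acc + dur:
                return size
            acc += dur
        return None

    def mig_at(t):
        cur = None
        for mt, mat in sorted(dem.migration):
            if mt <= t:
                cur = mat
        return cur

    stages = []
    for t_start, t_stop in zip(times[:-1], times[1:]):
        sizes, active = [], []
        for name, epochs in dem.demes:
            s = size_at(name, epochs, t_start)
            if s is not None:
                sizes.append(s)
                active.append(name)
        mat = mig_at(t_start)
        nd = len(active)
        mig = np.zeros((nd, nd))
        if mat is not None:
            for i2, ni in enumerate(active):
                for j2, nj in enumerate(active):
                    if ni != nj:
                        mig[i2, j2] = mat[names.index(ni)][names.index(nj)]
        for i2 in range(nd):
            mig[i2, i2] = 1.0 - mig[i2].sum() + mig[i2, i2]
        stages.append((t_stop - t_start, active, sizes, mig))
    return stages, founding


def simulate_population(
    config: SimConfig,
    layout: GenomeLayout | None = None,
    rng: np.random.Generator | int | None = None,
) -> PopulationState:
    """Run one forward simulation and return the final population state.

    ``config.rescale_Q`` is applied first; the burn-in then runs at the
    rescaled scale.  With ``init='equilibrium'`` the population is seeded
    from the analytic stationary spectrum before the burn-in, which lets a
    much shorter burn-in (a few N generations) reach stationarity.
    """
    rng = np.random.default_rng(rng)
    cfg = rescale(config, config.rescale_Q) if config.rescale_Q > 1 else config
    if layout is None:
        layout = generate_layout(
            cfg.mean_exon_len, cfg.mean_intron_len, cfg.target_exonic_bp, rng
        )
    sim = _Sim(cfg, layout, rng)
    if cfg.init == "equilibrium":
        sim.seed_equilibrium()
    if cfg.demography is None:
        sim.run(cfg.burn_in_generations)
        sim.run(cfg.extra_generations)
    else:
        sim.run(cfg.burn_in_generations)
        stages, founding = _demography_schedule(cfg.demography)
        prev_active = [stages[0][1][0]] if stages else []
        for gens, active, sizes, mig in stages:
            offs = np.concatenate([[0], np.cumsum([2 * s for s in sizes])]).astype(np.int64)
            if active != prev_active or offs.size != sim.offs.size or np.any(offs != sim.offs):
                tmig = np.zeros((len(active), len(prev_active)))
                for d, name in enumerate(active):
                    src = name if name in prev_active else founding.get(name, prev_active[0])
                    tmig[d, prev_active.index(src)] = 1.0
                sim.run(1, dst_offs=offs, mig=tmig)
                gens -= 1
            if gens > 0:
                sim.run(gens, mig=mig)
            prev_active = active
        sim.run(cfg.extra_generations)
    return sim.state()


def sample_sfs(
    state: PopulationState,
    sample_n: int = 100,
    rng: np.random.Generator | int | None = None,
    deme: int = 0,
) -> tuple[SFS, SFS]:
    """Sample haplotypes without replacement and tally per-class spectra.

    Returns (synonymous SFS, nonsynonymous SFS); the L fields carry the
    class mutational opportunity L_s = exonic/(1+ratio) and
    L_ns = exonic*ratio/(1+ratio).
    """
    rng = np.random.default_rng(rng)
    lo, hi = state.deme_offsets[deme], state.deme_offsets[deme + 1]
    R = hi - lo
    if sample_n > R:
        raise ValueError(f"sample_n={sample_n} exceeds {R} haplotypes in deme {deme}")
    rows = lo + rng.choice(R, size=sample_n, replace=False)
    counts = state.H[rows].sum(axis=0, dtype=np.int64)
    ratio = state.config.ns_to_s_ratio
    L_ex = state.layout.exonic_length
    out = []
    for is_ns, label, L in (
        (False, "synonymous", L_ex / (1.0 + ratio)),
        (True, "nonsynonymous", L_ex * ratio / (1.0 + ratio)),
    ):
        mask = state.is_ns == is_ns
        sfs = np.zeros(sample_n + 1)
        np.add.at(sfs, counts[mask], 1.0)
        sfs[0] = 0.0  # sites lost from the sample are not informative
        out.append(SFS(sfs, sample_n, L=L, class_label=label))
    return out[0], out[1]


def simulate_replicate(
    config: SimConfig,
    n_chunks: int = 22,
    rng: np.random.Generator | int | None = None,
) -> tuple[SFS, SFS]:
    """One replicate: sum the spectra of ``n_chunks`` independent runs,
    each with a fresh random exon/intron layout and a child seed."""
    ss = np.random.SeedSequence(
        rng if isinstance(rng, (int, np.integer)) else np.random.default_rng(rng).integers(2**31)
    )
    syn_list, ns_list = [], []
    for child in ss.spawn(n_chunks):
        crng = np.random.default_rng(child)
        state = simulate_population(config, rng=crng)
        syn, ns = sample_sfs(state, config.sample_n, rng=crng)
        syn_list.append(syn)
        ns_list.append(ns)
    return sum_sfs(syn_list), sum_sfs(ns_list)


def single_locus_counts(
    N: int,
    s: float,
    h: float,
    k0: int,
    gens: int,
    n_reps: int,
    seed: int = 0,
) -> np.ndarray:
    """Derived-allele counts after ``gens`` generations of the engine's
    selection + drift update at a single locus, across replicates.

    Starts each replicate from ``k0`` copies placed on distinct haplotypes;
    no new mutation, no recombination.  Used to cross-check the engine
    against the exact single-locus Wright-Fisher transition matrix.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps, dtype=np.int64)
    layout = GenomeLayout(((0, 1, "exon"),), 1, 1)
    cfg = SimConfig(
        N=N, mu=0.0, r=0.0, burn_in_generations=1, extra_generations=0,
        sample_n=2, target_exonic_bp=1,
        ns_model=SelectionModel("constant", s=s, h=h),
        syn_model=SelectionModel("neutral"),
    )
    for rep in range(n_reps):
        sim = _Sim(cfg, layout, rng)
        R = 2 * N
        sim._grow(64)
        rows = rng.choice(R, size=k0, replace=False)
        sim.final[rows, 0] = 1
        sim.pos[0] = 0
        sim.exo[0] = 0
        sim.s_arr[0] = s
        sim.a_log[0] = np.log1p(-h * s) if s > 0 else 0.0
        sim.b_log[0] = np.log1p(-s) if s > 0 else 0.0
        sim.is_ns[0] = 1
        sim.S = 1
        if s > 0:
            sim.sel_cols[0] = 0
            sim.n_sel = 1
        sim.cfg = cfg
        # evolve without compaction so absorbed states are observable
        src_is_A = sim.final is sim.A
        A, B = (sim.A, sim.B) if src_is_A else (sim.B, sim.A)
        kseed = int(rng.integers(0, 2**31 - 1))
        S, gdone, n_sel, status = _evolve_kernel(
            A, B, sim.pos, sim.exo, sim.s_arr, sim.a_log, sim.b_log,
            sim.is_ns, sim.origin, sim.sel_cols, sim.n_sel, sim.S, sim.S,
            sim.offs, sim.offs, np.eye(1),
            gens, 0, 0.0, 0.0, 1.0,
            sim.exon_starts, sim.exon_cums, 1, sim.occupied,
            sim.p_ns, sim.ns_pack, sim.syn_pack, kseed,
        )
        final = B if gdone % 2 == 1 else A
        out[rep] = int(final[:, 0].sum())
    return out
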