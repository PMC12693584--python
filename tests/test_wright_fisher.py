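import numpy as np
import pytest
from scipy import stats

from dfesim.models import (
    DemographyModel,
    GenomeLayout,
    SelectionModel,
    SimConfig,
)
from dfesim.sfs import pi_from_sfs, sum_sfs
from dfesim.wright_fisher import (
    PopulationState,
    sample_sfs,
    simulate_population,
    simulate_replicate,
    single_locus_counts,
)

TINY_NEUTRAL = dict(
    N=100,
    mu=1e-6,
    r=1e-6,
    burn_in_generations=2000,
    extra_generations=100,
    sample_n=20,
    target_exonic_bp=20_000,
    mean_exon_len=200,
    mean_intron_len=800,
    ns_model=SelectionModel("neutral"),
    syn_model=SelectionModel("neutral"),
)


class TestNeutralEquilibrium:
    def test_pi_within_three_se_of_4Nmu(self):
        cfg = SimConfig(**TINY_NEUTRAL)
        pis = []
        for seed in range(20):
            st = simulate_population(cfg, rng=300 + seed)
            syn, ns = sample_sfs(st, 20, rng=seed)
            pis.append(pi_from_sfs(syn) + pi_from_sfs(ns))
        pis = np.array(pis)
        expected = 4 * cfg.N * cfg.mu * cfg.target_exonic_bp
        sem = pis.std(ddof=1) / np.sqrt(len(pis))
        assert abs(pis.mean() - expected) < 3 * sem

    def test_pooled_sfs_shape_not_rejected_against_theta_over_i(self):
        cfg = SimConfig(**TINY_NEUTRAL)
        pooled = None
        for seed in range(20):
            st = simulate_population(cfg, rng=1300 + seed)
            syn, ns = sample_sfs(st, 20, rng=seed)
            tot = syn.counts + ns.counts
            pooled = tot if pooled is None else pooled + tot
        obs = pooled[1:-1]
        probs = (1 / np.arange(1, 20)) / (1 / np.arange(1, 20)).sum()
        chi2, p = stats.chisquare(obs, f_exp=obs.sum() * probs)
        assert p > 0.01


def test_selection_on_synonymous_skews_sfs_toward_rare_variants():
    base = dict(TINY_NEUTRAL)
    singleton_share = {}
    for name, syn in [
        ("neutral", SelectionModel("neutral")),
        ("selected", SelectionModel("constant", s=0.05)),  # Ns = 5
    ]:
        cfg = SimConfig(**{**base, "syn_model": syn})
        pooled = np.zeros(21)
        for seed in range(8):
            st = simulate_population(cfg, rng=700 + seed)
            syn_sfs, _ = sample_sfs(st, 20, rng=seed)
            pooled += syn_sfs.counts
        singleton_share[name] = pooled[1] / pooled[1:-1].sum()
    assert singleton_share["selected"] > singleton_share["neutral"]


class TestSampling:
    def _toy_state(self, R=40, k=12):
        H = np.zeros((R, 1), dtype=np.uint8)
        H[:k, 0] = 1
        cfg = SimConfig(**TINY_NEUTRAL)
        return PopulationState(
            H=H,
            pos=np.array([0]),
            s=np.array([0.0]),
            is_ns=np.array([False]),
            origin=np.array([0]),
            deme_offsets=np.array([0, R]),
            layout=GenomeLayout(((0, 100, "exon"),), 100, 100),
            config=cfg,
            substitutions=[],
            generation=0,
        )

    def test_full_sample_equals_population_counts(self):
        state = self._toy_state(R=40, k=12)
        syn, ns = sample_sfs(state, 40, rng=0)
        assert syn.counts[12] == 1 and syn.num_segregating == 1
        assert ns.num_segregating == 0

    def test_subsampling_is_hypergeometric(self):
        R, k, n = 40, 12, 10
        state = self._toy_state(R=R, k=k)
        rng = np.random.default_rng(9)
        draws = []
        for _ in range(2000):
            syn, _ = sample_sfs(state, n, rng=rng)
            draws.append(int(np.argmax(syn.counts)) if syn.counts.sum() else 0)
        draws = np.array(draws)
        hyp = stats.hypergeom(R, k, n)
        assert draws.mean() == pytest.approx(hyp.mean(), abs=4 * hyp.std() / np.sqrt(2000))
        assert draws.var() == pytest.approx(hyp.var(), rel=0.2)

    def test_sample_larger_than_population_raises(self):
        state = self._toy_state()
        with pytest.raises(ValueError):
            sample_sfs(state, 41, rng=0)

    def test_spectra_have_length_sample_n_plus_one_and_class_L(self):
        cfg = SimConfig(**{**TINY_NEUTRAL, "sample_n": 20})
        st = simulate_population(cfg, rng=5)
        syn, ns = sample_sfs(st, 20, rng=5)
        assert syn.counts.shape == (21,) and ns.counts.shape == (21,)
        # realized exonic length may exceed the target by part of one exon
        assert syn.L == pytest.approx(st.layout.exonic_length / 3.31)
        assert ns.L == pytest.approx(st.layout.exonic_length * 2.31 / 3.31)
        assert syn.L == pytest.approx(20_000 / 3.31, rel=0.02)


class TestReplicates:
    def test_same_master_seed_gives_identical_spectra(self):
        cfg = SimConfig(**{**TINY_NEUTRAL, "burn_in_generations": 500})
        a_syn, a_ns = simulate_replicate(cfg, n_chunks=2, rng=99)
        b_syn, b_ns = simulate_replicate(cfg, n_chunks=2, rng=99)
        assert np.array_equal(a_syn.counts, b_syn.counts)
        assert np.array_equal(a_ns.counts, b_ns.counts)

    def test_chunk_L_fields_add(self):
        cfg = SimConfig(**{**TINY_NEUTRAL, "burn_in_generations": 200})
        syn, ns = simulate_replicate(cfg, n_chunks=3, rng=4)
        assert syn.L == pytest.approx(3 * 20_000 / 3.31, rel=0.02)


def test_rescaling_preserves_diversity_per_site():
    """pi/L is invariant under Q-rescaling within sampling error."""
    base = dict(
        N=400, mu=2.5e-7, r=2.5e-7, burn_in_generations=8000, extra_generations=200,
        sample_n=20, target_exonic_bp=30_000, mean_exon_len=200, mean_intron_len=800,
        ns_model=SelectionModel("neutral"), syn_model=SelectionModel("neutral"),
    )
    means = {}
    for Q in (1, 5, 10):
        pis = []
        for seed in range(6):
            cfg = SimConfig(**base, rescale_Q=Q)
            st = simulate_population(cfg, rng=40 + seed)
            syn, ns = sample_sfs(st, 20, rng=seed)
            pis.append((pi_from_sfs(syn) + pi_from_sfs(ns)) / 30_000)
        means[Q] = (np.mean(pis), np.std(pis, ddof=1) / np.sqrt(6))
    theta = 4 * 400 * 2.5e-7
    for Q, (m, sem) in means.items():
        assert abs(m - theta) < 4 * sem + 0.1 * theta, (Q, m, theta)


def test_single_locus_dynamics_match_wf_transition_matrix_quick():
    """Mean frequency and loss probability vs the exact Markov chain."""
    N, s, h, k0, gens, reps = 30, 0.08, 0.5, 6, 10, 2500
    counts = single_locus_counts(N, s, h, k0, gens, reps, seed=12)
    R = 2 * N
    P = np.zeros((R + 1, R + 1))
    for k in range(R + 1):
        p = k / R
        waa, wab, wbb = 1 - s, 1 - h * s, 1.0
        denom = p * p * waa + 2 * p * (1 - p) * wab + (1 - p) ** 2 * wbb
        psi = (p * p * waa + p * (1 - p) * wab) / denom
        P[k] = stats.binom.pmf(np.arange(R + 1), R, psi)
    v = np.zeros(R + 1)
    v[k0] = 1.0
    for _ in range(gens):
        v = v @ P
    mean_exact = v @ np.arange(R + 1)
    var_exact = v @ np.arange(R + 1) ** 2 - mean_exact**2
    z = (counts.mean() - mean_exact) / np.sqrt(var_exact / reps)
    assert abs(z) < 4
    p_loss = v[0]
    z_loss = (np.mean(counts == 0) - p_loss) / np.sqrt(p_loss * (1 - p_loss) / reps)
    assert abs(z_loss) < 4
    # deleterious: mean frequency must sit below the neutral (martingale) value
    assert counts.mean() < k0


class TestMultiDeme:
    def _demography(self):
        return DemographyModel(
            demes=(
                ("ANC", ((60, 60),)),
                ("A", ((80, 50),)),
                ("B", ((80, 30),)),
            ),
            splits=((60, "ANC", "A"), (60, "ANC", "B")),
            migration=((60, ((0.0, 0.0, 0.0), (0.0, 0.0, 0.01), (0.0, 0.01, 0.0))),),
        )

    def _config(self):
        return SimConfig(
            N=60, mu=2e-6, r=1e-6, burn_in_generations=300, extra_generations=5,
            sample_n=10, target_exonic_bp=8_000, mean_exon_len=200, mean_intron_len=400,
            ns_model=SelectionModel("neutral"), syn_model=SelectionModel("neutral"),
            demography=self._demography(),
        )

    def test_split_produces_two_demes_with_requested_sizes(self):
        st = simulate_population(self._config(), rng=8)
        assert list(st.deme_offsets) == [0, 100, 160]

    def test_per_deme_sampling_and_determinism(self):
        st1 = simulate_population(self._config(), rng=8)
        st2 = simulate_population(self._config(), rng=8)
        assert np.array_equal(st1.H, st2.H)
        syn_a, _ = sample_sfs(st1, 10, rng=1, deme=0)
        syn_b, _ = sample_sfs(st1, 10, rng=1, deme=1)
        assert syn_a.counts.shape == (11,)
        assert syn_b.counts.shape == (11,)


def test_substitution_log_records_fixations():
    cfg = SimConfig(
        N=20, mu=5e-5, r=0.0, burn_in_generations=2000, extra_generations=10,
        sample_n=10, target_exonic_bp=500, mean_exon_len=100, mean_intron_len=100,
        ns_model=SelectionModel("neutral"), syn_model=SelectionModel("neutral"),
    )
    st = simulate_population(cfg, rng=2)
    assert len(st.substitutions) > 0
    pos, is_ns, s, origin, fixed = st.substitutions[0]
    assert 0 <= pos < st.layout.total_length and fixed >= origin
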