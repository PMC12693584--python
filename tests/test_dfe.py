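import numpy as np
import pytest

from dfesim.demography import EpochModel
from dfesim.dfe import (
    DEFAULT_BIN_EDGES,
    _mixture_weights,
    build_gamma_cache,
    discretize,
    expected_sfs_under_dfe,
    fit_dfe,
    scale_to_s,
    standardized_residuals,
)
from dfesim.expected_sfs import _unit_equilibrium
from dfesim.sfs import SFS


@pytest.fixture(scope="module")
def eq_cache():
    return build_gamma_cache(EpochModel("one_epoch"), 60)


class TestCache:
    def test_neutral_endpoint_matches_demography_only_spectrum(self, eq_cache):
        assert eq_cache.neutral == pytest.approx(_unit_equilibrium(60, 0.0), rel=1e-12)

    def test_polymorphic_mass_strictly_decreasing_in_gamma(self, eq_cache):
        totals = eq_cache.spectra.sum(axis=1)
        assert np.all(np.diff(totals) < 0)

    def test_grid_covers_the_study_dfe_mean(self, eq_cache):
        mean_gamma = 0.186 * 706.899  # ~131
        assert eq_cache.gamma_grid[0] < mean_gamma < eq_cache.gamma_grid[-1]

    def test_two_epoch_cache_neutral_endpoint(self):
        cache = build_gamma_cache(EpochModel("two_epoch", nu=2.0, T=0.1), 40, n_grid=40)
        from dfesim.expected_sfs import get_engine

        assert cache.neutral == pytest.approx(
            get_engine(40).neutral_two_epoch(2.0, 0.1), rel=1e-12
        )


class TestMixture:
    def test_weights_sum_to_one_with_tails(self, eq_cache):
        w, lo, hi = _mixture_weights(eq_cache, 0.186, 706.899)
        assert w.sum() + lo + hi == pytest.approx(1.0, abs=1e-12)
        assert hi > 0  # the study DFE has mass beyond the grid

    def test_linearity_in_theta(self, eq_cache):
        a = expected_sfs_under_dfe(eq_cache, 0.186, 706.899, 100.0)
        b = expected_sfs_under_dfe(eq_cache, 0.186, 706.899, 200.0)
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_near_point_mass_gamma_approximates_cache_lookup(self, eq_cache):
        k = 30
        g0 = eq_cache.gamma_grid[k]
        shape = 4000.0  # CV = 1/sqrt(shape) -> essentially a point mass
        mix = expected_sfs_under_dfe(eq_cache, shape, g0 / shape, 1.0)
        assert mix == pytest.approx(eq_cache.spectra[k], rel=0.02)

    def test_grid_density_insensitivity(self):
        coarse = build_gamma_cache(EpochModel("one_epoch"), 40, n_grid=60)
        fine = build_gamma_cache(EpochModel("one_epoch"), 40, n_grid=120)
        a = expected_sfs_under_dfe(coarse, 0.186, 706.899, 1.0)
        b = expected_sfs_under_dfe(fine, 0.186, 706.899, 1.0)
        assert np.max(np.abs(a - b) / b) < 0.002

    def test_invalid_parameters_raise(self, eq_cache):
        with pytest.raises(ValueError):
            expected_sfs_under_dfe(eq_cache, -0.1, 700.0, 1.0)
        with pytest.raises(ValueError):
            expected_sfs_under_dfe(eq_cache, 0.2, np.nan, 1.0)


class TestFit:
    def test_noiseless_self_consistency_study_parameters(self, eq_cache):
        theta_ns = 2.31 * 560.0
        mu_vec = expected_sfs_under_dfe(eq_cache, 0.186, 706.899, theta_ns)
        counts = np.zeros(61)
        counts[1:-1] = mu_vec
        obs = SFS(counts, 60, class_label="nonsynonymous")
        fit = fit_dfe(obs, eq_cache, theta_ns, N_a=10_000.0, n_starts=10, rng=1)
        assert fit.shape == pytest.approx(0.186, rel=0.01)
        assert fit.scale_gamma == pytest.approx(706.899, rel=0.01)
        assert fit.scale_s_dhet == pytest.approx(706.899 / 2e4, rel=0.01)

    @pytest.mark.parametrize("shape,scale", [(0.12, 50.0), (0.5, 400.0), (1.0, 2000.0)])
    def test_noiseless_recovery_across_parameter_space(self, eq_cache, shape, scale):
        theta_ns = 2000.0
        mu_vec = expected_sfs_under_dfe(eq_cache, shape, scale, theta_ns)
        counts = np.zeros(61)
        counts[1:-1] = mu_vec
        fit = fit_dfe(SFS(counts, 60), eq_cache, theta_ns, N_a=1e4, n_starts=10, rng=2)
        assert fit.shape == pytest.approx(shape, rel=0.02)
        assert fit.scale_gamma == pytest.approx(scale, rel=0.05)


class TestConversions:
    def test_scale_to_s_study_values(self):
        # the source study's ancestral size: 706.899/(2*8079) ~ 0.04375
        assert scale_to_s(706.899, 8079) == pytest.approx(0.04375, abs=2e-5)
        # the simulated population size: ~0.03534
        assert scale_to_s(706.899, 10_000) == pytest.approx(0.035345, abs=1e-5)
        assert scale_to_s(0.0, 123.0) == 0.0

    def test_nonpositive_na_raises(self):
        with pytest.raises(ValueError):
            scale_to_s(100.0, 0.0)


class TestDiscretize:
    def test_masses_sum_to_one(self):
        d = discretize(0.186, 0.04375)
        assert d.masses.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(d.masses) == len(DEFAULT_BIN_EDGES) - 1

    def test_cdf_mode_matches_monte_carlo(self):
        d = discretize(0.186, 0.04375)
        mc = discretize(0.186, 0.04375, method="mc", n_draws=1_000_000, rng=0)
        se = np.sqrt(d.masses * (1 - d.masses) / 1_000_000)
        assert np.all(np.abs(d.masses - mc.masses) < 5 * se + 1e-6)

    def test_point_mass_limit_lands_in_one_bin(self):
        # shape -> inf with mean 3e-3 inside bin (1e-3, 1e-2)
        d = discretize(1e6, 3e-3 / 1e6)
        assert d.masses[3] == pytest.approx(1.0, abs=1e-9)

    def test_unsorted_edges_raise(self):
        with pytest.raises(ValueError):
            discretize(0.2, 0.01, edges=(0.0, 1e-4, 1e-5, np.inf))


class TestResiduals:
    def test_zero_when_equal(self):
        t = np.array([0.2, 0.3, 0.5])
        assert standardized_residuals(t, t) == pytest.approx(np.zeros(3))

    def test_formula(self):
        r = standardized_residuals(np.array([0.20]), np.array([0.16]))
        assert r[0] == pytest.approx(0.1)

    def test_sign_antisymmetry(self):
        t = np.array([0.25, 0.75])
        up = standardized_residuals(t + [0.05, -0.05], t)
        down = standardized_residuals(t - [0.05, -0.05], t)
        assert up == pytest.approx(-down)

    def test_zero_true_mass_rejected(self):
        with pytest.raises(ValueError):
            standardized_residuals(np.array([0.1]), np.array([0.0]))
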