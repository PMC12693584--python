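import numpy as np
import pandas as pd
import pytest

from dfesim import experiments as exp
from dfesim.experiments import (
    Scenario,
    constant_size_grid,
    neutral_swap,
    out_of_africa_demography,
    report,
    results_to_frame,
    run_scenario,
)
from dfesim.models import SelectionModel, SimConfig
from dfesim.wright_fisher import sample_sfs, simulate_population

MICRO = dict(
    n_replicates=2,
    n_chunks=1,
    rescale_Q=100,
    sim_overrides=dict(
        target_exonic_bp=40_000,
        burn_in_generations=20_000,
        extra_generations=1_000,
        sample_n=20,
        init="equilibrium",
    ),
)


@pytest.fixture(scope="module")
def micro_results():
    sc = Scenario(name="micro_control", syn_model=SelectionModel("neutral"),
                  seed=1, **MICRO)
    return run_scenario(sc, n_starts=6)


class TestRunScenario:
    def test_complete_rows_per_replicate(self, micro_results):
        assert len(micro_results) == 2
        for res in micro_results:
            assert res.error is None
            assert res.demographic_fit is not None
            assert res.dfe_fit is not None
            assert res.dfe_masses.sum() == pytest.approx(1.0, abs=1e-9)
            assert 0 < res.pi_ratio_syn < 2

    def test_determinism_under_fixed_seed(self, micro_results):
        sc = Scenario(name="micro_control", syn_model=SelectionModel("neutral"),
                      seed=1, **MICRO)
        again = run_scenario(sc, n_starts=6)
        a, b = micro_results[0], again[0]
        assert np.array_equal(a.syn_sfs.counts, b.syn_sfs.counts)
        assert a.demographic_fit.theta_s == b.demographic_fit.theta_s
        assert a.dfe_fit.shape == b.dfe_fit.shape

    def test_failure_isolation(self, monkeypatch):
        calls = {"n": 0}
        real = exp.simulate_replicate

        def flaky(cfg, n_chunks, rng):
            calls["n"] += 1
            if calls["n"] == 1:
                raise RuntimeError("synthetic stage failure")
            return real(cfg, n_chunks=n_chunks, rng=rng)

        monkeypatch.setattr(exp, "simulate_replicate", flaky)
        sc = Scenario(name="flaky", syn_model=SelectionModel("neutral"), seed=3, **MICRO)
        results = run_scenario(sc, n_starts=4)
        assert results[0].error is not None and "synthetic stage failure" in results[0].error
        assert results[1].error is None

    def test_output_files_written(self, tmp_path):
        sc = Scenario(name="filed", syn_model=SelectionModel("neutral"), seed=2,
                      **{**MICRO, "n_replicates": 1})
        run_scenario(sc, out_dir=tmp_path, n_starts=4)
        assert (tmp_path / "filed_rep0_syn.fs").exists()
        assert (tmp_path / "filed_rep0_ns.fs").exists()
        assert (tmp_path / "filed_results.csv").exists()


class TestNeutralSwap:
    def test_self_pairing_uses_own_demography(self, micro_results):
        swapped = neutral_swap(micro_results, micro_results, rng=0)
        for orig, sw in zip(micro_results, swapped):
            assert sw.error is None
            assert sw.demographic_fit is orig.demographic_fit
            assert sw.dfe_fit.N_a_used == orig.dfe_fit.N_a_used
            assert sw.dfe_fit.shape == pytest.approx(orig.dfe_fit.shape, rel=0.05)

    def test_sample_size_mismatch_recorded_as_error(self, micro_results):
        other = Scenario(
            name="n10", syn_model=SelectionModel("neutral"), seed=9,
            **{**MICRO, "n_replicates": 1,
               "sim_overrides": {**MICRO["sim_overrides"], "sample_n": 10}},
        )
        small = run_scenario(other, n_starts=4)
        swapped = neutral_swap(small, micro_results, rng=0)
        assert swapped[0].error is not None

    def test_bound_hitting_neutral_fit_falls_back_to_one_epoch(self, micro_results):
        import copy

        from dfesim.demography import DemographicFit, EpochModel

        neu = [copy.copy(r) for r in micro_results]
        degenerate = DemographicFit(
            model=EpochModel("two_epoch", nu=3000.0, T=0.003),
            theta_s=neu[0].demographic_fit.theta_s,
            loglik=0.0,
            N_a_hat=neu[0].demographic_fit.N_a_hat,
            at_bounds={"nu": True, "T": False},
        )
        neu[0].demographic_fit = degenerate
        swapped = neutral_swap(micro_results, neu, rng=0)
        assert swapped[0].error is None
        # the swap conditioned on the sane one-epoch fit, not the corner
        assert swapped[0].demographic_fit.model.kind == "one_epoch"

    def test_unknown_pairing_rule_rejected(self, micro_results):
        with pytest.raises(ValueError):
            neutral_swap(micro_results, micro_results, pairing_rule="random")


class TestReport:
    def test_writes_tables_and_plots(self, micro_results, tmp_path):
        files = report(micro_results, tmp_path)
        names = {f.name for f in files}
        assert "results.csv" in names
        assert any(n.endswith(".png") for n in names)
        df = pd.read_csv(tmp_path / "results.csv")
        assert len(df) == len(micro_results)

    def test_empty_results_warn_and_write_nothing(self, tmp_path):
        with pytest.warns(UserWarning):
            files = report([], tmp_path / "empty")
        assert files == []


class TestGrids:
    def test_constant_size_grid_has_control_plus_six_conditions(self):
        grid = constant_size_grid()
        assert len(grid) == 7
        names = [s.name for s in grid]
        assert names[0] == "control"
        kinds = [s.syn_model.kind for s in grid]
        assert kinds.count("constant") == 3 and kinds.count("partial") == 3

    def test_elevated_recombination_adds_14_combinations(self):
        # 7 conditions x 2 elevated rates on top of the baseline grid
        grid = constant_size_grid(recombination_rates=(1e-8, 1e-7, 1e-6))
        assert len(grid) == 21
        elevated = [s for s in grid if s.r > 1e-8]
        assert len(elevated) == 14
        assert len({s.name for s in grid}) == 21


def test_human_like_demography_smoke():
    """Rescaled out-of-Africa run: all five demes schedule correctly and
    per-deme spectra are produced."""
    dem = out_of_africa_demography()
    cfg = SimConfig(
        N=7300, mu=1.44e-8, r=1e-8, burn_in_generations=30_000,
        extra_generations=1, sample_n=10, target_exonic_bp=30_000,
        mean_exon_len=200, mean_intron_len=800,
        ns_model=SelectionModel("neutral"), syn_model=SelectionModel("neutral"),
        demography=dem, rescale_Q=200, init="equilibrium",
    )
    st = simulate_population(cfg, rng=6)
    # final stage holds AF, EU, AS demes
    assert len(st.deme_offsets) == 4
    syn_af, ns_af = sample_sfs(st, 10, rng=0, deme=0)
    syn_eu, _ = sample_sfs(st, 10, rng=0, deme=1)
    assert syn_af.counts.shape == (11,)
    assert syn_eu.counts.shape == (11,)
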