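"""Experiment orchestration: scenario grids, the neutral-swap analysis,
and report generation.

A ``Scenario`` bundles a synonymous-selection model with recombination
rate, demography, replicate count and scale knobs; ``run_scenario`` runs
the full per-replicate pipeline (simulate -> fit 1- and 2-epoch demography
-> LRT -> gamma-grid cache -> DFE fit -> discretised DFE -> diversity
summaries), isolating failures per replicate.  ``neutral_swap`` refits the
DFE of selected-scenario replicates conditional on demographies inferred
from known-neutral replicates — the rescue analysis for biased fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .demography import (
    DemographicFit,
    OneEpochDemography,
    TwoEpochDemography,
    select_model_lrt,
)
from .dfe import (
    DEFAULT_BIN_EDGES,
    DFEFit,
    build_gamma_cache,
    discretize,
    fit_dfe,
)
from .models import (
    NS_TO_S_RATIO,
    DemographyModel,
    SelectionModel,
    SimConfig,
)
from .sfs import SFS, pi_over_pi0, write_fs
from .wright_fisher import simulate_replicate

__all__ = [
    "Scenario",
    "ReplicateResult",
    "run_scenario",
    "neutral_swap",
    "report",
    "constant_size_grid",
    "out_of_africa_demography",
    "results_to_frame",
]


@dataclass(frozen=True)
class Scenario:
    """One cell of the experiment grid."""

    name: str
    syn_model: SelectionModel
    r: float = 1e-8
    demography: DemographyModel | None = None
    n_replicates: int = 20
    n_chunks: int = 22
    rescale_Q: int = 1
    seed: int = 0
    sim_overrides: dict = field(default_factory=dict)

    def sim_config(self) -> SimConfig:
        clash = {"syn_model", "r", "demography", "rescale_Q"} & set(self.sim_overrides)
        if clash:
            raise ValueError(
                f"set {sorted(clash)} via the Scenario fields, not sim_overrides"
            )
        return SimConfig(
            syn_model=self.syn_model,
            r=self.r,
            demography=self.demography,
            rescale_Q=self.rescale_Q,
            **self.sim_overrides,
        )


@dataclass
class ReplicateResult:
    """Complete per-replicate record (or an explicit failure)."""

    scenario: str
    replicate: int
    syn_sfs: SFS | None = None
    ns_sfs: SFS | None = None
    demographic_fit: DemographicFit | None = None
    one_epoch_fit: DemographicFit | None = None
    dfe_fit: DFEFit | None = None
    dfe_masses: np.ndarray | None = None
    pi_ratio_syn: float | None = None
    pi_ratio_ns: float | None = None
    error: str | None = None

    def to_row(self) -> dict:
        row = {
            "scenario": self.scenario,
            "replicate": self.replicate,
            "error": self.error,
            "pi_ratio_syn": self.pi_ratio_syn,
            "pi_ratio_ns": self.pi_ratio_ns,
        }
        if self.demographic_fit is not None:
            d = self.demographic_fit
            row.update(
                model=d.model.kind,
                nu=d.model.nu,
                T=d.model.T,
                theta_s=d.theta_s,
                N_a_hat=d.N_a_hat,
                loglik_demog=d.loglik,
                delta_ll=d.delta_ll,
                at_bounds=any(d.at_bounds.values()) if d.at_bounds else False,
            )
        if self.dfe_fit is not None:
            f = self.dfe_fit
            row.update(
                shape=f.shape,
                scale_gamma=f.scale_gamma,
                s_dhet=f.scale_s_dhet,
                loglik_dfe=f.loglik,
                dfe_converged=f.converged,
            )
        if self.dfe_masses is not None:
            for k, m in enumerate(self.dfe_masses):
                row[f"mass_bin{k}"] = m
        return row


def _fit_demography_stage(
    syn: SFS, cfg: SimConfig, rng: np.random.Generator, n_starts: int = 25
) -> tuple[DemographicFit, DemographicFit]:
    """Returns (LRT-chosen fit, one-epoch fit)."""
    mu, L_s = cfg.mu, syn.L
    one = OneEpochDemography(mu=mu, L_s=L_s).fit(syn)
    two = TwoEpochDemography(n_starts=n_starts, mu=mu, L_s=L_s).fit(syn, rng=rng)
    return select_model_lrt(one.result(), two.result()), one.result()


def _fit_dfe_stage(
    ns: SFS,
    chosen: DemographicFit,
    cfg: SimConfig,
    rng: np.random.Generator,
    n_starts: int = 25,
) -> tuple[DFEFit, np.ndarray]:
    cache = build_gamma_cache(chosen, ns.n)
    theta_ns = cfg.ns_to_s_ratio * chosen.theta_s
    dfe = fit_dfe(ns, cache, theta_ns, chosen.N_a_hat, n_starts=n_starts, rng=rng)
    masses = discretize(dfe.shape, dfe.scale_s_dhet).masses
    return dfe, masses


def run_scenario(
    scenario: Scenario,
    out_dir: str | Path | None = None,
    n_starts: int = 25,
) -> list[ReplicateResult]:
    """Run every replicate of a scenario through the full pipeline.

    Stage failures are recorded in the result row (non-convergent
    conditions are findings, not crashes); spectra and fit summaries are
    written to ``out_dir`` when given.
    """
    cfg = scenario.sim_config()
    ss = np.random.SeedSequence(scenario.seed)
    results: list[ReplicateResult] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for rep, child in enumerate(ss.spawn(scenario.n_replicates)):
        rng = np.random.default_rng(child)
        res = ReplicateResult(scenario=scenario.name, replicate=rep)
        try:
            syn, ns = simulate_replicate(cfg, n_chunks=scenario.n_chunks, rng=rng)
            res.syn_sfs, res.ns_sfs = syn, ns
            res.pi_ratio_syn = pi_over_pi0(syn, cfg.N, cfg.mu, syn.L).ratio
            res.pi_ratio_ns = pi_over_pi0(ns, cfg.N, cfg.mu, ns.L).ratio
            res.demographic_fit, res.one_epoch_fit = _fit_demography_stage(
                syn, cfg, rng, n_starts
            )
            res.dfe_fit, res.dfe_masses = _fit_dfe_stage(
                ns, res.demographic_fit, cfg, rng, n_starts
            )
        except Exception as exc:  # failures are data, not crashes
            res.error = f"{type(exc).__name__}: {exc}"
        results.append(res)
        if out is not None and res.syn_sfs is not None:
            write_fs(res.syn_sfs, out / f"{scenario.name}_rep{rep}_syn.fs")
            write_fs(res.ns_sfs, out / f"{scenario.name}_rep{rep}_ns.fs")
    if out is not None:
        results_to_frame(results).to_csv(out / f"{scenario.name}_results.csv", index=False)
    return results


def neutral_swap(
    selected_results: list[ReplicateResult],
    neutral_results: list[ReplicateResult],
    pairing_rule: str = "by_index",
    n_starts: int = 25,
    rng: np.random.Generator | int | None = None,
) -> list[ReplicateResult]:
    """Refit DFEs conditioning on known-neutral demographies.

    Each selected replicate's nonsynonymous SFS is paired with the
    demographic parameters inferred from a neutral-scenario replicate
    (``by_index``: same replicate number), emulating access to a set of
    truly neutral, unlinked variants."""
    if pairing_rule != "by_index":
        raise ValueError(f"unknown pairing rule {pairing_rule!r}")
    rng = np.random.default_rng(rng)
    out = []
    for sel, neu in zip(selected_results, neutral_results):
        res = ReplicateResult(
            scenario=f"{sel.scenario}+neutral_demog", replicate=sel.replicate
        )
        try:
            if sel.ns_sfs is None or neu.demographic_fit is None:
                raise RuntimeError("missing spectra or neutral demographic fit")
            if sel.ns_sfs.n != neu.syn_sfs.n:
                raise ValueError("sample-size mismatch between paired replicates")
            chosen = neu.demographic_fit
            # the premise of the swap is a *sane* neutral demography; a
            # bound-hitting neutral fit is a degenerate noise-chaser, so
            # fall back to that replicate's constant-size fit
            if any(chosen.at_bounds.values()) and neu.one_epoch_fit is not None:
                chosen = neu.one_epoch_fit
            cache = build_gamma_cache(chosen, sel.ns_sfs.n)
            theta_ns = NS_TO_S_RATIO * chosen.theta_s
            dfe = fit_dfe(sel.ns_sfs, cache, theta_ns, chosen.N_a_hat,
                          n_starts=n_starts, rng=rng)
            res.ns_sfs = sel.ns_sfs
            res.demographic_fit = chosen
            res.dfe_fit = dfe
            res.dfe_masses = discretize(dfe.shape, dfe.scale_s_dhet).masses
        except Exception as exc:
            res.error = f"{type(exc).__name__}: {exc}"
        out.append(res)
    return out


def results_to_frame(results: list[ReplicateResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def report(results: list[ReplicateResult], out_dir: str | Path) -> list[Path]:
    """Write the results table and the standard diagnostic plots.

    Produces results.csv, an inferred-size step plot, a shape/scale
    scatter, mean discretised-DFE bars with SD error bars, and pi/pi0
    boxplots.  Returns the list of files written; empty input is a no-op
    with a warning."""
    import warnings

    out = Path(out_dir)
    if not results:
        warnings.warn("report called with no results; nothing written")
        return []
    out.mkdir(parents=True, exist_ok=True)
    written = []
    df = results_to_frame(results)
    csv = out / "results.csv"
    df.to_csv(csv, index=False)
    written.append(csv)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = df[df["error"].isna()] if "error" in df else df
    scenarios = list(dict.fromkeys(ok["scenario"]))

    if "N_a_hat" in ok.columns:
        fig, ax = plt.subplots(figsize=(7, 4))
        for sc in scenarios:
            sub = ok[ok["scenario"] == sc]
            for _, row in sub.iterrows():
                Na = row.get("N_a_hat")
                if Na is None or not np.isfinite(Na):
                    continue
                if row.get("model") == "two_epoch" and np.isfinite(row.get("T", np.nan)):
                    t_change = 2 * Na * row["T"]
                    ax.plot([0, t_change, t_change, 2 * t_change],
                            [Na * row["nu"], Na * row["nu"], Na, Na],
                            alpha=0.4, lw=0.8)
                else:
                    ax.axhline(Na, alpha=0.4, lw=0.8)
        ax.set_xlabel("generations in the past")
        ax.set_ylabel("inferred N")
        ax.set_yscale("log")
        f = out / "inferred_size.png"
        fig.savefig(f, dpi=120)
        plt.close(fig)
        written.append(f)

    if "shape" in ok.columns:
        fig, ax = plt.subplots(figsize=(5, 4))
        for sc in scenarios:
            sub = ok[ok["scenario"] == sc]
            ax.scatter(sub["s_dhet"], sub["shape"], label=sc, s=14, alpha=0.7)
        ax.set_xlabel("scale ($s_{dhet}$)")
        ax.set_ylabel("shape")
        ax.legend(fontsize=6)
        f = out / "dfe_parameters.png"
        fig.savefig(f, dpi=120)
        plt.close(fig)
        written.append(f)

        mass_cols = [c for c in ok.columns if c.startswith("mass_bin")]
        if mass_cols:
            fig, ax = plt.subplots(figsize=(7, 4))
            width = 0.8 / max(len(scenarios), 1)
            xs = np.arange(len(mass_cols))
            for si, sc in enumerate(scenarios):
                sub = ok[ok["scenario"] == sc][mass_cols]
                ax.bar(xs + si * width, sub.mean(), width,
                       yerr=sub.std(), label=sc, capsize=2)
            edges = DEFAULT_BIN_EDGES
            ax.set_xticks(xs + 0.4)
            ax.set_xticklabels(
                [f"{edges[i]:g}-{edges[i+1]:g}" for i in range(len(mass_cols))],
                fontsize=7,
            )
            ax.set_ylabel("probability mass")
            ax.set_xlabel("|s| bin")
            ax.legend(fontsize=6)
            f = out / "dfe_discretized.png"
            fig.savefig(f, dpi=120)
            plt.close(fig)
            written.append(f)

    if "pi_ratio_syn" in ok.columns:
        fig, ax = plt.subplots(figsize=(6, 4))
        data = [ok[ok["scenario"] == sc]["pi_ratio_syn"].dropna() for sc in scenarios]
        ax.boxplot(data, tick_labels=scenarios)
        ax.set_ylabel(r"synonymous $\pi/\pi_0$")
        ax.tick_params(axis="x", labelsize=6, rotation=30)
        f = out / "pi_ratio.png"
        fig.savefig(f, dpi=120)
        plt.close(fig)
        written.append(f)
    return written


def constant_size_grid(
    recombination_rates: tuple = (1e-8,),
    n_replicates: int = 20,
    n_chunks: int = 22,
    rescale_Q: int = 1,
    seed: int = 0,
    sim_overrides: dict | None = None,
) -> list[Scenario]:
    """The constant-population experiment grid: a neutral control plus six
    synonymous-selection conditions (constant and 22%-partial models at
    s in {1e-5, 1e-4, 1e-3}) per recombination rate."""
    conditions = [("control", SelectionModel("neutral"))]
    for s in (1e-5, 1e-4, 1e-3):
        conditions.append((f"constant_s{s:g}", SelectionModel("constant", s=s)))
    for s in (1e-5, 1e-4, 1e-3):
        conditions.append(
            (f"partial_s{s:g}", SelectionModel("partial", s=s, selected_fraction=0.22))
        )
    scenarios = []
    for r in recombination_rates:
        for i, (name, model) in enumerate(conditions):
            full = name if len(recombination_rates) == 1 else f"{name}_r{r:g}"
            scenarios.append(
                Scenario(
                    name=full,
                    syn_model=model,
                    r=r,
                    n_replicates=n_replicates,
                    n_chunks=n_chunks,
                    rescale_Q=rescale_Q,
                    seed=seed + 1000 * i + int(round(np.log10(r / 1e-8))) * 97,
                    sim_overrides=dict(sim_overrides or {}),
                )
            )
    return scenarios


def out_of_africa_demography() -> DemographyModel:
    """Approximate four-deme out-of-Africa history (Gutenkunst-style).

    Ancestral expansion, African deme, out-of-Africa bottleneck deme that
    later splits into European and East-Asian demes, with symmetric
    migration; growth is approximated piecewise-constant.  The parameter
    values are approximate stand-ins for the published estimates; override
    via a config file for exact replication work.
    """
    total = 10_000          # scheduled generations after the burn-in
    t_exp = total - 8_800   # ancestral expansion ~220 kya
    t_ooa = total - 5_600   # out-of-Africa split ~140 kya
    t_split = total - 848   # European/East-Asian split ~21.2 kya
    third = (total - t_split) // 3
    last = total - t_split - 2 * third
    return DemographyModel(
        demes=(
            ("ANC", ((t_exp, 7_300), (t_ooa - t_exp, 12_300))),
            ("AF", ((total - t_ooa, 12_300),)),
            ("B", ((t_split - t_ooa, 2_100),)),
            # exponential growth approximated by three constant steps
            ("EU", ((third, 1_800), (third, 5_500), (last, 17_000))),
            ("AS", ((third, 1_100), (third, 5_000), (last, 23_000))),
        ),
        splits=(
            (t_ooa, "ANC", "AF"),
            (t_ooa, "ANC", "B"),
            (t_split, "B", "EU"),
            (t_split, "B", "AS"),
        ),
        migration=(
            (t_ooa, (
                (0.0, 0.0, 0.0, 0.0, 0.0),
                (0.0, 0.0, 25e-5, 0.0, 0.0),
                (0.0, 25e-5, 0.0, 0.0, 0.0),
                (0.0, 0.0, 0.0, 0.0, 0.0),
                (0.0, 0.0, 0.0, 0.0, 0.0),
            )),
            (t_split, (
                (0.0, 0.0, 0.0, 0.0, 0.0),
                (0.0, 0.0, 0.0, 3e-5, 1.9e-5),
                (0.0, 0.0, 0.0, 0.0, 0.0),
                (0.0, 3e-5, 0.0, 0.0, 9.6e-5),
                (0.0, 1.9e-5, 0.0, 9.6e-5, 0.0),
            )),
        ),
    )
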