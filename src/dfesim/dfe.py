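"""Gamma-DFE inference for nonsynonymous spectra.

Conditional on a fitted (or supplied) demography, the expected
nonsynonymous SFS is a mixture over the population-scaled selection
coefficient gamma = 2*N_a*s_dhet of single-gamma expected spectra:

    E[SFS] = theta_ns * Int SFS_unit(gamma) * gammaPDF(gamma; shape, scale) dgamma

The single-gamma spectra are precomputed once per demography on a
log-spaced grid (``GammaGridCache``); fitting then only re-weights the
cache, which makes the 25-start maximum-likelihood search cheap.  Only
deleterious gamma DFEs are modelled.  theta_ns is fixed from the
conditioning demographic fit via the nonsynonymous-to-synonymous
mutational opportunity ratio (2.31:1) rather than refit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .demography import DemographicFit, EpochModel, poisson_loglik
from .expected_sfs import get_engine, _unit_equilibrium
from .sfs import SFS

__all__ = [
    "GammaGridCache",
    "DFEFit",
    "DiscretizedDFE",
    "build_gamma_cache",
    "expected_sfs_under_dfe",
    "GammaDFE",
    "fit_dfe",
    "scale_to_s",
    "discretize",
    "standardized_residuals",
    "DEFAULT_BIN_EDGES",
]

#: Discretization bin edges in s units: neutral (0 to 1e-5), nearly neutral
#: (1e-5 to 1e-4), weakly/moderately deleterious, strongly deleterious (>1e-2).
DEFAULT_BIN_EDGES = (0.0, 1e-5, 1e-4, 1e-3, 1e-2, np.inf)


@dataclass
class GammaGridCache:
    """Expected unit-theta spectra on a |gamma| grid under one demography."""

    demography: EpochModel
    gamma_grid: np.ndarray  # |gamma| values, strictly increasing, >0
    spectra: np.ndarray     # (len(grid), n-1) polymorphic bins at theta=1
    neutral: np.ndarray     # gamma=0 endpoint, (n-1,)
    n: int

    def __post_init__(self):
        if np.any(np.diff(self.gamma_grid) <= 0):
            raise ValueError("gamma grid must be strictly increasing")
        if np.any(self.spectra <= 0) or np.any(self.neutral <= 0):
            raise ValueError("cached spectra must be positive on polymorphic bins")


@dataclass
class DFEFit:
    """Maximum-likelihood gamma DFE with unit conversions."""

    shape: float
    scale_gamma: float      # in 2*N_a*s_dhet units
    scale_s_dhet: float
    theta_ns: float
    loglik: float
    N_a_used: float
    n_starts_converged: int = 0
    converged: bool = False


@dataclass(frozen=True)
class DiscretizedDFE:
    """Probability mass of new mutations per selection-strength bin."""

    bin_edges: tuple
    masses: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(np.asarray(self.bin_edges)) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.masses < 0) or abs(self.masses.sum() - 1.0) > 1e-6:
            raise ValueError("masses must be a probability vector")


def build_gamma_cache(
    demographic_fit: DemographicFit | EpochModel,
    n: int,
    gamma_min: float = 1e-4,
    gamma_max: float = 2000.0,
    n_grid: int = 120,
) -> GammaGridCache:
    """Precompute expected unit-theta spectra over a log-spaced |gamma| grid.

    Under a one-epoch demography the spectra come from the exact sojourn
    quadrature; under two-epoch from the transient solver evaluated at the
    fitted (nu, T).
    """
    model = (
        demographic_fit.model
        if isinstance(demographic_fit, DemographicFit)
        else demographic_fit
    )
    grid = np.geomspace(gamma_min, gamma_max, n_grid)
    if model.kind == "one_epoch":
        neutral = _unit_equilibrium(n, 0.0)
        spectra = np.array([_unit_equilibrium(n, -float(g)) for g in grid])
    else:
        engine = get_engine(n)
        neutral = engine.neutral_two_epoch(model.nu, model.T)
        spectra = np.array(
            [engine.selected_two_epoch(model.nu, model.T, -float(g)) for g in grid]
        )
    return GammaGridCache(
        demography=model, gamma_grid=grid, spectra=spectra, neutral=neutral, n=n
    )


def _mixture_weights(cache: GammaGridCache, shape: float, scale_gamma: float) -> tuple[np.ndarray, float, float]:
    """Gamma-distribution mass per grid cell, plus the two tail masses.

    Cells are delimited by geometric midpoints of the log-spaced grid and
    integrated exactly with the regularized incomplete gamma CDF; mass
    below the smallest |gamma| is treated as neutral, mass above the
    largest is assigned to the strongest-selection spectrum (whose
    polymorphic contribution is negligible).  Weights sum to one exactly.
    """
    g = cache.gamma_grid
    edges = np.empty(len(g) + 1)
    edges[1:-1] = np.sqrt(g[:-1] * g[1:])
    edges[0] = g[0] / np.sqrt(g[1] / g[0])
    edges[-1] = g[-1] * np.sqrt(g[-1] / g[-2])
    cdf = stats.gamma.cdf(edges, a=shape, scale=scale_gamma)
    w = np.diff(cdf)
    lo_tail = cdf[0]          # effectively neutral mass
    hi_tail = 1.0 - cdf[-1]   # beyond-grid strongly deleterious mass
    return w, lo_tail, hi_tail


def expected_sfs_under_dfe(
    cache: GammaGridCache,
    shape: float,
    scale_gamma: float,
    theta_ns: float,
) -> np.ndarray:
    """Expected polymorphic nonsynonymous spectrum under a gamma DFE."""
    if not (np.isfinite(shape) and np.isfinite(scale_gamma)) or shape <= 0 or scale_gamma <= 0:
        raise ValueError("shape and scale must be positive finite numbers")
    if theta_ns <= 0:
        raise ValueError("theta_ns must be positive")
    w, lo, hi = _mixture_weights(cache, shape, scale_gamma)
    mix = lo * cache.neutral + w @ cache.spectra + hi * cache.spectra[-1]
    return theta_ns * mix


class GammaDFE(BaseEstimator):
    """Gamma-DFE estimator conditioned on a demographic fit.

    Maximises the Poisson composite likelihood of the observed
    nonsynonymous spectrum over (shape, scale_gamma), with theta_ns held
    fixed; multi-start Nelder-Mead in log-parameter space.

    Parameters
    ----------
    n_starts : independent optimiser starts (study default 25).
    shape_start_bounds, scale_start_bounds : log-uniform sampling boxes for
        the starts (not fitting constraints).
    """

    def __init__(
        self,
        n_starts: int = 25,
        shape_start_bounds: tuple = (0.05, 1.0),
        scale_start_bounds: tuple = (10.0, 5000.0),
        maxiter: int = 400,
    ):
        self.n_starts = n_starts
        self.shape_start_bounds = shape_start_bounds
        self.scale_start_bounds = scale_start_bounds
        self.maxiter = maxiter

    def fit(
        self,
        sfs: SFS,
        cache: GammaGridCache,
        theta_ns: float,
        N_a: float,
        rng: np.random.Generator | int | None = None,
    ) -> "GammaDFE":
        if sfs.folded:
            raise ValueError("DFE fitting expects an unfolded SFS")
        if sfs.n != cache.n:
            raise ValueError(f"sample-size mismatch: sfs n={sfs.n}, cache n={cache.n}")
        rng = np.random.default_rng(rng)
        obs = sfs.polymorphic

        def neg_ll(logp):
            if not np.all(np.isfinite(logp)) or np.any(np.abs(logp) > 20):
                return 1e12
            shape, scale = np.exp(logp)
            exp = expected_sfs_under_dfe(cache, shape, scale, theta_ns)
            ll = poisson_loglik(exp, obs)
            return -ll if np.isfinite(ll) else 1e12

        lb = np.log([self.shape_start_bounds[0], self.scale_start_bounds[0]])
        ub = np.log([self.shape_start_bounds[1], self.scale_start_bounds[1]])
        results = []
        for _ in range(self.n_starts):
            x0 = rng.uniform(lb, ub)
            res = minimize(
                neg_ll,
                x0,
                method="Nelder-Mead",
                options={"maxiter": self.maxiter, "xatol": 1e-7, "fatol": 1e-9},
            )
            if np.isfinite(res.fun) and res.fun < 1e11:
                results.append(res)
        if not results:
            raise RuntimeError(f"all {self.n_starts} DFE optimiser starts failed")
        results.sort(key=lambda r: r.fun)
        best = results[0]
        self.shape_, self.scale_gamma_ = [float(v) for v in np.exp(best.x)]
        self.loglik_ = -float(best.fun)
        self.theta_ns_ = theta_ns
        self.N_a_used_ = N_a
        self.scale_s_dhet_ = scale_to_s(self.scale_gamma_, N_a)
        self.n_starts_converged_ = sum(
            1 for r in results if abs(r.fun - best.fun) / max(abs(best.fun), 1.0) < 1e-4
        )
        self.converged_ = (
            len(results) > 1
            and abs(results[1].fun - best.fun) / max(abs(best.fun), 1.0) < 1e-4
        )
        return self

    def result(self) -> DFEFit:
        return DFEFit(
            shape=self.shape_,
            scale_gamma=self.scale_gamma_,
            scale_s_dhet=self.scale_s_dhet_,
            theta_ns=self.theta_ns_,
            loglik=self.loglik_,
            N_a_used=self.N_a_used_,
            n_starts_converged=self.n_starts_converged_,
            converged=self.converged_,
        )


def fit_dfe(
    observed_ns: SFS,
    cache: GammaGridCache,
    theta_ns: float,
    N_a: float,
    n_starts: int = 25,
    rng: np.random.Generator | int | None = None,
) -> DFEFit:
    """Fit a gamma DFE to a nonsynonymous spectrum; see ``GammaDFE``."""
    est = GammaDFE(n_starts=n_starts)
    est.fit(observed_ns, cache, theta_ns, N_a, rng=rng)
    return est.result()


def scale_to_s(scale_gamma: float, N_a: float) -> float:
    """Convert a gamma-distribution scale from 2*N_a*s_dhet units to
    s_dhet units: s_dhet = gamma / (2*N_a)."""
    if N_a <= 0:
        raise ValueError("N_a must be positive")
    return scale_gamma / (2.0 * N_a)


def discretize(
    shape: float,
    scale_s: float,
    edges: tuple = DEFAULT_BIN_EDGES,
    *,
    method: str = "cdf",
    n_draws: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> DiscretizedDFE:
    """Probability mass of the gamma DFE in selection-strength bins.

    ``method='cdf'`` uses exact regularized-incomplete-gamma differences;
    ``method='mc'`` reproduces the sampling convention (default 10,000
    draws) for replication parity.
    """
    edges_arr = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges_arr) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if shape <= 0 or scale_s <= 0:
        raise ValueError("shape and scale must be positive")
    if method == "cdf":
        cdf = stats.gamma.cdf(edges_arr, a=shape, scale=scale_s)
        masses = np.diff(cdf)
    elif method == "mc":
        rng = np.random.default_rng(rng)
        draws = rng.gamma(shape, scale_s, size=n_draws)
        masses = np.histogram(draws, bins=edges_arr)[0] / n_draws
    else:
        raise ValueError(f"unknown method {method!r}")
    return DiscretizedDFE(bin_edges=tuple(edges_arr), masses=masses)


def standardized_residuals(
    inferred_masses: np.ndarray, true_masses: np.ndarray
) -> np.ndarray:
    """Per-bin (inferred - true) / sqrt(true) residuals of discretized DFEs."""
    inf_m = np.asarray(inferred_masses, float)
    tru_m = np.asarray(true_masses, float)
    if inf_m.shape != tru_m.shape:
        raise ValueError("binnings differ")
    if np.any(tru_m <= 0):
        raise ValueError("true masses must be positive")
    return (inf_m - tru_m) / np.sqrt(tru_m)
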