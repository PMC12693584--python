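"""Expected site-frequency spectra under the Poisson random field model.

Two solvers live here:

* ``expected_sfs_equilibrium`` — the stationary expectation for a
  constant-size population with genic selection, from Wright's sojourn
  density ``tau(x) = theta * (1 - exp(-2*gamma*(1-x))) /
  ((1 - exp(-2*gamma)) * x * (1-x))`` where ``gamma = 2*N_a*s_het`` is the
  population-scaled selection coefficient of the heterozygote (negative for
  deleterious mutations).  The neutral limit is the classical
  ``E[X_i] = theta / i``.

* ``TwoEpochEngine`` / ``expected_sfs_two_epoch`` — the transient
  expectation after an instantaneous size change ``nu = N_cur / N_a`` held
  for ``T`` units of ``2*N_a`` generations.  The sample spectrum obeys a
  linear ODE ``dPhi/dt = A(nu, gamma) Phi + u`` whose drift part is exact
  (the neutral moment hierarchy closes at order n); the selection part
  couples to order n+1 and is closed with a quadratic-interpolation
  jackknife.  The constant-coefficient system is solved in closed form via
  eigendecomposition (neutral) or a matrix exponential (selected), so no
  time-stepping error is incurred.

Sign convention: ``gamma`` is passed as the signed heterozygote coefficient;
the deleterious direction used throughout this study is ``gamma <= 0``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import linalg
from scipy.special import gammaln

from .sfs import SFS

__all__ = [
    "expected_sfs_equilibrium",
    "expected_sfs_two_epoch",
    "TwoEpochEngine",
    "sojourn_ratio",
]


def sojourn_ratio(x: np.ndarray, gamma: float) -> np.ndarray:
    """Stable evaluation of (1 - exp(-2g(1-x))) / (1 - exp(-2g)).

    Equals ``1 - x`` in the neutral limit.  For strongly deleterious gamma
    the naive form overflows; rewriting as
    ``exp(2gx) * expm1(2g(1-x)) / expm1(2g)`` keeps every exponent
    non-positive when gamma < 0.
    """
    x = np.asarray(x, dtype=float)
    if gamma == 0.0:
        return 1.0 - x
    if abs(gamma) < 1e-7:
        # second-order Taylor to dodge catastrophic cancellation
        return (1.0 - x) * (1.0 + gamma * x) / (1.0 + gamma)
    if gamma < 0:
        return np.exp(2.0 * gamma * x) * np.expm1(2.0 * gamma * (1.0 - x)) / np.expm1(2.0 * gamma)
    return np.expm1(-2.0 * gamma * (1.0 - x)) / np.expm1(-2.0 * gamma)


def _log_sojourn_ratio(x: np.ndarray, gamma: float) -> np.ndarray:
    """log of ``sojourn_ratio`` without intermediate underflow."""
    x = np.asarray(x, dtype=float)
    if abs(gamma) < 1e-7:
        return np.log(sojourn_ratio(x, gamma))
    if gamma < 0:
        return (
            2.0 * gamma * x
            + np.log(-np.expm1(2.0 * gamma * (1.0 - x)))
            - np.log(-np.expm1(2.0 * gamma))
        )
    return np.log(np.expm1(-2.0 * gamma * (1.0 - x))) - np.log(np.expm1(-2.0 * gamma))


def _gauss_legendre_panels(gamma: float, n: int, order: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Composite Gauss-Legendre nodes/weights on (0,1).

    Geometric refinement toward both endpoints resolves the 1/(2|gamma|)
    boundary layer where low-frequency bins peak; a uniform interior mesh
    resolves the sharp interior maxima of high-frequency bins (width
    ~ sqrt(i)/(2|gamma|)) that appear once |gamma| is large."""
    scale = min(0.5, 1.0 / (2.0 + 2.0 * abs(gamma)), 1.0 / (2.0 * n))
    lo = np.geomspace(scale * 1e-6, 0.5, 30)
    mid = np.arange(0.0125, 1.0, 0.0125)
    breaks = np.unique(np.concatenate([[0.0], lo, mid, 1.0 - lo[::-1], [1.0]]))
    xs, ws = np.polynomial.legendre.leggauss(order)
    nodes, weights = [], []
    for a, b in zip(breaks[:-1], breaks[1:]):
        h = 0.5 * (b - a)
        nodes.append(a + h * (xs + 1.0))
        weights.append(h * ws)
    return np.concatenate(nodes), np.concatenate(weights)


def expected_sfs_equilibrium(
    n: int,
    theta: float,
    gamma: float = 0.0,
    *,
    class_label: str = "other",
) -> SFS:
    """Expected unfolded SFS at mutation-selection-drift equilibrium.

    E[X_i] = theta * Int_0^1 C(n,i) x^(i-1) (1-x)^(n-i-1) R(x; gamma) dx
    with R the sojourn ratio above.  Numerically stable for |gamma| up to
    a few thousand (all exponentials evaluated in log space).
    """
    if n < 2:
        raise ValueError("sample size must be >= 2")
    if theta <= 0:
        raise ValueError("theta must be positive")
    counts = np.zeros(n + 1)
    counts[1:-1] = theta * _unit_equilibrium(n, float(gamma))
    return SFS(counts, n, class_label=class_label)


@lru_cache(maxsize=4096)
def _unit_equilibrium(n: int, gamma: float) -> np.ndarray:
    """Polymorphic bins (1..n-1) of the equilibrium spectrum at theta=1."""
    x, w = _gauss_legendre_panels(gamma, n)
    log_ratio = _log_sojourn_ratio(x, gamma)
    i = np.arange(1, n)
    lbin = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
    # integrand_i(x) = C(n,i) x^(i-1) (1-x)^(n-i-1) R(x); summed in log
    # space so that astronomically small bins keep full relative accuracy
    logx = np.log(x)
    log1mx = np.log1p(-x)
    logf = (
        lbin[:, None]
        + np.outer(i - 1, logx)
        + np.outer(n - i - 1, log1mx)
        + log_ratio[None, :]
        + np.log(w)[None, :]
    )
    m = logf.max(axis=1, keepdims=True)
    out = np.exp(m[:, 0] + np.log(np.exp(logf - m).sum(axis=1)))
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(
            f"equilibrium quadrature failed for n={n}, gamma={gamma}"
        )
    # under extreme selection high-frequency bins underflow float64; they
    # are physically ~0 but kept strictly positive for log-likelihoods
    return np.maximum(out, 1e-300)


# ---------------------------------------------------------------------------
# moment ODE machinery for the two-epoch model


def _drift_matrix(n: int) -> np.ndarray:
    """Exact drift generator A0 on the polymorphic bins 1..n-1 (theta-free).

    Row i:  0.5 * [ (i-1)(n-i+1) Phi(i-1) - 2 i (n-i) Phi(i)
                    + (i+1)(n-i-1) Phi(i+1) ],
    the projection of the Wright-Fisher diffusion's drift term onto
    binomially sampled spectra; time in units of 2*N_a generations.
    """
    A = np.zeros((n - 1, n - 1))
    for i in range(1, n):
        A[i - 1, i - 1] = -i * (n - i)
        if i - 1 >= 1:
            A[i - 1, i - 2] = 0.5 * (i - 1) * (n - i + 1)
        if i + 1 <= n - 1:
            A[i - 1, i] = 0.5 * (i + 1) * (n - i - 1)
    return A


def _jackknife_matrix(n: int) -> np.ndarray:
    """Quadratic-interpolation estimate of the order-(n+1) spectrum.

    Returns J (n x (n-1)) with Psi = J @ Phi, where Psi(j), j=1..n are the
    polymorphic bins of the (n+1)-sample spectrum.  Each row fits a local
    quadratic to the underlying density through three adjacent order-n
    bins, using the exact first two moments of the Beta kernels
    Phi_m(i) = E_Beta(i+1, m-i+1)[f] / (m+1).
    """
    J = np.zeros((n, n - 1))
    for j in range(1, n + 1):
        mu_t = (j + 1) / (n + 3)  # Beta mean of the target kernel
        i0 = int(round(mu_t * (n + 2) - 1))
        i0 = min(max(i0, 2), n - 2)
        idx = np.array([i0 - 1, i0, i0 + 1])
        # source kernel moments, centred at mu_t for conditioning
        a = idx + 1.0
        m1 = a / (n + 2)
        m2 = a * (a + 1.0) / ((n + 2) * (n + 3))
        M = np.column_stack([np.ones(3), m1 - mu_t, m2 - 2 * mu_t * m1 + mu_t**2])
        # target kernel moments
        at = j + 1.0
        t1 = at / (n + 3)
        t2 = at * (at + 1.0) / ((n + 3) * (n + 4))
        row_t = np.array([1.0, t1 - mu_t, t2 - 2 * mu_t * t1 + mu_t**2])
        coeff = row_t @ np.linalg.inv(M) * (n + 1) / (n + 2)
        J[j - 1, idx - 1] = coeff
    return J


def _selection_matrix(n: int) -> np.ndarray:
    """Projection of the advection term -d/dx[x(1-x) f] onto order-n bins.

    Acts on the order-(n+1) spectrum: row i couples Psi(i) and Psi(i+1)
    with weights i(n+1-i)/(n+1) and -(i+1)(n-i)/(n+1); multiplied by the
    signed gamma by the caller.
    """
    S = np.zeros((n - 1, n))
    for i in range(1, n):
        S[i - 1, i - 1] = i * (n + 1 - i) / (n + 1)
        S[i - 1, i] = -(i + 1) * (n - i) / (n + 1)
    return S


class TwoEpochEngine:
    """Expected-SFS solver for instantaneous size-change demographies.

    Caches the eigendecomposition of the (symmetrizable tridiagonal)
    neutral drift generator so that neutral likelihood evaluations cost two
    dense matrix-vector products; selected spectra fall back to a matrix
    exponential per call.
    """

    def __init__(self, n: int):
        if n < 4:
            raise ValueError("two-epoch engine needs n >= 4")
        self.n = n
        self.A0 = _drift_matrix(n)
        self.SJ = _selection_matrix(n) @ _jackknife_matrix(n)
        # unit-theta mutation influx: nθ/2 into the singleton bin
        self.u = np.zeros(n - 1)
        self.u[0] = n / 2.0
        # symmetrize A0 = Dinv @ Asym @ D for a stable real eigensolve
        a = np.diag(self.A0, 1)   # upper offdiag, length n-2
        b = np.diag(self.A0, -1)  # lower offdiag
        # D A0 D^-1 symmetric requires d[i+1]/d[i] = sqrt(a[i]/b[i+1])
        logd = np.concatenate([[0.0], np.cumsum(0.5 * (np.log(a) - np.log(b)))])
        logd -= logd.mean()
        self.d = np.exp(logd)
        main = np.diag(self.A0)
        off = np.sqrt(a * b)
        from scipy.linalg import eigh_tridiagonal

        lam, Q = eigh_tridiagonal(main, off)
        self.lam = lam
        self.Q = Q
        # e^{A0 t} v = (1/d) * (Q exp(lam t) Q^T) * (d * v)
        self.phi_neutral_eq = 1.0 / np.arange(1, n)  # unit-theta neutral equilibrium

    # -- neutral fast path -------------------------------------------------
    def neutral_two_epoch(self, nu: float, T: float) -> np.ndarray:
        """Unit-theta polymorphic spectrum after a size change to nu at time
        T (2*N_a generations) in the past; exact to machine precision."""
        if nu <= 0 or T <= 0:
            raise ValueError("nu and T must be positive")
        phi0 = self.phi_neutral_eq
        phi_star = nu * self.phi_neutral_eq
        v = self.d * (phi0 - phi_star)
        w = self.Q @ (np.exp(np.clip(self.lam * (T / nu), -745.0, 0.0)) * (self.Q.T @ v))
        return np.maximum(phi_star + w / self.d, 1e-300)

    # -- selected path -----------------------------------------------------
    def generator(self, nu: float, gamma: float) -> np.ndarray:
        return self.A0 / nu + gamma * self.SJ

    def stationary(self, nu: float, gamma: float) -> np.ndarray:
        """Unit-theta stationary spectrum of the (closed) moment system."""
        A = self.generator(nu, gamma)
        phi = linalg.solve(A, -self.u)
        return phi

    #: |gamma| below which the jackknife-closed moment ODE is trusted, and
    #: above which the current-epoch equilibrium (the exact strong-selection
    #: limit, in which the spectrum relaxes on the fast 1/|gamma| timescale)
    #: takes over; log-linear blend in between.
    GAMMA_ODE = 20.0
    GAMMA_EQ = 60.0

    def _ode_two_epoch(self, nu: float, T: float, gamma: float) -> np.ndarray:
        phi0 = self.stationary(1.0, gamma)
        A = self.generator(nu, gamma)
        phi_star = linalg.solve(A, -self.u)
        # propagate via eigendecomposition; the jackknife closure can leak
        # spuriously positive eigenvalues at extreme nu, which are clipped
        # to zero real part (the exact operator is dissipative)
        w, V = np.linalg.eig(A)
        w = np.where(w.real > 0, 1j * w.imag, w)
        c = np.linalg.solve(V, (phi0 - phi_star).astype(complex))
        phi = phi_star + (V @ (np.exp(np.maximum(w.real * T, -745.0) + 1j * w.imag * T) * c)).real
        if np.any(~np.isfinite(phi)):
            raise FloatingPointError(
                f"two-epoch solver produced non-finite values at nu={nu}, "
                f"T={T}, gamma={gamma}"
            )
        return phi

    def selected_two_epoch(self, nu: float, T: float, gamma: float) -> np.ndarray:
        """Unit-theta spectrum under selection gamma after a size change.

        Weak-to-moderate selection uses the closed moment ODE started from
        its own ancestral stationary state (so the nu=1 limit is exactly
        T-invariant); strong selection uses mutation-selection balance at
        the current size (local parameters theta*nu, gamma*nu), where the
        moment closure is unstable but the equilibrium is exact up to
        O(1/(|gamma*nu|*T)) transients."""
        if nu <= 0 or T <= 0:
            raise ValueError("nu and T must be positive")
        if gamma == 0.0:
            return self.neutral_two_epoch(nu, T)
        g = abs(gamma)
        eq_cur = None
        if g >= self.GAMMA_ODE:
            eq_cur = nu * _unit_equilibrium(self.n, gamma * nu)
            if g >= self.GAMMA_EQ:
                return eq_cur
        phi = self._ode_two_epoch(nu, T, gamma)
        if eq_cur is not None:
            w = (np.log(self.GAMMA_EQ) - np.log(g)) / (
                np.log(self.GAMMA_EQ) - np.log(self.GAMMA_ODE)
            )
            phi = w * phi + (1.0 - w) * eq_cur
        return np.maximum(phi, 1e-300)


@lru_cache(maxsize=16)
def get_engine(n: int) -> TwoEpochEngine:
    return TwoEpochEngine(n)


def expected_sfs_two_epoch(
    n: int,
    theta: float,
    nu: float,
    T: float,
    gamma: float = 0.0,
    *,
    class_label: str = "other",
) -> SFS:
    """Expected unfolded SFS ``T`` time units after a size change to
    ``nu`` times the ancestral size, with genic selection ``gamma``."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    engine = get_engine(n)
    phi = engine.selected_two_epoch(nu, T, gamma) if gamma != 0.0 else engine.neutral_two_epoch(nu, T)
    counts = np.zeros(n + 1)
    counts[1:-1] = theta * phi
    return SFS(counts, n, class_label=class_label)
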