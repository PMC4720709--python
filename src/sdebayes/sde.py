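"""Linear vector SDEs: closed-form Gaussian moments and Euler-Maruyama simulation.

The model class is the narrow-sense linear Ito SDE

    dX_t = (A(t) X_t + a(t)) dt + B(t) dW_t,    X_{t0} = c,

with ``A(t)`` a ``p x p`` drift matrix, ``a(t)`` a ``p``-vector offset,
``B(t)`` a ``p x q`` dispersion matrix (state-free), and ``W`` a standard
q-dimensional Wiener process.  When the initial condition is constant or
Gaussian the solution is a Gaussian process whose mean and covariance are
available in closed form through the fundamental matrix ``Phi(t)`` of the
homogeneous system ``dPhi/dt = A(t) Phi``, ``Phi(t0) = I``:

    m(t)        = Phi(t) (E[c] + int_{t0}^{t} Phi(s)^{-1} a(s) ds)
    Psi(ti, tj) = Phi(ti) (Cov[c] + int_{t0}^{ti} Phi(u)^{-1} B(u) B(u)^T
                                     Phi(u)^{-T} du) Phi(tj)^T,   ti <= tj.

The time integrals are evaluated by composite Gauss-Legendre quadrature
with automatic node doubling (relative tolerance 1e-9); constant-coefficient
specs use the matrix exponential for ``Phi``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .exceptions import InvalidSpecError, NumericalError
from .paths import UNLABELED, ObservationGrid, PathSet

MatrixLike = Union[np.ndarray, Callable[[float], np.ndarray]]

_QUAD_RTOL = 1e-9
_QUAD_START_ORDER = 8
_QUAD_MAX_ORDER = 256
#: Euler-Maruyama internal steps per inter-observation interval.
DEFAULT_SUBSTEPS = 10


def _as_const(x, shape, name: str):
    arr = np.asarray(x, dtype=float)
    if arr.shape != shape:
        raise InvalidSpecError(f"{name} must have shape {shape}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidSpecError(f"{name} has non-finite entries")
    return arr


@dataclass(frozen=True)
class LinearSDESpec:
    """Specification of one class-conditional linear vector SDE.

    Parameters
    ----------
    p, q : int
        State and Wiener-process dimensions.
    A : array or callable
        ``p x p`` drift matrix, constant or a function of time.
    a : array or callable
        ``p``-vector drift offset, constant or a function of time.
    B : array or callable
        ``p x q`` dispersion matrix, constant or a function of time.
    init_mean : array
        Mean of the initial condition ``c`` (the value itself when constant).
    init_cov : array, optional
        Covariance of a Gaussian initial condition; zero matrix (the
        default) for a constant initial condition.
    t0 : float
        Initial time.
    """

    p: int
    q: int
    A: MatrixLike
    a: MatrixLike
    B: MatrixLike
    init_mean: np.ndarray
    init_cov: np.ndarray = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        p, q = int(self.p), int(self.q)
        if p < 1 or q < 1:
            raise InvalidSpecError("p and q must be positive integers")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "t0", float(self.t0))
        if not callable(self.A):
            object.__setattr__(self, "A", _as_const(self.A, (p, p), "A"))
        if not callable(self.a):
            object.__setattr__(self, "a", _as_const(self.a, (p,), "a"))
        if not callable(self.B):
            object.__setattr__(self, "B", _as_const(self.B, (p, q), "B"))
        object.__setattr__(
            self, "init_mean", _as_const(self.init_mean, (p,), "init_mean")
        )
        ic = self.init_cov if self.init_cov is not None else np.zeros((p, p))
        ic = _as_const(ic, (p, p), "init_cov")
        if not np.allclose(ic, ic.T):
            raise InvalidSpecError("init_cov must be symmetric")
        eig = np.linalg.eigvalsh(0.5 * (ic + ic.T))
        if eig.min() < -1e-12 * max(1.0, eig.max()):
            raise InvalidSpecError("init_cov must be positive semidefinite")
        object.__setattr__(self, "init_cov", 0.5 * (ic + ic.T))

    # -- time-indexed coefficient access ------------------------------------
    @property
    def A_constant(self) -> bool:
        return not callable(self.A)

    def A_at(self, t: float) -> np.ndarray:
        M = self.A(t) if callable(self.A) else self.A
        M = np.asarray(M, dtype=float)
        if M.shape != (self.p, self.p) or not np.all(np.isfinite(M)):
            raise InvalidSpecError(f"A({t}) is not a finite {self.p}x{self.p} matrix")
        return M

    def a_at(self, t: float) -> np.ndarray:
        v = self.a(t) if callable(self.a) else self.a
        v = np.asarray(v, dtype=float).reshape(-1)
        if v.shape != (self.p,) or not np.all(np.isfinite(v)):
            raise InvalidSpecError(f"a({t}) is not a finite {self.p}-vector")
        return v

    def B_at(self, t: float) -> np.ndarray:
        M = self.B(t) if callable(self.B) else self.B
        M = np.asarray(M, dtype=float)
        if M.shape != (self.p, self.q) or not np.all(np.isfinite(M)):
            raise InvalidSpecError(f"B({t}) is not a finite {self.p}x{self.q} matrix")
        return M

    @property
    def a_is_zero(self) -> bool:
        return not callable(self.a) and bool(np.all(self.a == 0.0))


def ou_spec(beta: float, theta: float, sigma: float, xa: float) -> LinearSDESpec:
    """Ornstein-Uhlenbeck trait-evolution model as a linear SDE spec.

    The mean-reverting process ``dX = -beta (X - theta) dt + sigma dW`` with
    ancestral state ``X_{t0} = xa`` maps to the linear form with
    ``A = -beta``, ``a = beta * theta``, ``B = sigma``. ``beta`` is the rate
    of adaptation toward the trait optimum ``theta``; ``sigma`` measures
    random selective perturbation.
    """
    if beta < 0 or sigma < 0:
        raise InvalidSpecError("beta and sigma must be nonnegative")
    return LinearSDESpec(
        p=1,
        q=1,
        A=np.array([[-beta]]),
        a=np.array([beta * theta]),
        B=np.array([[sigma]]),
        init_mean=np.array([xa]),
        init_cov=np.zeros((1, 1)),
        t0=0.0,
    )


# ---------------------------------------------------------------------------
# Fundamental matrix
# ---------------------------------------------------------------------------

def fundamental_matrix(spec: LinearSDESpec, t: float) -> np.ndarray:
    """Fundamental matrix ``Phi(t)`` with ``Phi(t0) = I``.

    Solves ``dPhi/dt = A(t) Phi``; for constant ``A`` this is the matrix
    exponential ``expm(A (t - t0))``.
    """
    return _phi_at(spec, np.array([float(t)]))[0]


def _phi_at(spec: LinearSDESpec, times: np.ndarray) -> np.ndarray:
    """Phi(t) for an array of times >= t0, shape (len(times), p, p)."""
    times = np.asarray(times, dtype=float)
    if times.size and times.min() < spec.t0 - 1e-12:
        raise InvalidSpecError(f"requested time {times.min()} precedes t0={spec.t0}")
    p = spec.p
    if spec.A_constant:
        A = spec.A_at(spec.t0)
        return np.array([expm(A * (t - spec.t0)) for t in times])
    # No commutativity assumption: integrate the matrix ODE column-by-column
    # (as one flattened system) with a tight-tolerance adaptive solver.
    order = np.argsort(times)
    sorted_t = times[order]
    out = np.empty((times.size, p, p))
    t_end = sorted_t[-1] if sorted_t.size else spec.t0

    def rhs(s, y):
        return (spec.A_at(s) @ y.reshape(p, p)).reshape(-1)

    if t_end <= spec.t0 + 1e-15:
        out[:] = np.eye(p)
        return out
    sol = solve_ivp(
        rhs,
        (spec.t0, t_end),
        np.eye(p).reshape(-1),
        method="DOP853",
        rtol=1e-11,
        atol=1e-13,
        dense_output=True,
    )
    if not sol.success:
        raise NumericalError(f"fundamental-matrix integration failed: {sol.message}")
    for k, t in zip(order, sorted_t):
        if t <= spec.t0 + 1e-15:
            out[k] = np.eye(p)
        else:
            out[k] = sol.sol(t).reshape(p, p)
    return out


def _phi_inv_at(spec: LinearSDESpec, times: np.ndarray) -> np.ndarray:
    """Phi(t)^{-1} at an array of times, shape (len(times), p, p).

    For constant A this is expm(-A (t - t0)) directly; otherwise the
    computed Phi is inverted (p is small and Phi is nonsingular for any
    genuine fundamental matrix).
    """
    times = np.asarray(times, dtype=float)
    if spec.A_constant:
        A = spec.A_at(spec.t0)
        return np.array([expm(-A * (t - spec.t0)) for t in times])
    phis = _phi_at(spec, times)
    try:
        inv = np.linalg.inv(phis)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guards broken A
        raise NumericalError(f"singular fundamental matrix: {exc}") from exc
    if not np.all(np.isfinite(inv)):
        raise NumericalError("non-finite fundamental-matrix inverse")
    return inv


# ---------------------------------------------------------------------------
# Quadrature
# ---------------------------------------------------------------------------

def _gl_panel(f, lo: float, hi: float, order: int) -> np.ndarray:
    """Gauss-Legendre integral of an array-valued integrand over [lo, hi]."""
    nodes, weights = np.polynomial.legendre.leggauss(order)
    s = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
    vals = f(s)  # shape (order, ...)
    return 0.5 * (hi - lo) * np.tensordot(weights, vals, axes=(0, 0))


def _adaptive_gl(f, lo: float, hi: float) -> np.ndarray:
    """Gauss-Legendre with node doubling until relative change < 1e-9."""
    if hi <= lo:
        shape = np.asarray(f(np.array([lo]))).shape[1:]
        return np.zeros(shape)
    order = _QUAD_START_ORDER
    prev = _gl_panel(f, lo, hi, order)
    while order < _QUAD_MAX_ORDER:
        order *= 2
        cur = _gl_panel(f, lo, hi, order)
        scale = max(np.max(np.abs(cur)), 1e-300)
        if np.max(np.abs(cur - prev)) <= _QUAD_RTOL * max(scale, 1.0):
            return cur
        prev = cur
    return prev


def _mean_integrand(spec: LinearSDESpec):
    def f(s_nodes: np.ndarray) -> np.ndarray:
        phinv = _phi_inv_at(spec, s_nodes)
        avals = np.array([spec.a_at(s) for s in s_nodes])
        return np.einsum("kij,kj->ki", phinv, avals)

    return f


def _cov_integrand(spec: LinearSDESpec):
    def f(s_nodes: np.ndarray) -> np.ndarray:
        phinv = _phi_inv_at(spec, s_nodes)
        bvals = np.array([spec.B_at(s) for s in s_nodes])
        g = np.einsum("kij,kjl->kil", phinv, bvals)  # Phi^{-1} B
        return np.einsum("kil,kjl->kij", g, g)  # (Phi^{-1} B)(Phi^{-1} B)^T

    return f


def _cumulative_integrals(spec: LinearSDESpec, times: np.ndarray):
    """Cumulative mean/covariance integrals from t0 up to each time.

    Returns ``(Ia, IC)`` where ``Ia[k] = int_{t0}^{times[k]} Phi^{-1} a ds``
    and ``IC[k]`` is the matching dispersion integral. ``times`` must be
    sorted ascending.
    """
    p = spec.p
    K = times.size
    Ia = np.zeros((K, p))
    IC = np.zeros((K, p, p))
    fm = _mean_integrand(spec)
    fc = _cov_integrand(spec)
    acc_a = np.zeros(p)
    acc_c = np.zeros((p, p))
    lo = spec.t0
    for k, hi in enumerate(times):
        if hi > lo:
            if not spec.a_is_zero:
                acc_a = acc_a + _adaptive_gl(fm, lo, hi)
            acc_c = acc_c + _adaptive_gl(fc, lo, hi)
            lo = hi
        Ia[k] = acc_a
        IC[k] = acc_c
    return Ia, IC


# ---------------------------------------------------------------------------
# Moments
# ---------------------------------------------------------------------------

def sde_mean(spec: LinearSDESpec, t: float) -> np.ndarray:
    """Closed-form process mean ``m(t)`` (deterministic quadrature in time)."""
    t = float(t)
    if t < spec.t0 - 1e-12:
        raise InvalidSpecError(f"t={t} precedes t0={spec.t0}")
    phi = fundamental_matrix(spec, t)
    if spec.a_is_zero:
        return phi @ spec.init_mean
    integral = _adaptive_gl(_mean_integrand(spec), spec.t0, t)
    return phi @ (spec.init_mean + integral)


def sde_cov(spec: LinearSDESpec, ti: float, tj: float) -> np.ndarray:
    """Closed-form process covariance ``Psi(ti, tj)`` between two times.

    Defined for ``t0 <= ti <= tj``; for ``ti > tj`` the transpose identity
    ``Psi(ti, tj) = Psi(tj, ti)^T`` is applied.
    """
    ti, tj = float(ti), float(tj)
    if min(ti, tj) < spec.t0 - 1e-12:
        raise InvalidSpecError(f"times ({ti}, {tj}) precede t0={spec.t0}")
    if ti > tj:
        return sde_cov(spec, tj, ti).T
    C = spec.init_cov + _adaptive_gl(_cov_integrand(spec), spec.t0, ti)
    phi_i = fundamental_matrix(spec, ti)
    phi_j = phi_i if tj == ti else fundamental_matrix(spec, tj)
    out = phi_i @ C @ phi_j.T
    if ti == tj:
        out = 0.5 * (out + out.T)
    return out


def stacked_moments(spec: LinearSDESpec, grid: ObservationGrid):
    """Stacked mean and block covariance of the process on an observation grid.

    Returns
    -------
    mean : ndarray, shape (Np,)
        ``[m(t_1); ...; m(t_N)]`` in time-block order.
    cov : ndarray, shape (Np, Np)
        Symmetric block matrix with ``(i, j)`` block ``Psi(t_i, t_j)``.
    """
    if grid.p != spec.p:
        raise InvalidSpecError(
            f"grid dimension p={grid.p} does not match spec p={spec.p}"
        )
    times = grid.times
    if times.min() < spec.t0 - 1e-12:
        raise InvalidSpecError("grid times must not precede spec t0")
    p, N = spec.p, grid.N
    phis = _phi_at(spec, times)
    Ia, IC = _cumulative_integrals(spec, times)
    mean = np.empty(N * p)
    for i in range(N):
        mean[i * p : (i + 1) * p] = phis[i] @ (spec.init_mean + Ia[i])
    cov = np.empty((N * p, N * p))
    for i in range(N):
        Ci = spec.init_cov + IC[i]
        left = phis[i] @ Ci
        for j in range(i, N):
            block = left @ phis[j].T
            cov[i * p : (i + 1) * p, j * p : (j + 1) * p] = block
            if j > i:
                cov[j * p : (j + 1) * p, i * p : (i + 1) * p] = block.T
    cov = 0.5 * (cov + cov.T)
    return mean, cov


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_paths(
    spec: LinearSDESpec,
    grid: ObservationGrid,
    n: int,
    substeps: int = DEFAULT_SUBSTEPS,
    seed=None,
    label: int = UNLABELED,
) -> PathSet:
    """Euler-Maruyama sample paths of the SDE recorded at the grid times.

    Between consecutive recording times (and between ``t0`` and ``t_1``)
    ``substeps`` uniform internal steps are taken; each internal step of
    length ``dt`` uses independent Wiener increments ``N(0, dt I_q)``.
    The same ``seed`` yields bit-identical output.

    Parameters
    ----------
    n : int
        Number of independent sample paths.
    substeps : int
        Internal Euler-Maruyama steps per inter-observation interval. The
        weak discretization bias is O(dt); increase for moment-accuracy
        studies.
    seed : int, SeedSequence, Generator, or None
        Randomness source.
    label : int
        Class label recorded on the returned PathSet.
    """
    if grid.p != spec.p:
        raise InvalidSpecError(
            f"grid dimension p={grid.p} does not match spec p={spec.p}"
        )
    if n < 1:
        raise InvalidSpecError("n must be >= 1")
    if substeps < 1:
        raise InvalidSpecError("substeps must be >= 1")
    times = grid.times
    if times.min() < spec.t0 - 1e-12:
        raise InvalidSpecError("grid times must not precede spec t0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p, q, N = spec.p, spec.q, grid.N

    X = np.tile(spec.init_mean, (n, 1))
    if np.any(spec.init_cov):
        L0 = np.linalg.cholesky(
            spec.init_cov + 1e-15 * np.eye(p) * max(1.0, np.trace(spec.init_cov))
        )
        X = X + rng.standard_normal((n, p)) @ L0.T

    out = np.empty((n, N, p))
    knots = np.concatenate(([spec.t0], times))
    sqrt = np.sqrt
    for i in range(N):
        lo, hi = knots[i], knots[i + 1]
        if hi > lo:
            dt = (hi - lo) / substeps
            sdt = sqrt(dt)
            for k in range(substeps):
                t = lo + k * dt
                A_t = spec.A_at(t)
                a_t = spec.a_at(t)
                B_t = spec.B_at(t)
                dW = rng.standard_normal((n, q)) * sdt
                X = X + (X @ A_t.T + a_t) * dt + dW @ B_t.T
        out[:, i, :] = X
    return PathSet(grid=grid, paths=out, label=label)
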