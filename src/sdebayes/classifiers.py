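"""Discriminants over stacked path observations: QDA, plug-in Bayes, and the OBC.

All three classifiers operate on the ``Np``-dimensional stacked vectors of a
sample path and output class 0 when a discriminant favors the class-0
process.

* Stochastic QDA plugs per-class Gaussian moments (true, SDE-derived, or
  empirical) into the exact Gaussian log posterior-odds.
* The plug-in Bayes classifier is QDA with the ground-truth process moments.
* The optimal Bayesian classifier (OBC) compares prior-weighted *effective*
  class-conditional densities: under a normal-inverse-Wishart posterior with
  parameters ``(m*, Psi*, nu*, kappa*)`` the effective density is a
  multivariate Student-t with

      k  = kappa* - Np + 1          degrees of freedom,
      Pi = (nu* + 1) / (k nu*) Psi* scale matrix,

  and location ``m*``. Decisions use log densities throughout: the literal
  polynomial form of the discriminant overflows at moderate ``Np``, while
  the log form defines the same boundary. Exact ties go to class 0.

Quadratic forms and log-determinants are computed from one Cholesky
factorization per class; covariance matrices are never inverted explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import gammaln

from .exceptions import InvalidInputError, NumericalError
from .paths import ObservationGrid, PathSet
from .priors import NIWParams

KIND_QDA = "qda"
KIND_OBC = "obc"
KIND_PLUGIN = "bayes-plugin"


def _chol(mat: np.ndarray, what: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if not np.allclose(mat, mat.T, rtol=1e-8, atol=1e-10):
        raise InvalidInputError(f"{what} must be symmetric")
    try:
        return np.linalg.cholesky(0.5 * (mat + mat.T))
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            f"{what} is not positive definite; if this is a sample covariance, "
            "more training paths than the stacked dimension Np are required"
        ) from exc


@dataclass(frozen=True)
class GaussianClassParams:
    """Gaussian moments (m, Psi) of one class, with cached factorization."""

    m: np.ndarray
    Psi: np.ndarray
    chol: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float).reshape(-1)
        Psi = np.asarray(self.Psi, dtype=float)
        if Psi.shape != (m.size, m.size):
            raise InvalidInputError("Psi shape does not match mean dimension")
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "Psi", 0.5 * (Psi + Psi.T))
        object.__setattr__(self, "chol", _chol(self.Psi, "class covariance"))

    @property
    def dim(self) -> int:
        return self.m.size

    @property
    def logdet(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self.chol))))

    def mahalanobis_sq(self, X: np.ndarray) -> np.ndarray:
        """(x - m)^T Psi^{-1} (x - m) for each row of X, via triangular solve."""
        Z = solve_triangular(self.chol, (X - self.m).T, lower=True)
        return np.sum(Z * Z, axis=0)


@dataclass(frozen=True)
class OBCClassParams:
    """Effective multivariate Student-t parameters of one class.

    ``k`` degrees of freedom, location ``m_star``, scale ``Pi``.
    """

    m_star: np.ndarray
    Pi: np.ndarray
    k: float
    chol: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.m_star, dtype=float).reshape(-1)
        Pi = np.asarray(self.Pi, dtype=float)
        if Pi.shape != (m.size, m.size):
            raise InvalidInputError("Pi shape does not match location dimension")
        if not self.k > 0:
            raise InvalidInputError(f"degrees of freedom k must be > 0, got {self.k}")
        object.__setattr__(self, "m_star", m)
        object.__setattr__(self, "Pi", 0.5 * (Pi + Pi.T))
        object.__setattr__(self, "k", float(self.k))
        object.__setattr__(self, "chol", _chol(self.Pi, "effective scale matrix"))

    @property
    def dim(self) -> int:
        return self.m_star.size

    @property
    def logdet(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self.chol))))

    def mahalanobis_sq(self, X: np.ndarray) -> np.ndarray:
        Z = solve_triangular(self.chol, (X - self.m_star).T, lower=True)
        return np.sum(Z * Z, axis=0)


ClassParams = Union[GaussianClassParams, OBCClassParams]


@dataclass(frozen=True)
class BinaryClassifier:
    """A trained binary discriminant over stacked path observations.

    ``kind`` is one of ``"qda"``, ``"bayes-plugin"`` (QDA built from
    ground-truth moments) or ``"obc"``. ``alpha1`` is the known class-1
    mixing probability (separate sampling forbids estimating it from data).
    """

    kind: str
    class0: ClassParams
    class1: ClassParams
    alpha1: float

    def __post_init__(self) -> None:
        if self.kind not in (KIND_QDA, KIND_OBC, KIND_PLUGIN):
            raise InvalidInputError(f"unknown classifier kind {self.kind!r}")
        if not 0.0 < self.alpha1 < 1.0:
            raise InvalidInputError(f"alpha1 must lie in (0, 1), got {self.alpha1}")
        if self.class0.dim != self.class1.dim:
            raise InvalidInputError("class parameter dimensions disagree")
        want = OBCClassParams if self.kind == KIND_OBC else GaussianClassParams
        if not (isinstance(self.class0, want) and isinstance(self.class1, want)):
            raise InvalidInputError(
                f"classifier kind {self.kind!r} requires {want.__name__} bundles"
            )
        object.__setattr__(self, "alpha1", float(self.alpha1))

    @property
    def dim(self) -> int:
        return self.class0.dim

    # -- discriminants -------------------------------------------------------
    def _as_matrix(self, x) -> tuple[np.ndarray, bool]:
        if isinstance(x, PathSet):
            return x.stacked(), False
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            if x.size != self.dim:
                raise InvalidInputError(
                    f"observation dimension {x.size} does not match classifier dimension {self.dim}"
                )
            return x[None, :], True
        if x.ndim != 2 or x.shape[1] != self.dim:
            raise InvalidInputError(
                f"observations must be (n, {self.dim}), got shape {x.shape}"
            )
        return x, False

    def discriminant(self, x) -> np.ndarray:
        """Log-odds style statistic; positive values favor class 0.

        For QDA/plug-in this is the Gaussian log posterior-odds
        ``log[(1-alpha1) f0(x)] - log[alpha1 f1(x)]``; for the OBC the same
        expression with the effective Student-t densities.
        """
        X, single = self._as_matrix(x)
        if self.kind == KIND_OBC:
            val = (
                np.log1p(-self.alpha1)
                + obc_log_effective_density(self.class0, X)
                - np.log(self.alpha1)
                - obc_log_effective_density(self.class1, X)
            )
        else:
            val = qda_discriminant(self, X)
        return float(val[0]) if single else val

    def classify(self, x) -> np.ndarray:
        """Assign labels. QDA assigns 0 iff the discriminant is strictly
        positive; the OBC assigns 0 on ties (weighted-density comparison
        with >=)."""
        X, single = self._as_matrix(x)
        psi = self.discriminant(X)
        if self.kind == KIND_OBC:
            labels = np.where(psi >= 0.0, 0, 1)
        else:
            labels = np.where(psi > 0.0, 0, 1)
        return int(labels[0]) if single else labels


def qda_discriminant(model: BinaryClassifier, x) -> np.ndarray:
    """Quadratic discriminant of stacked observations; > 0 favors class 0.

    psi(x) = -1/2 (x-m0)^T Psi0^{-1} (x-m0) + 1/2 (x-m1)^T Psi1^{-1} (x-m1)
             + 1/2 log(|Psi1| / |Psi0|) - log(alpha1 / (1-alpha1)),

    the exact Gaussian log posterior-odds, computed with stable Cholesky
    log-determinants and triangular solves.
    """
    if model.kind == KIND_OBC:
        raise InvalidInputError("qda_discriminant requires a QDA/plug-in classifier")
    X = x.stacked() if isinstance(x, PathSet) else np.atleast_2d(np.asarray(x, float))
    c0, c1 = model.class0, model.class1
    q0 = c0.mahalanobis_sq(X)
    q1 = c1.mahalanobis_sq(X)
    logdet_term = 0.5 * (c1.logdet - c0.logdet)
    prior_term = -np.log(model.alpha1 / (1.0 - model.alpha1))
    return -0.5 * q0 + 0.5 * q1 + logdet_term + prior_term


def obc_log_effective_density(params: OBCClassParams, x) -> np.ndarray:
    """Log of the normalized multivariate Student-t effective density.

    log f(x) = lgamma((k+d)/2) - lgamma(k/2) - (d/2) log(k pi)
               - 1/2 log|Pi| - ((k+d)/2) log(1 + q(x)/k),

    with ``q(x)`` the Mahalanobis form under the scale ``Pi``. Integrates
    to one.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != params.dim:
        raise InvalidInputError(
            f"observation dimension {X.shape[1]} does not match {params.dim}"
        )
    d = params.dim
    k = params.k
    q = params.mahalanobis_sq(X)
    if not np.all(np.isfinite(q)):
        raise NumericalError("non-finite quadratic form in effective density")
    lognorm = (
        gammaln(0.5 * (k + d))
        - gammaln(0.5 * k)
        - 0.5 * d * np.log(k * np.pi)
        - 0.5 * params.logdet
    )
    return lognorm - 0.5 * (k + d) * np.log1p(q / k)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_obc(post0: NIWParams, post1: NIWParams, alpha1: float) -> BinaryClassifier:
    """Optimal Bayesian classifier from per-class NIW parameters.

    Accepts posteriors (the trained OBC) or priors (the robust, zero-data
    classifier). For each class:

        k  = kappa - Np + 1,
        Pi = (nu + 1) / (k nu) * Psi.
    """
    if post0.dim != post1.dim:
        raise InvalidInputError("class posterior dimensions disagree")
    d = post0.dim

    def effective(p: NIWParams) -> OBCClassParams:
        k = p.kappa - d + 1
        if not k > 0:
            raise InvalidInputError(
                f"kappa*={p.kappa} gives nonpositive degrees of freedom k={k}"
            )
        Pi = (p.nu + 1.0) / (k * p.nu) * p.Psi
        return OBCClassParams(m_star=p.m, Pi=Pi, k=k)

    return BinaryClassifier(
        kind=KIND_OBC, class0=effective(post0), class1=effective(post1), alpha1=alpha1
    )


def build_qda_from_moments(
    m0, Psi0, m1, Psi1, alpha1: float, kind: str = KIND_QDA
) -> BinaryClassifier:
    """QDA classifier directly from per-class Gaussian moments."""
    return BinaryClassifier(
        kind=kind,
        class0=GaussianClassParams(m=m0, Psi=Psi0),
        class1=GaussianClassParams(m=m1, Psi=Psi1),
        alpha1=alpha1,
    )


def build_qda_from_sde(
    spec0,
    spec1,
    grid: ObservationGrid,
    alpha1: float,
    moment_source: str = "analytic",
    l: int = 2000,
    seed=None,
    substeps: int = 10,
) -> BinaryClassifier:
    """QDA whose class moments come from the SDE pair (no training paths).

    With the ground-truth specs and analytic moments this is the Bayes
    classifier; with ``moment_source="simulated"`` the moments are the
    Monte-Carlo estimates from ``l`` simulated paths per class (requires
    ``l > Np`` for invertibility; the Euler-Maruyama ``substeps`` control
    the O(dt) weak bias of those estimates).
    """
    if moment_source == "analytic":
        from .sde import stacked_moments

        m0, P0 = stacked_moments(spec0, grid)
        m1, P1 = stacked_moments(spec1, grid)
    elif moment_source == "simulated":
        from .paths import sde_moment_estimate

        if l <= grid.dim:
            raise NumericalError(
                f"simulated moments need l > Np = {grid.dim} paths for an invertible covariance, got l={l}"
            )
        ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
        s0, s1 = ss.spawn(2)
        m0, P0 = sde_moment_estimate(spec0, grid, l=l, seed=s0, substeps=substeps)
        m1, P1 = sde_moment_estimate(spec1, grid, l=l, seed=s1, substeps=substeps)
    else:
        raise InvalidInputError(
            f"moment_source must be 'analytic' or 'simulated', got {moment_source!r}"
        )
    return BinaryClassifier(
        kind=KIND_PLUGIN,
        class0=GaussianClassParams(m=m0, Psi=P0),
        class1=GaussianClassParams(m=m1, Psi=P1),
        alpha1=alpha1,
    )


def build_qda_from_data(
    train0: PathSet, train1: PathSet, alpha1: float
) -> BinaryClassifier:
    """Stochastic QDA from empirical moments of per-class training paths.

    Requires ``min(n0, n1) > Np`` so that both sample covariances are
    invertible.
    """
    from .paths import empirical_moments

    if train0.grid != train1.grid:
        raise InvalidInputError("training path sets must share one observation grid")
    d = train0.grid.dim
    nmin = min(train0.n, train1.n)
    if nmin <= d:
        raise NumericalError(
            f"QDA needs min(n0, n1) > Np = {d} training paths per class for "
            f"invertible sample covariances; got min(n0, n1) = {nmin}"
        )
    m0, P0 = empirical_moments(train0)
    m1, P1 = empirical_moments(train1)
    return build_qda_from_moments(m0, P0, m1, P1, alpha1, kind=KIND_QDA)
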