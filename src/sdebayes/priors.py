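"""Normal-inverse-Wishart priors induced from SDE moments, and their updates.

The class-conditional stacked mean and covariance ``(mu, Sigma)`` are treated
as uncertain with the conjugate normal-inverse-Wishart (NIW) prior

    Sigma ~ InvWishart(kappa, Psi_breve),    mu | Sigma ~ N(m_breve, Sigma / nu).

``nu`` and ``kappa`` encode confidence in the prior location and scale.  An
SDE whose moments are believed correct *on average* induces the mapping

    m_breve   = m(t_N)                      (stacked SDE mean)
    Psi_breve = (kappa - Np - 1) Psi(t_N)   (stacked SDE covariance),

so that the prior mean of the inverse-Wishart covariance equals the SDE
covariance exactly; this requires ``kappa > Np + 1`` for the inverse-Wishart
mean to exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ImproperPriorError, InvalidInputError
from .paths import ObservationGrid, PathSet, empirical_moments, sde_moment_estimate


@dataclass(frozen=True)
class NIWParams:
    """Normal-inverse-Wishart parameter bundle (prior or posterior).

    Attributes
    ----------
    m : ndarray, shape (d,)
        Location of the Gaussian mean prior.
    Psi : ndarray, shape (d, d)
        Inverse-Wishart scale matrix, symmetric positive definite.
    nu : float
        Mean-confidence scalar (> 0).
    kappa : float
        Covariance-confidence scalar (inverse-Wishart degrees of freedom).
    """

    m: np.ndarray
    Psi: np.ndarray
    nu: float
    kappa: float

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float).reshape(-1)
        Psi = np.asarray(self.Psi, dtype=float)
        if Psi.shape != (m.size, m.size):
            raise InvalidInputError(
                f"Psi shape {Psi.shape} does not match location dimension {m.size}"
            )
        if not np.allclose(Psi, Psi.T, rtol=1e-10, atol=1e-12):
            raise InvalidInputError("Psi must be symmetric")
        Psi = 0.5 * (Psi + Psi.T)
        try:
            np.linalg.cholesky(Psi)
        except np.linalg.LinAlgError as exc:
            raise ImproperPriorError("Psi must be positive definite") from exc
        if not self.nu > 0:
            raise ImproperPriorError(f"nu must be > 0, got {self.nu}")
        if not self.kappa > m.size - 1:
            raise ImproperPriorError(
                f"kappa={self.kappa} violates the propriety condition kappa > d-1 = {m.size - 1}"
            )
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "Psi", Psi)
        object.__setattr__(self, "nu", float(self.nu))
        object.__setattr__(self, "kappa", float(self.kappa))

    @property
    def dim(self) -> int:
        return self.m.size


def prior_from_sde(
    spec,
    grid: ObservationGrid,
    nu: float,
    kappa: float,
    moment_source: str = "analytic",
    l: int = 2000,
    seed=None,
) -> NIWParams:
    """Build the NIW prior from the SDE-induced Gaussian-process moments.

    Parameters
    ----------
    moment_source : {"analytic", "simulated"}
        ``"analytic"`` evaluates the closed-form stacked moments;
        ``"simulated"`` estimates them from ``l`` Euler-Maruyama paths
        (requires ``l > Np`` for a positive-definite scale).
    nu, kappa : float
        Confidence hyperparameters; ``kappa`` must exceed ``Np + 1`` so that
        the inverse-Wishart mean (the SDE covariance) exists.
    """
    d = grid.dim
    if not kappa > d + 1:
        raise ImproperPriorError(
            f"the SDE-to-prior mapping needs kappa > Np+1 = {d + 1}, got kappa={kappa}"
        )
    if moment_source == "analytic":
        from .sde import stacked_moments

        m, Psi = stacked_moments(spec, grid)
    elif moment_source == "simulated":
        m, Psi = sde_moment_estimate(spec, grid, l=l, seed=seed)
    else:
        raise InvalidInputError(
            f"moment_source must be 'analytic' or 'simulated', got {moment_source!r}"
        )
    return NIWParams(m=m, Psi=(kappa - d - 1) * Psi, nu=nu, kappa=kappa)


def posterior_update(prior: NIWParams, train: PathSet) -> NIWParams:
    """Conjugate NIW update with a training set of stacked sample paths.

    With ``n`` training paths of sample mean ``mu_hat`` and (for n >= 2)
    unbiased sample covariance ``Sigma_hat``:

        nu*    = nu + n
        kappa* = kappa + n
        m*     = (nu m + n mu_hat) / (nu + n)
        Psi*   = Psi + (n-1) Sigma_hat
                 + (nu n / (nu + n)) (mu_hat - m)(mu_hat - m)^T.

    ``n = 1`` is allowed: the sample-covariance term vanishes through its
    ``n - 1`` weight. The update is batchwise over pooled sufficient
    statistics.
    """
    if train.grid.dim != prior.dim:
        raise InvalidInputError(
            f"training dimension {train.grid.dim} does not match prior dimension {prior.dim}"
        )
    n = train.n
    mu_hat, Sigma_hat = empirical_moments(train, require_cov=False)
    nu_star = prior.nu + n
    kappa_star = prior.kappa + n
    m_star = (prior.nu * prior.m + n * mu_hat) / (prior.nu + n)
    dev = mu_hat - prior.m
    Psi_star = prior.Psi + (prior.nu * n / (prior.nu + n)) * np.outer(dev, dev)
    if n >= 2:
        Psi_star = Psi_star + (n - 1) * Sigma_hat
    Psi_star = 0.5 * (Psi_star + Psi_star.T)
    return NIWParams(m=m_star, Psi=Psi_star, nu=nu_star, kappa=kappa_star)
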