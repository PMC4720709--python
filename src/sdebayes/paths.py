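"""Observation grids, sample-path collections, and their empirical moments.

A multivariate Gaussian process observed at the common *observation time
vector* ``t_1 < t_2 < ... < t_N`` yields, per sample path, an ``N x p`` array
of states.  Classification treats each path as a single stacked vector of
dimension ``N*p``, blocks ordered by time, so that the stacked mean and
block covariance of the process are ordinary multivariate-Gaussian moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientDataError, InvalidInputError

#: Sentinel label for test paths whose class is unknown. Never 0 or 1.
UNLABELED = -1


@dataclass(frozen=True)
class ObservationGrid:
    """Strictly increasing observation times for a p-dimensional process.

    Parameters
    ----------
    times : array_like
        Observation times ``[t_1, ..., t_N]``, strictly increasing.
    p : int
        State dimension of the observed process.

    The stacked feature space has dimension ``N * p``.
    """

    times: np.ndarray
    p: int

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise InvalidInputError("times must be a nonempty 1-D array")
        if not np.all(np.isfinite(t)):
            raise InvalidInputError("observation times must be finite")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise InvalidInputError("observation times must be strictly increasing")
        if int(self.p) < 1:
            raise InvalidInputError("state dimension p must be a positive integer")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "p", int(self.p))

    @property
    def N(self) -> int:
        """Number of observation times."""
        return self.times.size

    @property
    def dim(self) -> int:
        """Stacked dimension N*p."""
        return self.N * self.p

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ObservationGrid)
            and self.p == other.p
            and self.times.shape == other.times.shape
            and bool(np.all(self.times == other.times))
        )

    def __hash__(self) -> int:
        return hash((self.p, self.times.tobytes()))


def stack(path: np.ndarray) -> np.ndarray:
    """Stack an ``N x p`` path into one ``Np``-vector in time-block order."""
    path = np.asarray(path, dtype=float)
    if path.ndim != 2:
        raise InvalidInputError(f"path must be 2-D (N, p), got shape {path.shape}")
    if not np.all(np.isfinite(path)):
        raise InvalidInputError("path values must be finite")
    return path.reshape(-1)


def unstack(vec: np.ndarray, N: int, p: int) -> np.ndarray:
    """Inverse of :func:`stack`: reshape an ``Np``-vector to ``N x p``."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != N * p:
        raise InvalidInputError(f"vector of size {vec.size} is not N*p = {N * p}")
    return vec.reshape(N, p)


@dataclass(frozen=True)
class PathSet:
    """A labeled collection of sample paths on a common observation grid.

    ``paths`` has shape ``(n, N, p)``; ``label`` is 0 or 1 for training
    data and :data:`UNLABELED` for test points. Classification never reads
    labels; they exist for bookkeeping and error estimation.
    """

    grid: ObservationGrid
    paths: np.ndarray
    label: int = UNLABELED

    def __post_init__(self) -> None:
        x = np.asarray(self.paths, dtype=float)
        if x.ndim != 3:
            raise InvalidInputError(f"paths must be 3-D (n, N, p), got shape {x.shape}")
        if x.shape[1] != self.grid.N or x.shape[2] != self.grid.p:
            raise InvalidInputError(
                f"paths shape {x.shape[1:]} does not match grid (N={self.grid.N}, p={self.grid.p})"
            )
        if x.shape[0] < 1:
            raise InvalidInputError("a PathSet requires at least one path")
        if not np.all(np.isfinite(x)):
            raise InvalidInputError("path values must be finite")
        object.__setattr__(self, "paths", x)
        object.__setattr__(self, "label", int(self.label))

    @property
    def n(self) -> int:
        """Number of sample paths."""
        return self.paths.shape[0]

    def stacked(self) -> np.ndarray:
        """All paths as an ``(n, Np)`` matrix of stacked vectors."""
        return self.paths.reshape(self.n, self.grid.dim)


def empirical_moments(pathset: PathSet, *, require_cov: bool = True):
    """Sample mean and unbiased (divisor n-1) sample covariance of stacked paths.

    Returns
    -------
    mean : ndarray, shape (Np,)
    cov : ndarray, shape (Np, Np) or None
        Symmetric PSD sample covariance; ``None`` when ``require_cov`` is
        False and n == 1.
    """
    X = pathset.stacked()
    n = X.shape[0]
    mean = X.mean(axis=0)
    if n < 2:
        if require_cov:
            raise InsufficientDataError(
                f"sample covariance needs at least 2 paths, got n={n}"
            )
        return mean, None
    D = X - mean
    cov = D.T @ D / (n - 1)
    cov = 0.5 * (cov + cov.T)
    return mean, cov


def sde_moment_estimate(spec, grid: ObservationGrid, l: int, seed, *, substeps: int = 10):
    """Monte-Carlo estimate of the stacked process moments from simulated paths.

    Simulates ``l`` Euler-Maruyama sample paths of ``spec`` on ``grid`` and
    returns their empirical stacked mean and covariance. With ``l > N*p``
    the covariance estimate is almost surely positive definite.
    """
    if l < 2:
        raise InsufficientDataError("moment estimation needs l >= 2 simulated paths")
    from .sde import simulate_paths

    ps = simulate_paths(spec, grid, n=l, substeps=substeps, seed=seed)
    return empirical_moments(ps)
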