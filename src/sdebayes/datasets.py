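"""Ready-made ground-truth configurations for the package's study systems.

Two systems are bundled:

* ``eq33`` — a three-dimensional linear SDE pair whose classes share
  drift ``A = diag(0.01)`` and dispersion ``B = 0.1 * [[1, .4, .4], [.4, 1,
  .4], [.4, .4, 1]]`` and differ only in constant initial condition
  (``[0,0,0]`` vs ``[0.25,0.25,0.25]``), observed at unit spacing on
  ``t = 1..20``.
* ``ou_beta010`` / ``ou_beta015`` — Ornstein-Uhlenbeck trait-evolution
  models for two species adapting to trait optima ``theta0 = 80`` and
  ``theta1 = 85`` from a common ancestral state ``xa = 1`` with perturbation
  ``sigma = 1``, observed over 30 million years at 1-million-year steps
  (time in units of 10^6 years).

Misspecified *a-priori* variants take additive offsets: ``delta_mu`` on the
class-1 drift diagonal, ``delta_rho`` on the class-1 dispersion correlation
(before the 0.1 scaling), ``delta_beta`` on the class-1 adaptation rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .exceptions import InvalidInputError
from .paths import ObservationGrid
from .sde import LinearSDESpec, ou_spec

FIXTURE_NAMES = ("eq33", "ou_beta010", "ou_beta015")


def eq33_spec(
    init_mean, delta_mu: float = 0.0, delta_rho: float = 0.0
) -> LinearSDESpec:
    """One class of the three-dimensional benchmark SDE, optionally offset.

    ``delta_mu`` shifts every diagonal drift entry; ``delta_rho`` shifts the
    off-diagonal correlation entries of the dispersion before its 0.1
    scaling.
    """
    A = np.diag([0.01 + delta_mu] * 3)
    rho = 0.4 + delta_rho
    B = 0.1 * np.array(
        [[1.0, rho, rho], [rho, 1.0, rho], [rho, rho, 1.0]]
    )
    return LinearSDESpec(
        p=3,
        q=3,
        A=A,
        a=np.zeros(3),
        B=B,
        init_mean=np.asarray(init_mean, dtype=float),
        init_cov=np.zeros((3, 3)),
        t0=0.0,
    )


def eq33_grid() -> ObservationGrid:
    """Unit-spaced observation grid t = 1..20 for the p=3 benchmark."""
    return ObservationGrid(times=np.arange(1.0, 21.0), p=3)


def ou_grid() -> ObservationGrid:
    """Observation grid t = 1..30 (units of 10^6 years) for the OU models."""
    return ObservationGrid(times=np.arange(1.0, 31.0), p=1)


@dataclass(frozen=True)
class Fixture:
    """A fully instantiated ground-truth experiment configuration."""

    name: str
    spec0: LinearSDESpec
    spec1: LinearSDESpec
    grid: ObservationGrid
    defaults: dict = field(default_factory=dict)


_EQ33_PARAMS = {
    "init0": (0.0, 0.0, 0.0),
    "init1": (0.25, 0.25, 0.25),
}

_OU_PARAMS = {
    "theta0": 80.0,
    "theta1": 85.0,
    "sigma": 1.0,
    "xa": 1.0,
}

# Reduced-scale experiment defaults; the full-scale study uses T=1000
# replicates and n_test=2000 per class (available via overrides/config).
_COMMON_DEFAULTS = {
    "alpha1": 0.5,
    "n_test": 500,
    "T": 50,
    "substeps": 10,
    "l": 2000,
    "kappa_extras": (20, 50, 100, 500),
}


def make_fixture(name: str, **overrides: Any) -> Fixture:
    """Instantiate a named ground-truth configuration.

    Overrides replace only the named model parameters or experiment
    defaults, leaving everything else at the fixture values. Recognized
    override keys: the per-fixture model parameters (``init0``/``init1``
    for eq33; ``beta``, ``theta0``, ``theta1``, ``sigma``, ``xa`` for the OU
    fixtures) plus the defaults ``alpha1``, ``n_values``, ``n_test``, ``T``,
    ``substeps``, ``l``, ``kappa_extras``.
    """
    if name == "eq33":
        params = dict(_EQ33_PARAMS)
        defaults = dict(_COMMON_DEFAULTS, n_values=(65, 80, 100, 120))
    elif name in ("ou_beta010", "ou_beta015"):
        params = dict(_OU_PARAMS, beta=0.1 if name == "ou_beta010" else 0.15)
        defaults = dict(_COMMON_DEFAULTS, n_values=(60, 100, 140))
    else:
        raise InvalidInputError(
            f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}"
        )
    for key, value in overrides.items():
        if key in params:
            params[key] = value
        elif key in defaults:
            defaults[key] = value
        else:
            raise InvalidInputError(f"unknown override {key!r} for fixture {name!r}")

    if name == "eq33":
        spec0 = eq33_spec(params["init0"])
        spec1 = eq33_spec(params["init1"])
        grid = eq33_grid()
    else:
        spec0 = ou_spec(params["beta"], params["theta0"], params["sigma"], params["xa"])
        spec1 = ou_spec(params["beta"], params["theta1"], params["sigma"], params["xa"])
        grid = ou_grid()
    defaults["params"] = params
    return Fixture(name=name, spec0=spec0, spec1=spec1, grid=grid, defaults=defaults)
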