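"""True-error estimation and the end-to-end misspecification experiments.

The protocol, per experiment cell (a priori offset, training size n,
confidence kappa) and replicate:

1. simulate n ground-truth training paths per class and n_test fresh test
   paths per class (Euler-Maruyama);
2. build the NIW prior of each class from the *a priori* SDE pair (exact
   moments by default, or l simulated paths), with nu = kappa;
3. update the priors with the training paths and build the OBC; train the
   stochastic QDA on the same training paths;
4. score both on the test paths; attach the plug-in Bayes classifier's
   error (ground-truth moments) on the same test sets as a lower-bound
   reference.

Errors are averaged over T replicates. Every replicate's randomness derives
from the root seed and the cell/replicate indices, so any cell reruns
bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classifiers import (
    BinaryClassifier,
    build_obc,
    build_qda_from_data,
    build_qda_from_sde,
)
from .datasets import eq33_spec, make_fixture
from .exceptions import InvalidInputError, SDEBayesError
from .paths import ObservationGrid, PathSet, sde_moment_estimate
from .priors import NIWParams, posterior_update
from .sde import LinearSDESpec, ou_spec, simulate_paths, stacked_moments

logger = logging.getLogger(__name__)

#: Column schema of the error table returned by the experiment drivers.
ERROR_TABLE_COLUMNS = (
    "classifier",
    "n",
    "kappa",
    "offset_name",
    "offset_value",
    "mean_error",
    "mc_se",
    "bayes_error",
    "bayes_se",
)


def true_error(
    model: BinaryClassifier, test0: PathSet, test1: PathSet, alpha1: float
) -> float:
    """Monte-Carlo misclassification probability on labeled test path sets.

    Returns ``(1-alpha1) * P(label 1 | class 0) + alpha1 * P(label 0 |
    class 1)`` estimated by the per-class test error rates.
    """
    if test0.grid != test1.grid:
        raise InvalidInputError("test path sets must share one observation grid")
    if test0.grid.dim != model.dim:
        raise InvalidInputError(
            f"test grid dimension {test0.grid.dim} does not match classifier dimension {model.dim}"
        )
    err0 = float(np.mean(model.classify(test0) != 0))
    err1 = float(np.mean(model.classify(test1) != 1))
    return (1.0 - alpha1) * err0 + alpha1 * err1


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to run one misspecification experiment sweep.

    ``apriori`` lists the prior-knowledge SDE pairs to sweep, each tagged
    with the offset that produced it: tuples ``(offset_name, offset_value,
    spec0, spec1)``. ``kappa_values`` are the absolute confidence
    hyperparameters (the propriety-motivated choice is ``Np + extra``);
    ``nu = kappa`` for both classes.
    """

    grid: ObservationGrid
    gt0: LinearSDESpec
    gt1: LinearSDESpec
    apriori: tuple
    n_values: tuple
    kappa_values: tuple
    alpha1: float = 0.5
    n_test: int = 500
    T: int = 50
    substeps: int = 10
    prior_moment_source: str = "analytic"
    l_prior: int = 2000
    bayes_moment_source: str = "analytic"
    l_bayes: int = 2000
    root_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_test < 1 or self.T < 1:
            raise InvalidInputError("n_test and T must be >= 1")
        if not 0.0 < self.alpha1 < 1.0:
            raise InvalidInputError("alpha1 must lie in (0, 1)")
        d = self.grid.dim
        for n in self.n_values:
            if n <= d:
                raise InvalidInputError(
                    f"training size n={n} must exceed Np={d} for the data-QDA baseline"
                )
        for kappa in self.kappa_values:
            if not kappa > d + 1:
                raise InvalidInputError(
                    f"kappa={kappa} must exceed Np+1={d + 1} for the SDE-to-prior mapping"
                )
        object.__setattr__(self, "apriori", tuple(self.apriori))
        object.__setattr__(self, "n_values", tuple(int(n) for n in self.n_values))
        object.__setattr__(
            self, "kappa_values", tuple(float(k) for k in self.kappa_values)
        )


def synthetic_config(
    offset_name: str = "delta_mu",
    offset_values: Sequence[float] = (0.0, 0.1, 0.2, 0.3),
    *,
    n_values: Sequence[int] | None = None,
    kappa_extras: Sequence[float] | None = None,
    T: int | None = None,
    n_test: int | None = None,
    alpha1: float | None = None,
    root_seed: int = 0,
    **kwargs,
) -> ExperimentConfig:
    """Config for the three-dimensional benchmark with drift or dispersion offsets.

    ``offset_name`` is ``"delta_mu"`` (added to each diagonal entry of the
    class-1 a-priori drift) or ``"delta_rho"`` (added to the class-1
    dispersion correlation). Class 0's a-priori SDE always equals the
    ground truth.
    """
    fx = make_fixture("eq33")
    d = fx.grid.dim
    defaults = fx.defaults
    if offset_name not in ("delta_mu", "delta_rho"):
        raise InvalidInputError(
            f"offset_name must be 'delta_mu' or 'delta_rho', got {offset_name!r}"
        )
    apriori = []
    for val in offset_values:
        kw = {offset_name: float(val)}
        ap1 = eq33_spec(fx.defaults["params"]["init1"], **kw)
        apriori.append((offset_name, float(val), fx.spec0, ap1))
    extras = kappa_extras if kappa_extras is not None else defaults["kappa_extras"]
    return ExperimentConfig(
        grid=fx.grid,
        gt0=fx.spec0,
        gt1=fx.spec1,
        apriori=tuple(apriori),
        n_values=tuple(n_values if n_values is not None else defaults["n_values"]),
        kappa_values=tuple(d + e for e in extras),
        alpha1=alpha1 if alpha1 is not None else defaults["alpha1"],
        n_test=n_test if n_test is not None else defaults["n_test"],
        T=T if T is not None else defaults["T"],
        root_seed=root_seed,
        **kwargs,
    )


def ou_config(
    beta: float = 0.1,
    delta_betas: Sequence[float] = (0.0, 0.02, 0.04, 0.06),
    *,
    n_values: Sequence[int] | None = None,
    kappa_extras: Sequence[float] | None = None,
    T: int | None = None,
    n_test: int | None = None,
    alpha1: float | None = None,
    root_seed: int = 0,
    **kwargs,
) -> ExperimentConfig:
    """Config for the OU trait-evolution experiment with adaptation-rate offsets.

    The a-priori class-1 model uses adaptation rate ``beta + delta_beta``;
    everything else matches the ground truth.
    """
    name = "ou_beta015" if np.isclose(beta, 0.15) else "ou_beta010"
    fx = make_fixture(name, beta=beta)
    params = fx.defaults["params"]
    d = fx.grid.dim
    apriori = []
    for db in delta_betas:
        ap1 = ou_spec(beta + db, params["theta1"], params["sigma"], params["xa"])
        apriori.append(("delta_beta", float(db), fx.spec0, ap1))
    defaults = fx.defaults
    extras = kappa_extras if kappa_extras is not None else defaults["kappa_extras"]
    return ExperimentConfig(
        grid=fx.grid,
        gt0=fx.spec0,
        gt1=fx.spec1,
        apriori=tuple(apriori),
        n_values=tuple(n_values if n_values is not None else defaults["n_values"]),
        kappa_values=tuple(d + e for e in extras),
        alpha1=alpha1 if alpha1 is not None else defaults["alpha1"],
        n_test=n_test if n_test is not None else defaults["n_test"],
        T=T if T is not None else defaults["T"],
        root_seed=root_seed,
        **kwargs,
    )


def _prior_moments(config: ExperimentConfig, spec: LinearSDESpec, offset_index: int, class_label: int):
    if config.prior_moment_source == "analytic":
        return stacked_moments(spec, config.grid)
    seed = np.random.SeedSequence(
        entropy=config.root_seed, spawn_key=(900 + offset_index, class_label)
    )
    return sde_moment_estimate(
        spec, config.grid, l=config.l_prior, seed=seed, substeps=config.substeps
    )


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Execute the full sweep and return the error table.

    One row per (classifier in {OBC, QDA}, offset, n, kappa), with the
    plug-in Bayes error for the same cell attached as columns. All cells
    are reproducible bit-exactly from ``config.root_seed``.
    """
    grid = config.grid
    d = grid.dim
    bayes = build_qda_from_sde(
        config.gt0,
        config.gt1,
        grid,
        config.alpha1,
        moment_source=config.bayes_moment_source,
        l=config.l_bayes,
        seed=np.random.SeedSequence(entropy=config.root_seed, spawn_key=(999,)),
    )
    rows = []
    for oi, (oname, oval, ap0, ap1) in enumerate(config.apriori):
        m0p, P0p = _prior_moments(config, ap0, oi, 0)
        m1p, P1p = _prior_moments(config, ap1, oi, 1)
        for ni, n in enumerate(config.n_values):
            for ki, kappa in enumerate(config.kappa_values):
                prior0 = NIWParams(m=m0p, Psi=(kappa - d - 1) * P0p, nu=kappa, kappa=kappa)
                prior1 = NIWParams(m=m1p, Psi=(kappa - d - 1) * P1p, nu=kappa, kappa=kappa)
                obc_errs = np.empty(config.T)
                qda_errs = np.empty(config.T)
                bayes_errs = np.empty(config.T)
                for r in range(config.T):
                    ss = np.random.SeedSequence(
                        entropy=config.root_seed, spawn_key=(oi, ni, ki, r)
                    )
                    s_tr0, s_tr1, s_te0, s_te1 = ss.spawn(4)
                    try:
                        tr0 = simulate_paths(
                            config.gt0, grid, n, config.substeps, s_tr0, label=0
                        )
                        tr1 = simulate_paths(
                            config.gt1, grid, n, config.substeps, s_tr1, label=1
                        )
                        te0 = simulate_paths(
                            config.gt0, grid, config.n_test, config.substeps, s_te0, label=0
                        )
                        te1 = simulate_paths(
                            config.gt1, grid, config.n_test, config.substeps, s_te1, label=1
                        )
                        post0 = posterior_update(prior0, tr0)
                        post1 = posterior_update(prior1, tr1)
                        obc = build_obc(post0, post1, config.alpha1)
                        qda = build_qda_from_data(tr0, tr1, config.alpha1)
                        obc_errs[r] = true_error(obc, te0, te1, config.alpha1)
                        qda_errs[r] = true_error(qda, te0, te1, config.alpha1)
                        bayes_errs[r] = true_error(bayes, te0, te1, config.alpha1)
                    except SDEBayesError as exc:
                        raise SDEBayesError(
                            f"replicate failed in cell (offset={oname}={oval}, n={n}, "
                            f"kappa={kappa}), replicate {r}, root_seed={config.root_seed}: {exc}"
                        ) from exc
                bayes_mean = float(bayes_errs.mean())
                bayes_se = _se(bayes_errs)
                for kind, errs in (("OBC", obc_errs), ("QDA", qda_errs)):
                    rows.append(
                        {
                            "classifier": kind,
                            "n": n,
                            "kappa": kappa,
                            "offset_name": oname,
                            "offset_value": oval,
                            "mean_error": float(errs.mean()),
                            "mc_se": _se(errs),
                            "bayes_error": bayes_mean,
                            "bayes_se": bayes_se,
                        }
                    )
                logger.info(
                    "cell offset=%s=%.4g n=%d kappa=%.0f: OBC %.4f QDA %.4f Bayes %.4f",
                    oname, oval, n, kappa,
                    obc_errs.mean(), qda_errs.mean(), bayes_mean,
                )
    return pd.DataFrame(rows, columns=list(ERROR_TABLE_COLUMNS))


def _se(errs: np.ndarray) -> float:
    if errs.size < 2:
        return 0.0
    return float(errs.std(ddof=1) / np.sqrt(errs.size))


def run_synthetic_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run the three-dimensional benchmark sweep (drift/dispersion offsets)."""
    if config.grid.p != 3:
        raise InvalidInputError("the synthetic benchmark uses p=3 processes")
    return run_experiment(config)


def run_ou_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run the OU trait-evolution sweep (adaptation-rate offsets)."""
    if config.grid.p != 1 or config.grid.N != 30:
        raise InvalidInputError("the OU experiment uses p=1 and N=30")
    return run_experiment(config)
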